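import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from scipy.ndimage import gaussian_filter1d

from sandgait.core_io import DataError
from sandgait.stats import (
    LMMSpec,
    anova_tukey,
    estimate_fwhm,
    fit_lmm,
    fpc_order,
    permutation_threshold,
    rft_threshold,
    spearman_correlogram,
    spm_paired_t,
    spm_paired_test,
    suprathreshold_clusters,
)


def smooth_field(n, nodes, fwhm, rng):
    """Unit-variance smooth Gaussian fields (n, nodes) with known FWHM."""
    sigma = fwhm / np.sqrt(8 * np.log(2))
    x = gaussian_filter1d(rng.standard_normal((n, nodes * 3)), sigma, axis=1, mode="wrap")
    x = x[:, nodes : 2 * nodes]
    return x / x.std(axis=0, ddof=1).mean()


def test_spm_paired_t_matches_scipy():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, (12, 20)), rng.normal(0, 1, (12, 20))
    t, df = spm_paired_t(a, b)
    assert df == 11
    for j in range(20):
        ref = sps.ttest_rel(a[:, j], b[:, j]).statistic
        assert t[j] == pytest.approx(ref, rel=1e-12)


def test_spm_paired_t_zero_variance_node_is_nan():
    a = np.tile(np.arange(10.0), (4, 1)).T.reshape(10, 4)
    t, _ = spm_paired_t(a, a)
    assert np.isnan(t).all()
    with pytest.raises(DataError):
        spm_paired_t(a[:2], a[:2])


def test_fwhm_white_noise():
    rng = np.random.default_rng(1)
    r = rng.standard_normal((4000, 101))
    # independent unit-variance nodes: mean squared gradient = 2
    assert estimate_fwhm(r) == pytest.approx(np.sqrt(4 * np.log(2) / 2), rel=0.02)


def test_fwhm_smoothed_calibration():
    rng = np.random.default_rng(2)
    for target in (8.0, 15.0, 25.0):
        r = smooth_field(400, 101, target, rng)
        assert estimate_fwhm(r) == pytest.approx(target, rel=0.12)


def test_fwhm_linear_field_effectively_infinite():
    # a linear field has no curvature; up to float error its FWHM is unbounded
    base = np.linspace(0, 1, 50)
    r = np.outer(np.array([1.0, 2.0, -1.0]), base)
    assert estimate_fwhm(r) > 1e6


def test_rft_threshold_monotonicity():
    # smoother fields need lower thresholds; stricter alpha needs higher ones
    u_rough = rft_threshold(20, 5.0)
    u_smooth = rft_threshold(20, 25.0)
    assert u_rough > u_smooth
    assert rft_threshold(20, 10.0, alpha=0.01) > rft_threshold(20, 10.0, alpha=0.05)


def test_rft_threshold_infinite_fwhm_is_pointwise_t():
    # with zero resels the expected-EC equation reduces to the pointwise
    # t quantile of the Poisson-clumping tail: P = 1 - exp(-sf(u))
    u = rft_threshold(20, np.inf, alpha=0.05)
    assert u == pytest.approx(sps.t.isf(-np.log(1 - 0.025), 20), abs=1e-4)


def test_rft_threshold_validation():
    with pytest.raises(DataError):
        rft_threshold(1, 10.0)
    with pytest.raises(DataError):
        rft_threshold(20, -1.0)
    with pytest.raises(DataError):
        rft_threshold(20, 10.0, alpha=1.5)


def test_suprathreshold_clusters():
    t = np.zeros(20)
    t[3:6] = 4.0
    t[10] = -5.0
    out = suprathreshold_clusters(t, 3.0)
    assert out == [(3.0, 5.0, 4.0), (10.0, 10.0, 5.0)]


def test_spm_paired_test_detects_large_effect():
    rng = np.random.default_rng(3)
    a = smooth_field(15, 101, 15.0, rng)
    b = smooth_field(15, 101, 15.0, rng)
    b[:, 40:60] += 4.0
    res = spm_paired_test(a, b, comparison="x", n_comparisons=6)
    assert res.alpha_effective == pytest.approx(0.05 / 6)
    assert res.clusters
    lo = min(c[0] for c in res.clusters)
    hi = max(c[1] for c in res.clusters)
    assert lo >= 30 and hi <= 70


def test_permutation_exhaustive_matches_bruteforce():
    rng = np.random.default_rng(4)
    d = rng.normal(0.3, 1.0, (6, 8))
    got = permutation_threshold(d, alpha=0.25, n_perm=10000, seed=0)
    # independent brute force over all 64 sign patterns
    maxima = []
    for signs in itertools.product((1.0, -1.0), repeat=6):
        f = d * np.array(signs)[:, None]
        t = f.mean(0) / (f.std(0, ddof=1) / np.sqrt(6))
        maxima.append(np.max(np.abs(t)))
    assert got == pytest.approx(float(np.quantile(maxima, 0.75)), rel=1e-12)
    assert permutation_threshold(d, alpha=1.0) == pytest.approx(min(maxima), rel=1e-12)


def test_permutation_validation():
    with pytest.raises(DataError):
        permutation_threshold(np.zeros((3, 5)))
    with pytest.raises(DataError):
        permutation_threshold(np.random.default_rng(0).normal(size=(8, 5)), alpha=0.0)


def test_anova_matches_scipy():
    rng = np.random.default_rng(5)
    groups = {k: rng.normal(mu, 1.0, 30) for k, mu in (("a", 0.0), ("b", 0.5), ("c", 1.2))}
    res = anova_tukey(groups)
    ref = sps.f_oneway(*groups.values())
    assert res.f == pytest.approx(ref.statistic, rel=1e-10)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-8)
    ref_tukey = sps.tukey_hsd(*groups.values())
    names = list(groups)
    for pair in res.tukey:
        i, j = names.index(pair.group_a), names.index(pair.group_b)
        assert pair.p == pytest.approx(ref_tukey.pvalue[i, j], abs=1e-6)


def test_anova_degenerate_cases():
    same = {"a": np.ones(5), "b": np.ones(5)}
    res = anova_tukey(same)
    assert res.f == 0.0 and res.p == 1.0
    sep = {"a": np.ones(5), "b": np.full(5, 2.0)}
    res = anova_tukey(sep)
    assert np.isinf(res.f) and res.p == 0.0
    with pytest.raises(DataError):
        anova_tukey({"a": np.ones(5)})
    with pytest.raises(DataError):
        anova_tukey({"a": np.ones(5), "b": np.ones(1)})


def test_spearman_monotone_pairs():
    x = np.linspace(0.0, 2.0, 30)
    tab = pd.DataFrame({"x": x, "up": np.exp(x), "down": -(x**3)})
    cm = spearman_correlogram(tab)
    i, j, k = (cm.variables.index(v) for v in ("x", "up", "down"))
    assert cm.rho[i, j] == pytest.approx(1.0)
    assert cm.rho[i, k] == pytest.approx(-1.0)
    assert cm.p[i, j] < 1e-10


def test_spearman_constant_variable_flagged():
    tab = pd.DataFrame({"x": np.arange(10.0), "c": np.ones(10), "y": np.arange(10.0) ** 2})
    cm = spearman_correlogram(tab)
    i = cm.variables.index("c")
    assert np.isnan(cm.rho[i, :]).all() or np.isnan(np.delete(cm.rho[i, :], i)).all()
    # constant variable sorts last in the PC1 ordering
    assert cm.order[-1] == i


def test_fpc_order_matches_eigen_oracle():
    rng = np.random.default_rng(6)
    for _ in range(10):
        data = rng.normal(size=(60, 7))
        data[:, 3] += 2.0 * data[:, 0]  # induce structure
        rho = np.corrcoef(data, rowvar=False)
        got = fpc_order(rho)
        evals, evecs = np.linalg.eigh(rho)
        v1 = evecs[:, np.argmax(evals)]
        if v1[np.argmax(np.abs(v1))] < 0:
            v1 = -v1
        expect = list(np.argsort(-v1, kind="stable"))
        assert got == expect


def _lmm_data(rng, n_participants=10, n_obs=6, effect=-0.12):
    rows = []
    for p in range(n_participants):
        u = rng.normal(0.0, 0.06)
        for sub in ("floor", "sand"):
            for _ in range(n_obs):
                y = 1.3 + (effect if sub == "sand" else 0.0) + u + rng.normal(0.0, 0.05)
                rows.append({"participant_id": f"P{p}", "substrate_id": sub, "speed": y})
    return pd.DataFrame(rows)


def test_fit_lmm_recovers_effect():
    rng = np.random.default_rng(7)
    data = _lmm_data(rng, n_participants=20, n_obs=10)
    fit = fit_lmm(LMMSpec(response="speed", fixed=["C(substrate_id)"]), data)
    name = [k for k in fit.estimates.index if "sand" in k][0]
    assert fit.estimates[name] == pytest.approx(-0.12, abs=3 * fit.se[name])
    assert fit.var_participant > 0
    assert not fit.singular


def test_fit_lmm_degenerate_inputs():
    rng = np.random.default_rng(8)
    data = _lmm_data(rng)
    with pytest.raises(DataError):
        fit_lmm(LMMSpec(response="speed", fixed=["C(substrate_id)"]), data[data.participant_id == "P0"])
    const = data.copy()
    const["speed"] = 1.0
    with pytest.raises(DataError):
        fit_lmm(LMMSpec(response="speed", fixed=["C(substrate_id)"]), const)
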