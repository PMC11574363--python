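"""Statistical battery: 1D-SPM paired t-tests with random-field-theory and
permutation thresholds, one-way ANOVA with Tukey HSD, Spearman correlograms
ordered by the first principal component, and REML linear mixed models.

The 1D-SPM machinery tests whole 101-node curves (joint angles, energies,
nEMG) between conditions while controlling the family-wise error over the
field.  The critical threshold solves the expected-Euler-characteristic
equation

    alpha_tail = 1 - exp(-(rho0(u) + R1 * rho1(u)))

with resel count R1 = (n_nodes - 1) / FWHM, rho0 the upper-tail t
probability and rho1 the 1D EC density of a t field.  Field smoothness
(FWHM) is estimated from normalized residual gradients.  A max-statistic
sign-flip permutation threshold provides a nonparametric cross-check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import DataError


# ---------------------------------------------------------------------------
# SPM paired t


@dataclass
class SPMResult:
    comparison: str
    t_field: np.ndarray  # (n_nodes,)
    df: int
    fwhm: float
    resels: float
    alpha: float
    alpha_effective: float
    t_critical: float
    clusters: list[tuple[float, float, float]]  # (start %, end %, max |t|)


def spm_paired_t(curves_a: np.ndarray, curves_b: np.ndarray) -> tuple[np.ndarray, int]:
    """Node-wise paired t field between two conditions.

    Inputs are (n_participants, n_nodes) arrays of participant-mean curves
    with matching participant order.  Returns (t field, df); zero-variance
    nodes yield NaN (flagged, not an error).
    """
    a = np.asarray(curves_a, float)
    b = np.asarray(curves_b, float)
    if a.shape != b.shape:
        raise DataError("paired conditions must have identical (participants, nodes) shape")
    n = a.shape[0]
    if n < 3:
        raise DataError("paired t needs >= 3 participants")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    return t, n - 1


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Field smoothness (FWHM, in nodes) from normalized residual gradients.

    Residual fields are scaled to unit variance per node; with v the mean
    squared node-to-node gradient, FWHM = sqrt(4 ln 2 / v).  Zero-variance
    nodes are excluded.  Returns inf for perfectly smooth (linear) fields.
    """
    r = np.asarray(residuals, float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise DataError("need an (n >= 2, nodes) residual array")
    sd = r.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise DataError("all residual nodes have zero variance")
    z = r[:, keep] / sd[keep]
    grad = np.diff(z, axis=1)
    v = float(np.mean(grad**2))
    if v <= 0:
        return float("inf")
    return float(np.sqrt(4 * np.log(2) / v))


def _ec_density_t(u: float, df: int) -> float:
    """1D Euler-characteristic density of a t field (unit-FWHM resel)."""
    return (np.sqrt(4 * np.log(2)) / (2 * np.pi)) * (1 + u**2 / df) ** (-(df - 1) / 2)


def rft_threshold(
    df: int,
    fwhm: float,
    n_nodes: int = 101,
    alpha: float = 0.05,
    two_sided: bool = True,
) -> float:
    """Random-field-theory critical |t| at family-wise level ``alpha``.

    Solves 1 - exp(-(rho0(u) + R1 rho1(u))) = alpha_tail by bisection on
    u in [0.5, 50] (alpha_tail = alpha/2 for two-sided fields).
    """
    if df < 2 or fwhm <= 0 or not 0 < alpha < 1:
        raise DataError("need df >= 2, fwhm > 0, 0 < alpha < 1")
    r1 = (n_nodes - 1) / fwhm if np.isfinite(fwhm) else 0.0
    target = alpha / 2 if two_sided else alpha

    def f(u: float) -> float:
        return 1.0 - np.exp(-(sps.t.sf(u, df) + r1 * _ec_density_t(u, df))) - target

    # bracket the root: f is decreasing in u, f(0+) > 0, f(inf) = -target < 0
    lo, hi = 0.5, 50.0
    while f(lo) < 0 and lo > 1e-6:
        lo /= 2
    while f(hi) > 0 and hi < 1e9:
        hi *= 2
    if f(lo) < 0 or f(hi) > 0:
        raise DataError(
            f"no RFT root in bracket (df={df}, fwhm={fwhm}, alpha={alpha})"
        )
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def suprathreshold_clusters(t_field: np.ndarray, t_critical: float) -> list[tuple[float, float, float]]:
    """Maximal runs of nodes where |t| exceeds the threshold.

    Returns (start %, end %, max |t|) per cluster, node index == % cycle.
    """
    over = np.abs(np.nan_to_num(t_field)) > t_critical
    clusters = []
    i = 0
    n = len(over)
    while i < n:
        if over[i]:
            j = i
            while j + 1 < n and over[j + 1]:
                j += 1
            seg = np.abs(t_field[i : j + 1])
            clusters.append((float(i), float(j), float(np.nanmax(seg))))
            i = j + 1
        else:
            i += 1
    return clusters


def spm_paired_test(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    comparison: str = "",
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> SPMResult:
    """Full paired 1D-SPM test with Bonferroni-adjusted RFT threshold."""
    t_field, df = spm_paired_t(curves_a, curves_b)
    d = np.asarray(curves_a, float) - np.asarray(curves_b, float)
    residuals = d - d.mean(axis=0)
    fwhm = estimate_fwhm(residuals)
    alpha_eff = alpha / max(n_comparisons, 1)
    t_crit = rft_threshold(df, fwhm, d.shape[1], alpha_eff)
    return SPMResult(
        comparison=comparison,
        t_field=t_field,
        df=df,
        fwhm=fwhm,
        resels=(d.shape[1] - 1) / fwhm if np.isfinite(fwhm) else 0.0,
        alpha=alpha,
        alpha_effective=alpha_eff,
        t_critical=t_crit,
        clusters=suprathreshold_clusters(t_field, t_crit),
    )


def permutation_threshold(
    differences: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Max-|t| sign-flip permutation threshold for paired difference fields.

    Deterministic given the seed; enumerates all 2^n sign patterns when that
    is cheaper than ``n_perm`` random draws.
    """
    d = np.asarray(differences, float)
    n, _ = d.shape
    if n < 5:
        raise DataError("need >= 5 participants for a meaningful permutation test")
    if not 0 < alpha <= 1:
        raise DataError("alpha must lie in (0, 1]")
    if n <= 20 and 2**n <= n_perm:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    maxima = np.empty(len(signs))
    chunk = 2000  # bound peak memory for large n_perm
    for i0 in range(0, len(signs), chunk):
        s = signs[i0 : i0 + chunk]
        flipped_mean = s @ d / n
        flipped_sq = (s**2) @ (d**2) / n  # == mean of d^2, constant rows
        var = (flipped_sq - flipped_mean**2) * n / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = flipped_mean / np.sqrt(var / n)
        maxima[i0 : i0 + len(s)] = np.nanmax(np.abs(t), axis=1)
    if alpha == 1.0:
        return float(maxima.min())
    return float(np.quantile(maxima, 1 - alpha))


# ---------------------------------------------------------------------------
# ANOVA + Tukey


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    diff: float
    q: float
    p: float


@dataclass
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    tukey: list[TukeyPair] = field(default_factory=list)


def anova_tukey(groups: dict[str, np.ndarray]) -> AnovaResult:
    """One-way ANOVA with Tukey HSD post hoc comparisons.

    F = MS_between / MS_within; Tukey p-values come from the studentized
    range distribution.  All-identical data yields F = 0, p = 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise DataError("ANOVA needs >= 2 groups")
    data = {k: np.asarray(v, float) for k, v in groups.items()}
    ns = {k: len(v) for k, v in data.items()}
    if min(ns.values()) < 2:
        raise DataError("every group needs >= 2 values")
    grand = np.mean(np.concatenate(list(data.values())))
    n_tot = sum(ns.values())
    k = len(names)
    ss_b = sum(ns[g] * (data[g].mean() - grand) ** 2 for g in names)
    ss_w = sum(((data[g] - data[g].mean()) ** 2).sum() for g in names)
    df_b, df_w = k - 1, n_tot - k
    ms_w = ss_w / df_w
    if ss_b == 0:
        f_stat, p = 0.0, 1.0
    elif ms_w == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_b / df_b) / ms_w
        p = float(sps.f.sf(f_stat, df_b, df_w))
    pairs = []
    for a, b in itertools.combinations(names, 2):
        diff = data[a].mean() - data[b].mean()
        se = np.sqrt(ms_w / 2 * (1 / ns[a] + 1 / ns[b])) if ms_w > 0 else 0.0
        if se == 0:
            q = float("inf") if diff != 0 else 0.0
            pq = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            pq = float(sps.studentized_range.sf(q, k, df_w))
        pairs.append(TukeyPair(a, b, float(diff), float(q), pq))
    return AnovaResult(float(f_stat), p, df_b, df_w, pairs)


# ---------------------------------------------------------------------------
# Spearman correlogram with PC1 ordering


@dataclass
class CorrMatrix:
    variables: list[str]
    rho: np.ndarray
    p: np.ndarray
    order: list[int]  # permutation of variables by first principal component

    def ordered(self) -> pd.DataFrame:
        idx = self.order
        names = [self.variables[i] for i in idx]
        return pd.DataFrame(self.rho[np.ix_(idx, idx)], index=names, columns=names)


def spearman_correlogram(table: pd.DataFrame) -> CorrMatrix:
    """Pairwise Spearman correlations with PC1 variable ordering.

    p-values use the t approximation t = rho sqrt((n-2)/(1-rho^2));
    constant variables get NaN correlations (flagged, excluded from PC1).
    """
    if table.shape[0] < 5 or table.shape[1] < 2:
        raise DataError("need >= 5 rows and >= 2 variables")
    names = list(table.columns)
    x = table.to_numpy(float)
    n = x.shape[0]
    ranks = np.apply_along_axis(sps.rankdata, 0, x)  # average ranks for ties
    sd = ranks.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho[sd == 0, :] = np.nan
    rho[:, sd == 0] = np.nan
    np.fill_diagonal(rho, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * sps.t.sf(np.abs(tstat), n - 2)
    p[np.abs(rho) >= 1 - 1e-15] = 0.0
    np.fill_diagonal(p, 0.0)
    order = fpc_order(rho)
    return CorrMatrix(names, rho, p, order)


def fpc_order(rho: np.ndarray) -> list[int]:
    """Order variables by descending loading on rho's first eigenvector.

    The eigenvector sign is fixed so its largest-magnitude entry is positive;
    variables with undefined correlations sort last (loading -inf).
    """
    r = np.array(rho, float)
    valid = ~np.isnan(r).all(axis=1)
    idx = np.flatnonzero(valid)
    sub = r[np.ix_(idx, idx)]
    sub = np.nan_to_num(sub, nan=0.0)
    evals, evecs = np.linalg.eigh(sub)
    v1 = evecs[:, -1]
    if v1[np.argmax(np.abs(v1))] < 0:
        v1 = -v1
    loadings = np.full(len(r), -np.inf)
    loadings[idx] = v1
    return list(np.argsort(-loadings, kind="stable"))


# ---------------------------------------------------------------------------
# linear mixed models


@dataclass
class LMMSpec:
    response: str
    fixed: list[str] = field(default_factory=lambda: ["C(substrate_id)", "C(sex)", "speed"])
    interactions: list[str] = field(default_factory=list)
    group: str = "participant_id"


@dataclass
class LMMResult:
    spec: LMMSpec
    estimates: pd.Series
    se: pd.Series
    pvalues: pd.Series
    var_participant: float
    var_residual: float
    converged: bool
    singular: bool


def fit_lmm(spec: LMMSpec, data: pd.DataFrame) -> LMMResult:
    """REML random-intercept mixed model via statsmodels MixedLM.

    Fixed effects per the spec (substrate, sex, speed and optional
    interactions); participants enter as random intercepts.  A singular fit
    is flagged and its participant variance reported as 0.
    """
    import statsmodels.formula.api as smf

    if data[spec.group].nunique() < 2:
        raise DataError("mixed model needs >= 2 participants")
    if np.ptp(data[spec.response].to_numpy(float)) == 0:
        raise DataError("response is constant")
    terms = [t for t in spec.fixed + spec.interactions if t]
    # drop fixed effects that are constant in this dataset (e.g. one substrate)
    kept = []
    for t in terms:
        cols = [c.strip() for c in t.replace("C(", "").replace(")", "").split(":")]
        if all(data[c].nunique() > 1 for c in cols if c in data.columns):
            kept.append(t)
    formula = f"{spec.response} ~ " + (" + ".join(kept) if kept else "1")
    model = smf.mixedlm(formula, data=data, groups=data[spec.group])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True, method=["lbfgs", "bfgs"])
        except np.linalg.LinAlgError:
            # gradient-based optimizers can hit a singular profile-likelihood
            # step on near-boundary variance components; Powell is slower but
            # derivative-free
            fit = model.fit(reml=True, method="powell", maxiter=2000)
    var_p = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    singular = bool(var_p < 1e-10)
    fe = fit.params.drop(labels=[i for i in fit.params.index if "Group" in i], errors="ignore")
    return LMMResult(
        spec=spec,
        estimates=fe,
        se=fit.bse[fe.index],
        pvalues=fit.pvalues[fe.index],
        var_participant=0.0 if singular else var_p,
        var_residual=float(fit.scale),
        converged=bool(fit.converged),
        singular=singular,
    )
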