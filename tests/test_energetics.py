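import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sandgait.core_io import (
    AnthropometricTable,
    DataError,
    MarkerSchema,
    SchemaError,
    Segment,
)
from sandgait.energetics import (
    G,
    EnergySeries,
    body_com,
    energies,
    exchange_metrics,
    stride_exchange,
)
from sandgait.events import Stride
from sandgait.synthetic import oracle_exchange

from conftest import make_trial


def _two_segment_setup():
    table = AnthropometricTable(
        [
            Segment("a", "P1", "D1", 0.6, 0.5),
            Segment("b", "P2", "D2", 0.4, 0.25),
        ]
    )
    roles = {r: r for r in ("SACR", "LHEE", "RHEE", "LHALL", "RHALL", "P1", "D1", "P2", "D2")}
    schema = MarkerSchema(roles)
    n = 10
    filler = {r: np.zeros((n, 3)) for r in ("SACR", "LHEE", "RHEE", "LHALL", "RHALL")}
    markers = {
        **filler,
        "P1": np.tile([0.0, 0.0, 1.0], (n, 1)),
        "D1": np.tile([1.0, 0.0, 1.0], (n, 1)),
        "P2": np.tile([0.0, 0.0, 0.0], (n, 1)),
        "D2": np.tile([0.0, 0.0, 2.0], (n, 1)),
    }
    return table, schema, make_trial(markers)


def test_body_com_two_segment_oracle():
    table, schema, trial = _two_segment_setup()
    com = body_com(trial, schema, table)
    # seg a CoM = (0.5, 0, 1); seg b CoM = (0, 0, 0.5)
    expect = 0.6 * np.array([0.5, 0.0, 1.0]) + 0.4 * np.array([0.0, 0.0, 0.5])
    assert np.allclose(com, expect, atol=1e-12)


def test_body_com_missing_segment_raises():
    table, schema, trial = _two_segment_setup()
    del trial.markers["D2"]
    with pytest.raises(SchemaError, match="b"):
        body_com(trial, schema, table)


def test_body_com_direct_channel_bypass():
    table, schema, trial = _two_segment_setup()
    direct = np.tile([9.0, 9.0, 9.0], (10, 1))
    trial.markers["P1"] = direct  # reuse an existing role as the CoM channel
    assert np.array_equal(body_com(trial, schema, table, com_role="P1"), direct)


def test_energies_stationary_com():
    com = np.tile([0.3, 0.1, 0.9], (50, 1))
    es = energies(com, body_mass=70.0, rate=200.0, lowpass_hz=None)
    assert np.allclose(es.e_kin, 0.0, atol=1e-20)
    assert np.allclose(es.e_pot, 70.0 * G * 0.9, atol=1e-9)


def test_energies_constant_velocity():
    t = np.arange(100) / 200.0
    com = np.column_stack([1.5 * t, np.zeros_like(t), np.full_like(t, 0.9)])
    es = energies(com, body_mass=70.0, rate=200.0, lowpass_hz=None)
    assert np.allclose(es.e_kin, 0.5 * 70.0 * 1.5**2, atol=1e-9)


def test_energies_sagittal_component_restriction():
    t = np.arange(100) / 200.0
    com = np.column_stack([1.5 * t, 2.0 * t, np.full_like(t, 0.9)])
    es = energies(com, 70.0, 200.0, lowpass_hz=None, components="xz")
    assert np.allclose(es.e_kin, 0.5 * 70.0 * 1.5**2, atol=1e-9)


def test_energies_input_validation():
    with pytest.raises(DataError):
        energies(np.zeros((3, 3)), 70.0, 200.0)
    with pytest.raises(DataError):
        energies(np.zeros((10, 2)), 70.0, 200.0)
    with pytest.raises(DataError):
        energies(np.zeros((10, 3)), 70.0, 0.0)


def _sine_series(phase_deg, n=2001):
    t = np.linspace(0.0, 2.0, n)
    e_pot = 30.0 + 10.0 * np.sin(2 * np.pi * t)
    e_kin = 40.0 + 10.0 * np.sin(2 * np.pi * t + np.radians(phase_deg))
    return EnergySeries(t, e_pot, e_kin)


def test_exchange_limits():
    anti = exchange_metrics(_sine_series(180.0))
    assert anti.r == pytest.approx(100.0, abs=1e-9)
    assert anti.co == pytest.approx(0.0, abs=1e-9)
    inphase = exchange_metrics(_sine_series(0.0))
    assert inphase.r == pytest.approx(0.0, abs=1e-9)
    assert inphase.co == pytest.approx(100.0, abs=1e-9)
    quarter = exchange_metrics(_sine_series(90.0))
    assert quarter.co == pytest.approx(50.0, abs=1.0)


@given(phase=st.floats(min_value=5.0, max_value=355.0))
@settings(max_examples=25, deadline=None)
def test_exchange_matches_bruteforce_oracle(phase):
    es = _sine_series(phase, n=801)
    m = exchange_metrics(es)
    r, ra, co = oracle_exchange(es.e_pot, es.e_kin)
    assert m.r == pytest.approx(r, abs=1e-9)
    assert m.ra == pytest.approx(ra, abs=1e-12)
    assert m.co == pytest.approx(co, abs=1e-9)


def test_exchange_offset_and_time_rescaling_invariance():
    es = _sine_series(132.0)
    base = exchange_metrics(es)
    shifted = exchange_metrics(EnergySeries(es.time, es.e_pot + 123.0, es.e_kin + 45.0))
    assert shifted.r == pytest.approx(base.r, abs=1e-9)
    assert shifted.ra == pytest.approx(base.ra, abs=1e-12)
    assert shifted.co == pytest.approx(base.co, abs=1e-9)
    rescaled = exchange_metrics(EnergySeries(es.time * 3.0, es.e_pot, es.e_kin))
    assert rescaled.r == pytest.approx(base.r, abs=1e-9)
    assert rescaled.co == pytest.approx(base.co, abs=1e-9)


def test_exchange_phase_sweep_monotone_recovery():
    # moving away from perfect anti-phase strictly lowers recovery
    rs = [exchange_metrics(_sine_series(p)).r for p in (180.0, 150.0, 120.0, 90.0)]
    assert all(a > b for a, b in zip(rs, rs[1:]))


def test_exchange_errors():
    t = np.linspace(0, 1, 101)
    with pytest.raises(DataError):
        exchange_metrics(EnergySeries(t, np.ones_like(t), np.ones_like(t)))


def test_stride_exchange_rows(one_trial, schema):
    trial, truth = one_trial
    from sandgait.core_io import default_anthropometric_table

    strides = [
        Stride(r.side, r.heel_strike, r.end, r.toe_off)
        for r in truth.strides.itertuples()
    ]
    rows = stride_exchange(trial, schema, default_anthropometric_table(), strides)
    assert len(rows) == len(strides)
    for row, (_, gt) in zip(rows, truth.strides.iterrows()):
        assert row["r_pct"] == pytest.approx(gt.r_pct, abs=0.5)
        assert row["co_pct"] == pytest.approx(gt.co_pct, abs=1.0)
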