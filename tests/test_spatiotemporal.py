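import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sandgait.core_io import DataError
from sandgait.events import GaitEventSet, Stride
from sandgait.spatiotemporal import (
    coefficient_of_variation,
    compute_sinkage,
    compute_spatiotemporal,
    cv_relative_change,
)
from sandgait.synthetic import synthetic_schema

from conftest import make_trial

RATE = 200.0


def _hand_trial(v=1.25, n=1201):
    t = np.arange(n) / RATE
    zeros = np.zeros(n)
    markers = {
        "SACR": np.column_stack([v * t, zeros, np.full(n, 0.95)]),
        "LHEE": np.column_stack([v * t, np.full(n, 0.06), zeros]),
        "RHEE": np.column_stack([v * t, np.full(n, -0.06), zeros]),
        "LHALL": np.column_stack([v * t, np.full(n, 0.06), zeros]),
        "RHALL": np.column_stack([v * t, np.full(n, -0.06), zeros]),
    }
    events = GaitEventSet(
        heel_strikes={
            "left": np.array([1.0, 2.0, 3.0, 4.0]),
            "right": np.array([0.5, 1.5, 2.5, 3.5, 4.5]),
        },
        toe_offs={
            "left": np.array([1.62, 2.62, 3.62]),
            "right": np.array([1.12, 2.12, 3.12, 4.12]),
        },
    )
    trial = make_trial(markers, rate=RATE)
    strides = [
        Stride("left", 1.0, 2.0, 1.62),
        Stride("left", 2.0, 3.0, 2.62),
        Stride("right", 1.5, 2.5, 2.12),
    ]
    return trial, events, strides


def test_spatiotemporal_hand_example(schema):
    trial, events, strides = _hand_trial(v=1.25)
    out = compute_spatiotemporal(trial, strides, events, schema)
    assert len(out) == 3
    row = out.iloc[0]
    assert row.cycle_time == pytest.approx(1.0)
    assert row.stance_time == pytest.approx(0.62)
    assert row.swing_time == pytest.approx(0.38)
    assert row.duty_factor == pytest.approx(0.62)
    assert row.speed == pytest.approx(1.25, rel=1e-9)
    assert row.stride_length == pytest.approx(1.25, rel=1e-9)
    # symmetric gait: double support = cycle * (2*duty - 1)
    assert row.double_support_time == pytest.approx(1.0 * (2 * 0.62 - 1), abs=1e-9)
    # heel y-separation is constant 0.12 m
    assert row.stride_width == pytest.approx(0.12, abs=1e-12)


def test_spatiotemporal_invalid_strides_skipped(schema):
    trial, events, strides = _hand_trial()
    strides[1].valid = False
    out = compute_spatiotemporal(trial, strides, events, schema)
    assert len(out) == 2


def test_stride_width_missing_contralateral(schema):
    trial, events, strides = _hand_trial()
    events.heel_strikes["right"] = np.array([5.0, 5.9])  # outside left strides
    events.toe_offs["right"] = np.array([5.5])
    out = compute_spatiotemporal(trial, strides[:2], events, schema)
    assert out.stride_width.isna().all()
    assert (out.stride_width_reason == "no contralateral heel-strike in stride").all()


def test_sinkage_hand_example(schema):
    trial, _, strides = _hand_trial()
    trial = make_trial(dict(trial.markers), rate=RATE, surface_z=0.10)
    trial.markers["LHEE"] = trial.markers["LHEE"].copy()
    trial.markers["LHEE"][:, 2] = 0.10
    trial.markers["LHEE"][205:215, 2] = 0.06  # dip inside the first left stride
    out = compute_sinkage(trial, strides[:1], schema)
    assert out.heel_sink_depth.iloc[0] == pytest.approx(4.0, abs=1e-9)
    assert out.hallux_sink_depth.iloc[0] == pytest.approx(10.0, abs=1e-9)  # z = 0


def test_sinkage_negative_flagged_and_gap_missing(schema):
    trial, _, strides = _hand_trial()
    trial = make_trial(dict(trial.markers), rate=RATE, surface_z=0.0)
    trial.markers["LHEE"] = trial.markers["LHEE"].copy()
    trial.markers["LHEE"][:, 2] = 0.02  # always above the surface
    trial.markers["LHALL"] = trial.markers["LHALL"].copy()
    trial.markers["LHALL"][150:450, 2] = np.nan  # long gap spanning the stride
    out = compute_sinkage(trial, strides[:1], schema)
    row = out.iloc[0]
    assert row.heel_sink_depth == pytest.approx(-2.0, abs=1e-9)
    assert row.heel_sink_depth_flagged
    assert np.isnan(row.hallux_sink_depth)
    assert row.hallux_sink_depth_reason == "marker gap spans stride"


def test_cv_hand_example():
    out = coefficient_of_variation(
        pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        pd.Series(["a", "a", "a", "b", "b", "b"]),
    )
    a = out[out.group == "a"].iloc[0]
    assert a["mean"] == pytest.approx(2.0)
    assert a["sd"] == pytest.approx(1.0)
    assert a["cv"] == pytest.approx(0.5)


@given(scale=st.floats(min_value=0.01, max_value=1e4))
@settings(max_examples=25, deadline=None)
def test_cv_scale_invariance(scale):
    vals = pd.Series([1.0, 2.0, 3.0])
    grp = pd.Series(["g", "g", "g"])
    base = coefficient_of_variation(vals, grp).cv.iloc[0]
    scaled = coefficient_of_variation(vals * scale, grp).cv.iloc[0]
    assert scaled == pytest.approx(base, rel=1e-9)


def test_cv_errors():
    with pytest.raises(DataError):
        coefficient_of_variation(pd.Series([1.0]), pd.Series(["a"]))
    with pytest.raises(DataError):
        coefficient_of_variation(pd.Series([-1.0, 1.0]), pd.Series(["a", "a"]))


def test_cv_relative_change():
    tab = coefficient_of_variation(
        pd.Series([1.0, 2.0, 3.0, 2.0, 4.0, 6.0]),
        pd.Series(["floor", "floor", "floor", "sand", "sand", "sand"]),
    )
    out = cv_relative_change(tab, "floor")
    assert out[out.group == "floor"].cv_change_pct.iloc[0] == pytest.approx(0.0)
    assert out[out.group == "sand"].cv_change_pct.iloc[0] == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(DataError):
        cv_relative_change(tab, "nope")
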