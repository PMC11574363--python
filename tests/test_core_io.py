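import numpy as np
import pandas as pd
import pytest

from sandgait.core_io import (
    AnthropometricTable,
    ConfigError,
    DataError,
    MarkerSchema,
    RateError,
    SchemaError,
    Segment,
    default_anthropometric_table,
    dump_config,
    fill_gaps,
    load_config,
    read_stride_table,
    read_tabular_trial,
    write_stride_table,
    write_tabular_trial,
)

from conftest import make_trial


def test_default_anthropometric_fractions_sum_to_one():
    table = default_anthropometric_table()
    assert len(table.segments) == 13
    assert sum(s.mass_fraction for s in table.segments) == pytest.approx(1.0, abs=1e-9)


def test_anthropometric_table_rejects_bad_fractions():
    with pytest.raises(ConfigError):
        AnthropometricTable([Segment("a", "X", "Y", 0.5, 0.5)])
    with pytest.raises(ConfigError):
        AnthropometricTable([Segment("a", "X", "Y", 1.0, 1.5)])


def test_schema_missing_required_role():
    with pytest.raises(SchemaError):
        MarkerSchema({"SACR": "SACR"})


def test_schema_duplicate_label():
    roles = {r: r for r in ("SACR", "LHEE", "RHEE", "LHALL", "RHALL")}
    roles["RHALL"] = "LHALL"
    with pytest.raises(SchemaError):
        MarkerSchema(roles)


def test_schema_resolves_and_reports_missing(schema):
    trial = make_trial({"SACR": np.zeros((10, 3))})
    assert schema.series(trial, "SACR").shape == (10, 3)
    assert schema.has(trial, "SACR")
    assert not schema.has(trial, "LHEE")
    with pytest.raises(SchemaError):
        schema.series(trial, "LHEE")


def test_trial_validation_errors():
    with pytest.raises(DataError):
        make_trial({}, mass=-1.0)
    with pytest.raises(DataError):
        make_trial({}, direction=2)
    with pytest.raises(DataError):
        make_trial({"A": np.zeros((5, 3)), "B": np.zeros((6, 3))})


def test_fill_gaps_cubic_exact_and_long_gap_reported():
    idx = np.arange(50, dtype=float)
    xyz = np.column_stack([idx**3, idx, np.ones(50)])
    xyz[10:14] = np.nan  # short interior gap, cubic-recoverable
    xyz[30:45] = np.nan  # long gap
    filled, long_gaps = fill_gaps(xyz, max_gap=10)
    expect = np.column_stack([idx**3, idx, np.ones(50)])
    assert np.allclose(filled[10:14], expect[10:14], atol=1e-6)
    assert long_gaps == [(30, 45)]
    assert np.isnan(filled[30:45]).all()


def test_fill_gaps_edge_gap_not_filled():
    xyz = np.ones((20, 3))
    xyz[:3] = np.nan
    filled, long_gaps = fill_gaps(xyz, max_gap=10)
    assert long_gaps == [(0, 3)]


def test_tabular_round_trip(tmp_path, one_trial):
    trial, _ = one_trial
    mk, em = tmp_path / "m.csv", tmp_path / "e.csv"
    write_tabular_trial(trial, mk, em)
    meta = dict(
        trial_id=trial.trial_id,
        participant_id=trial.participant_id,
        sex=trial.sex,
        body_mass=trial.body_mass,
        height=trial.height,
        substrate_id=trial.substrate_id,
        substrate_surface_z=trial.substrate_surface_z,
        travel_direction=trial.travel_direction,
    )
    back = read_tabular_trial(mk, em, meta=meta)
    assert back.marker_rate == pytest.approx(trial.marker_rate, rel=1e-6)
    assert set(back.markers) == set(trial.markers)
    for label in trial.markers:
        assert np.allclose(back.markers[label], trial.markers[label], atol=1e-8)
    for muscle in trial.emg:
        assert np.allclose(back.emg[muscle], trial.emg[muscle], atol=1e-12)


def test_tabular_rejects_nonuniform_time(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame(
        {"time": [0.0, 0.005, 0.02], "label": "SACR", "x": 0.0, "y": 0.0, "z": 0.0}
    ).to_csv(path, index=False)
    with pytest.raises(RateError):
        read_tabular_trial(path, meta=dict(
            trial_id="t", participant_id="p", sex="male", body_mass=70.0,
            height=1.8, substrate_id="hard_floor", substrate_surface_z=0.0,
            travel_direction=1,
        ))


def test_stride_table_round_trip(tmp_path):
    df = pd.DataFrame(
        {
            "trial_id": ["a", "a"],
            "side": ["left", "right"],
            "stride_index": [0, 0],
            "cycle_time": [1.1, 1.12],
            "heel_sink_depth": [2.0, np.nan],
        }
    )
    path = tmp_path / "strides.csv"
    write_stride_table(df, path)
    back = read_stride_table(path)
    assert list(back.trial_id) == ["a", "a"]
    assert back.cycle_time.tolist() == pytest.approx([1.1, 1.12])
    assert np.isnan(back.heel_sink_depth.iloc[1])


def test_config_round_trip(tmp_path):
    cfg = {"n_participants": 3, "seed": 9, "duty_factor": 0.62}
    path = tmp_path / "cfg.yaml"
    dump_config(cfg, path)
    assert load_config(path) == cfg


def test_config_rejects_non_mapping(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("- 1\n- 2\n")
    with pytest.raises(ConfigError):
        load_config(path)
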