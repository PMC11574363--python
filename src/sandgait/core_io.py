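"""Domain types, coordinate conventions and file I/O shared by all stages.

Conventions used throughout the package:

* lab frame: right-handed, ``x`` = direction of progression (signed by
  ``travel_direction``), ``y`` = mediolateral, ``z`` = vertical up with
  ``z = 0`` at the hard lab floor;
* units: positions in metres, times in seconds, angles in degrees,
  masses in kilograms, EMG in volts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml


class SandgaitError(Exception):
    """Base class for all package errors."""


class SchemaError(SandgaitError):
    """A required marker role is missing or mapped inconsistently."""


class FormatError(SandgaitError):
    """A file does not conform to the expected layout."""


class RateError(SandgaitError):
    """Sampling is non-uniform or a rate is invalid."""


class ConfigError(SandgaitError):
    """A configuration value violates its invariants."""


class DataError(SandgaitError):
    """Input data violates a precondition of an operation."""


#: default surface-EMG muscle labels (left lower limb)
EMG_MUSCLES = ("BFL", "RF", "VL", "VM", "TA", "LG", "MG", "SOL")

#: maximum marker gap (frames) filled by cubic interpolation
DEFAULT_MAX_GAP_FRAMES = 10


@dataclass
class TrialRecording:
    """Synchronized marker + EMG time series and metadata for one walking pass."""

    trial_id: str
    participant_id: str
    sex: str  # "male" | "female"
    body_mass: float  # kg
    height: float  # m
    substrate_id: str
    substrate_surface_z: float  # m above lab z=0
    travel_direction: int = 1  # +1 / -1 along lab x
    marker_rate: float = 200.0  # Hz
    markers: dict[str, np.ndarray] = field(default_factory=dict)  # label -> (n,3) m
    emg_rate: float = 1110.0  # Hz
    emg: dict[str, np.ndarray] = field(default_factory=dict)  # muscle -> (n,) V
    t0: float = 0.0  # shared clock origin, s

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.marker_rate <= 0 or self.emg_rate <= 0:
            raise RateError("marker_rate and emg_rate must be positive")
        if self.body_mass <= 0:
            raise DataError("body_mass must be positive")
        if self.substrate_surface_z < 0:
            raise DataError("substrate_surface_z must be >= 0")
        if self.travel_direction not in (-1, 1):
            raise DataError("travel_direction must be +1 or -1")
        if self.sex not in ("male", "female"):
            raise DataError(f"unknown sex {self.sex!r}")
        lengths = {len(v) for v in self.markers.values()}
        if len(lengths) > 1:
            raise DataError("all marker series must have identical length")
        for label, xyz in self.markers.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise DataError(f"marker {label!r} must be an (n, 3) array")
            self.markers[label] = arr
        elengths = {len(v) for v in self.emg.values()}
        if len(elengths) > 1:
            raise DataError("all EMG series must have identical length")
        for label, v in self.emg.items():
            self.emg[label] = np.asarray(v, dtype=float)

    @property
    def n_frames(self) -> int:
        return 0 if not self.markers else len(next(iter(self.markers.values())))

    @property
    def duration(self) -> float:
        return max(self.n_frames - 1, 0) / self.marker_rate

    def marker_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.marker_rate

    def emg_times(self) -> np.ndarray:
        n = 0 if not self.emg else len(next(iter(self.emg.values())))
        return self.t0 + np.arange(n) / self.emg_rate

    def time_to_frame(self, t: float | np.ndarray) -> np.ndarray:
        """Nearest marker frame index for a time on the shared clock."""
        idx = np.rint((np.asarray(t) - self.t0) * self.marker_rate).astype(int)
        return np.clip(idx, 0, max(self.n_frames - 1, 0))


#: semantic roles every downstream stage relies on
REQUIRED_ROLES = ("SACR", "LHEE", "RHEE", "LHALL", "RHALL")


@dataclass
class MarkerSchema:
    """Mapping of semantic roles (SACR, LHEE, ...) to trial marker labels."""

    roles: dict[str, str]

    def __post_init__(self) -> None:
        missing = [r for r in REQUIRED_ROLES if r not in self.roles]
        if missing:
            raise SchemaError(f"schema is missing required roles: {missing}")
        labels = list(self.roles.values())
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise SchemaError(f"labels mapped to more than one role: {dupes}")

    @classmethod
    def identity(cls, roles: tuple[str, ...] | list[str]) -> "MarkerSchema":
        return cls({r: r for r in roles})

    def label(self, role: str) -> str:
        try:
            return self.roles[role]
        except KeyError:
            raise SchemaError(f"schema does not define role {role!r}") from None

    def series(self, trial: TrialRecording, role: str) -> np.ndarray:
        """Resolve a role to its (n, 3) marker series.

        The virtual roles MIDHIP and MIDSHO are computed as midpoints of the
        corresponding left/right joint-centre roles.
        """
        if role == "MIDHIP":
            return 0.5 * (self.series(trial, "LHIP") + self.series(trial, "RHIP"))
        if role == "MIDSHO":
            return 0.5 * (self.series(trial, "LSHO") + self.series(trial, "RSHO"))
        label = self.label(role)
        if label not in trial.markers:
            raise SchemaError(
                f"trial {trial.trial_id!r} has no marker {label!r} (role {role!r})"
            )
        return trial.markers[label]

    def has(self, trial: TrialRecording, role: str) -> bool:
        try:
            self.series(trial, role)
            return True
        except SchemaError:
            return False


@dataclass(frozen=True)
class Segment:
    """One rigid segment of the whole-body model."""

    name: str
    proximal: str  # schema role of the proximal endpoint
    distal: str  # schema role of the distal endpoint
    mass_fraction: float  # of body mass
    com_fraction: float  # position of segment CoM along proximal->distal


@dataclass
class AnthropometricTable:
    """Segment mass and CoM-position fractions for the 13-segment model."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        total = sum(s.mass_fraction for s in self.segments)
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"segment mass fractions sum to {total}, expected 1")
        for s in self.segments:
            if not 0.0 <= s.com_fraction <= 1.0:
                raise ConfigError(f"segment {s.name}: com_fraction outside [0, 1]")


def default_anthropometric_table() -> AnthropometricTable:
    """Dempster-derived mass/CoM fractions for the 13 segments.

    Segments: feet, shanks, thighs, upper arms and forearms (with hands)
    bilaterally, plus head, trunk and pelvis.  Fractions follow the classic
    cadaver-based tables used in gait analysis; forearm carries the hand mass.
    """
    bilateral = [
        ("foot", "ANK", "TOE", 0.0145, 0.50),
        ("shank", "KNEE", "ANK", 0.0465, 0.433),
        ("thigh", "HIP", "KNEE", 0.100, 0.433),
        ("upper_arm", "SHO", "ELB", 0.028, 0.436),
        ("forearm", "ELB", "WRI", 0.022, 0.682),
    ]
    segs: list[Segment] = []
    for name, prox, dist, m, c in bilateral:
        for side in ("L", "R"):
            segs.append(Segment(f"{side.lower()}_{name}", side + prox, side + dist, m, c))
    segs.append(Segment("head", "C7", "HEAD", 0.081, 0.5))
    segs.append(Segment("trunk", "MIDSHO", "MIDHIP", 0.355, 0.5))
    segs.append(Segment("pelvis", "SACR", "MIDHIP", 0.142, 0.5))
    return AnthropometricTable(segs)


def anthropometric_table_from_mapping(rows: list[dict]) -> AnthropometricTable:
    """Build a table from config rows (name/proximal/distal/mass_fraction/com_fraction)."""
    return AnthropometricTable([Segment(**row) for row in rows])


# ---------------------------------------------------------------------------
# gap filling


def fill_gaps(xyz: np.ndarray, max_gap: int = DEFAULT_MAX_GAP_FRAMES) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Fill NaN runs up to ``max_gap`` frames by cubic interpolation.

    Returns the filled series and the list of (start, stop) index ranges of
    gaps that were too long to fill (these invalidate overlapping strides).
    """
    from scipy.interpolate import CubicSpline

    out = np.array(xyz, dtype=float)
    bad = np.isnan(out).any(axis=1)
    if not bad.any():
        return out, []
    long_gaps: list[tuple[int, int]] = []
    idx = np.arange(len(out))
    # locate contiguous NaN runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2]))
    good = ~bad
    if good.sum() >= 4:
        spline = CubicSpline(idx[good], out[good], axis=0)
    else:
        spline = None
    for start, stop in runs:
        interior = start > 0 and stop < len(out)
        if interior and (stop - start) <= max_gap and spline is not None:
            out[start:stop] = spline(idx[start:stop])
        else:
            long_gaps.append((start, stop))
    return out, long_gaps


# ---------------------------------------------------------------------------
# tabular trial format
#
# markers: CSV with columns time, label, x, y, z (long format, seconds/metres)
# emg:     CSV with columns time, muscle, value (seconds/volts)

_TIME_JITTER = 1e-6  # s


def _uniform_rate(times: np.ndarray, what: str) -> float:
    times = np.sort(np.unique(times))
    if len(times) < 2:
        raise RateError(f"{what}: need at least 2 samples to infer a rate")
    dt = np.diff(times)
    if np.ptp(dt) > _TIME_JITTER:
        raise RateError(
            f"{what}: non-uniform sampling (time step spread {np.ptp(dt):.3g} s)"
        )
    return 1.0 / float(np.mean(dt))


def read_tabular_trial(
    markers_path,
    emg_path=None,
    *,
    meta: dict,
) -> TrialRecording:
    """Read a trial from long-format marker (and optional EMG) CSV files.

    ``meta`` supplies the TrialRecording metadata fields (trial_id,
    participant_id, sex, body_mass, height, substrate_id,
    substrate_surface_z, travel_direction).
    """
    mdf = pd.read_csv(markers_path, comment="#")
    expected = {"time", "label", "x", "y", "z"}
    if not expected.issubset(mdf.columns):
        raise FormatError(f"marker table must have columns {sorted(expected)}")
    if mdf.duplicated(subset=["time", "label"]).any():
        raise FormatError("duplicate (time, label) rows in marker table")
    rate = _uniform_rate(mdf["time"].to_numpy(), "markers")
    t0 = float(mdf["time"].min())
    markers: dict[str, np.ndarray] = {}
    n_frames = mdf["time"].nunique()
    for label, grp in mdf.groupby("label", sort=False):
        grp = grp.sort_values("time")
        if len(grp) != n_frames:
            raise FormatError(f"marker {label!r} does not cover every frame")
        markers[str(label)] = grp[["x", "y", "z"]].to_numpy(dtype=float)

    emg: dict[str, np.ndarray] = {}
    emg_rate = float(meta.get("emg_rate", 1110.0))
    if emg_path is not None:
        edf = pd.read_csv(emg_path, comment="#")
        if not {"time", "muscle", "value"}.issubset(edf.columns):
            raise FormatError("EMG table must have columns time, muscle, value")
        if edf.duplicated(subset=["time", "muscle"]).any():
            raise FormatError("duplicate (time, muscle) rows in EMG table")
        emg_rate = _uniform_rate(edf["time"].to_numpy(), "emg")
        for muscle, grp in edf.groupby("muscle", sort=False):
            emg[str(muscle)] = grp.sort_values("time")["value"].to_numpy(dtype=float)

    return TrialRecording(
        trial_id=str(meta["trial_id"]),
        participant_id=str(meta["participant_id"]),
        sex=meta.get("sex", "female"),
        body_mass=float(meta.get("body_mass", 68.5)),
        height=float(meta.get("height", 1.73)),
        substrate_id=str(meta.get("substrate_id", "hard_floor")),
        substrate_surface_z=float(meta.get("substrate_surface_z", 0.0)),
        travel_direction=int(meta.get("travel_direction", 1)),
        marker_rate=rate,
        markers=markers,
        emg_rate=emg_rate,
        emg=emg,
        t0=t0,
    )


def write_tabular_trial(trial: TrialRecording, markers_path, emg_path=None) -> None:
    """Write a trial to the long-format CSV files read by read_tabular_trial."""
    t = trial.marker_times()
    frames = []
    for label, xyz in trial.markers.items():
        frames.append(
            pd.DataFrame(
                {"time": t, "label": label, "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(markers_path, index=False, float_format="%.9f")
    if emg_path is not None and trial.emg:
        te = trial.emg_times()
        eframes = [
            pd.DataFrame({"time": te, "muscle": muscle, "value": v})
            for muscle, v in trial.emg.items()
        ]
        pd.concat(eframes, ignore_index=True).to_csv(emg_path, index=False, float_format="%.9e")


# ---------------------------------------------------------------------------
# stride table

STRIDE_TABLE_COLUMNS = [
    "participant_id",
    "trial_id",
    "substrate_id",
    "side",
    "stride_index",
    "speed",
    "stride_length",
    "stride_width",
    "cycle_time",
    "stance_time",
    "swing_time",
    "double_support_time",
    "duty_factor",
    "heel_sink_depth",
    "hallux_sink_depth",
]


def write_stride_table(rows: pd.DataFrame, path) -> None:
    """Write the tidy per-stride table as CSV with a documented column header."""
    cols = [c for c in STRIDE_TABLE_COLUMNS if c in rows.columns]
    cols += [c for c in rows.columns if c not in cols]
    with open(path, "w") as fh:
        fh.write(
            "# sandgait stride table: one row per (trial, side, stride); times s, "
            "lengths m, depths cm, speed m/s\n"
        )
        rows[cols].to_csv(fh, index=False, float_format="%.9g")


def read_stride_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# C3D

def read_c3d(path, schema: MarkerSchema, meta: dict) -> TrialRecording:
    """Read a C3D motion-capture file into a TrialRecording.

    Marker positions are converted to metres using POINT:UNITS; rates come
    from the file header.  Analog channels whose labels appear in the EMG
    muscle set (or in ``meta['emg_labels']``) are mapped as EMG.
    """
    from . import c3d as _c3d

    data = _c3d.read_c3d_file(path)
    labels_present = set(data.point_labels)
    for role in REQUIRED_ROLES:
        label = schema.label(role)
        if label not in labels_present:
            raise SchemaError(f"C3D file is missing required marker {label!r}")
    markers = {
        label: data.points[:, i, :] for i, label in enumerate(data.point_labels)
    }
    wanted = set(meta.get("emg_labels", EMG_MUSCLES))
    emg = {
        label: data.analog[:, i]
        for i, label in enumerate(data.analog_labels)
        if label in wanted
    }
    return TrialRecording(
        trial_id=str(meta["trial_id"]),
        participant_id=str(meta["participant_id"]),
        sex=meta.get("sex", "female"),
        body_mass=float(meta.get("body_mass", 68.5)),
        height=float(meta.get("height", 1.73)),
        substrate_id=str(meta.get("substrate_id", "hard_floor")),
        substrate_surface_z=float(meta.get("substrate_surface_z", 0.0)),
        travel_direction=int(meta.get("travel_direction", 1)),
        marker_rate=data.point_rate,
        markers=markers,
        emg_rate=data.analog_rate if emg else float(meta.get("emg_rate", 1110.0)),
        emg=emg,
        t0=float(meta.get("t0", 0.0)),
    )


# ---------------------------------------------------------------------------
# YAML config

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config file must contain a mapping at top level")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
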