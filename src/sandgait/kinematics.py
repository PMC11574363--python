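"""Sagittal joint angles, trial ROMs and 101-node gait-cycle normalization.

Angles are computed from three joint-centre points projected onto the plane
of progression (x-z).  Sign conventions (degrees): hip and knee flexion
positive, ankle dorsiflexion positive with 0 deg at anatomical neutral
(foot perpendicular to shank).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .core_io import DataError

N_NODES = 101  # 0..100 % gait cycle
_MIN_SEGMENT = 1e-3  # m; shorter segments yield missing samples

#: joint id -> (sign, offset_deg) applied to the raw proximal->distal
#: direction change; ankle is offset by 90 deg so neutral reads 0
_CONVENTIONS = {
    "hip": (-1.0, 0.0),
    "knee": (1.0, 0.0),
    "ankle": (-1.0, 90.0),
}


def sagittal_angle(
    proximal: np.ndarray,
    joint: np.ndarray,
    distal: np.ndarray,
    convention: str,
) -> np.ndarray:
    """Signed sagittal-plane angle series (deg) for hip / knee / ankle.

    The raw angle is the signed rotation (about +y) from the
    proximal->joint segment to the joint->distal segment in the x-z plane;
    the joint convention maps it to the clinical sign and neutral.
    Degenerate frames (segment shorter than 1 mm) are returned as NaN.
    """
    if convention not in _CONVENTIONS:
        raise DataError(f"unknown joint convention {convention!r}")
    u = np.asarray(joint, float) - np.asarray(proximal, float)
    w = np.asarray(distal, float) - np.asarray(joint, float)
    ux, uz = u[:, 0], u[:, 2]
    wx, wz = w[:, 0], w[:, 2]
    nu = np.hypot(ux, uz)
    nw = np.hypot(wx, wz)
    # signed rotation about +y: cross = u x w |_y = uz*wx - ux*wz
    cross = uz * wx - ux * wz
    dot = ux * wx + uz * wz
    ang = np.degrees(np.arctan2(cross, dot))
    sign, offset = _CONVENTIONS[convention]
    out = sign * (ang + offset)
    # wrap to (-180, 180]
    out = (out + 180.0) % 360.0 - 180.0
    out[(nu < _MIN_SEGMENT) | (nw < _MIN_SEGMENT)] = np.nan
    return out


def normalize_cycle(series: np.ndarray, times: np.ndarray, stride) -> np.ndarray:
    """Interpolate a per-stride series onto 101 nodes (0..100% cycle).

    Cubic (not-a-knot) interpolation, exact on polynomials of degree <= 3;
    stride must be covered by the series' time span.
    """
    series = np.asarray(series, float)
    times = np.asarray(times, float)
    if stride.start < times[0] - 1e-9 or stride.end > times[-1] + 1e-9:
        raise DataError("stride extends beyond the series")
    nodes = np.linspace(stride.start, stride.end, N_NODES)
    good = ~np.isnan(series)
    if good.sum() < 4:
        raise DataError("too few finite samples to interpolate a stride")
    spline = CubicSpline(times[good], series[good])
    return spline(np.clip(nodes, times[good][0], times[good][-1]))


def rom_per_trial(angles: dict[str, np.ndarray], trial_id: str | None = None) -> pd.DataFrame:
    """ROM = max - min joint angle over the whole trial, per joint."""
    rows = []
    for joint, series in angles.items():
        series = np.asarray(series, float)
        finite = series[~np.isnan(series)]
        if finite.size == 0:
            rows.append({"trial_id": trial_id, "joint": joint, "rom": np.nan, "reason": "all samples missing"})
        else:
            rows.append({"trial_id": trial_id, "joint": joint, "rom": float(np.ptp(finite))})
    return pd.DataFrame(rows)


def trial_joint_angles(trial, schema, side: str) -> dict[str, np.ndarray]:
    """Hip/knee/ankle sagittal angle series for one side of a trial.

    Hip uses the ipsilateral shoulder as the trunk reference, knee the
    hip-knee-ankle chain, ankle the knee-ankle-toe chain.
    """
    pre = "L" if side == "left" else "R"
    sho = schema.series(trial, pre + "SHO")
    hip = schema.series(trial, pre + "HIP")
    knee = schema.series(trial, pre + "KNEE")
    ank = schema.series(trial, pre + "ANK")
    toe = schema.series(trial, pre + "TOE")
    return {
        "hip": sagittal_angle(sho, hip, knee, "hip"),
        "knee": sagittal_angle(hip, knee, ank, "knee"),
        "ankle": sagittal_angle(knee, ank, toe, "ankle"),
    }


def stride_angle_curves(trial, schema, strides) -> pd.DataFrame:
    """Long table of 101-node angle curves: (side, stride, joint, node, angle)."""
    t = trial.marker_times()
    rows = []
    cache: dict[str, dict[str, np.ndarray]] = {}
    for k, st in enumerate(strides):
        if not st.valid:
            continue
        if st.side not in cache:
            cache[st.side] = trial_joint_angles(trial, schema, st.side)
        for joint, series in cache[st.side].items():
            curve = normalize_cycle(series, t, st)
            rows.append(
                {
                    "trial_id": trial.trial_id,
                    "participant_id": trial.participant_id,
                    "substrate_id": trial.substrate_id,
                    "side": st.side,
                    "stride_index": k,
                    "joint": joint,
                    **{f"node_{i}": curve[i] for i in range(N_NODES)},
                }
            )
    return pd.DataFrame(rows)
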