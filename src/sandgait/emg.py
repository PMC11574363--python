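"""Surface-EMG processing: high-pass filtering, rectification, per-participant
normalization (nEMG), stride cropping and per-stride integration (iEMG).

The chain is: second-order Butterworth high-pass at 12 Hz (applied
forward-backward by default, so zero-phase and 4th-order effective), full-wave
rectification, normalization of each muscle to the participant's maximum
rectified amplitude across all their trials, then a trapezoidal time integral
per stride.  No envelope smoothing is applied before integration; the 101-node
curves for plotting and SPM are bin means of the rectified signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt, sosfiltfilt

from .core_io import DataError
from .kinematics import N_NODES

DEFAULT_CUTOFF_HZ = 12.0


def filter_rectify(
    raw: np.ndarray,
    rate: float,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    zero_phase: bool = True,
) -> np.ndarray:
    """High-pass filter (2nd-order Butterworth) and full-wave rectify."""
    raw = np.asarray(raw, float)
    if rate <= 2 * cutoff_hz:
        raise DataError(f"rate {rate} Hz too low for a {cutoff_hz} Hz high-pass")
    settle = int(3 * rate / cutoff_hz)
    if len(raw) < settle:
        raise DataError(f"series too short ({len(raw)} < {settle} samples) to filter")
    sos = butter(2, cutoff_hz, btype="highpass", fs=rate, output="sos")
    filtered = sosfiltfilt(sos, raw) if zero_phase else sosfilt(sos, raw)
    return np.abs(filtered)


def normalize_participant(
    rectified: dict[str, np.ndarray],
) -> tuple[dict[str, np.ndarray], float]:
    """Normalize one muscle's rectified trials by the participant-wide maximum.

    ``rectified`` maps trial id -> rectified series (one muscle, all trials of
    one participant).  Returns the normalized series and the maximum used.
    """
    peak = max((float(np.max(v)) for v in rectified.values() if len(v)), default=0.0)
    if peak == 0.0:
        raise DataError("normalization undefined: channel is all-zero")
    return {k: v / peak for k, v in rectified.items()}, peak


def iemg_per_stride(nemg: np.ndarray, times: np.ndarray, stride, rate: float) -> float:
    """Trapezoidal integral of nEMG over the stride's time span (unit: 1*s)."""
    nemg = np.asarray(nemg, float)
    times = np.asarray(times, float)
    if stride.start < times[0] - 0.5 / rate or stride.end > times[-1] + 0.5 / rate:
        raise DataError("stride lies outside the EMG series")
    # integrate on the sample grid, with exact interpolated endpoints
    grid = times[(times > stride.start) & (times < stride.end)]
    tt = np.concatenate(([stride.start], grid, [stride.end]))
    vv = np.interp(tt, times, nemg)
    return float(np.trapezoid(vv, tt))


def nemg_cycle_curve(nemg: np.ndarray, times: np.ndarray, stride) -> np.ndarray:
    """101-node nEMG curve: mean of the rectified signal within each cycle bin."""
    rel = (times - stride.start) / (stride.end - stride.start)
    inside = (rel >= 0.0) & (rel <= 1.0)
    bins = np.clip((rel[inside] * N_NODES).astype(int), 0, N_NODES - 1)
    out = np.full(N_NODES, np.nan)
    sums = np.bincount(bins, weights=nemg[inside], minlength=N_NODES)
    counts = np.bincount(bins, minlength=N_NODES)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def process_participant_emg(
    trials: list,
    strides_by_trial: dict[str, list],
    *,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    zero_phase: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full EMG chain for all trials of one participant.

    Returns (iemg_table, nemg_curves): per-stride iEMG values and 101-node
    nEMG curves, one row per (trial, stride, muscle).
    """
    if not trials:
        return pd.DataFrame(), pd.DataFrame()
    muscles = sorted({m for tr in trials for m in tr.emg})
    iemg_rows, curve_rows = [], []
    for muscle in muscles:
        rect = {
            tr.trial_id: filter_rectify(tr.emg[muscle], tr.emg_rate, cutoff_hz, zero_phase)
            for tr in trials
            if muscle in tr.emg
        }
        normed, _peak = normalize_participant(rect)
        for tr in trials:
            if muscle not in tr.emg:
                continue
            nemg = normed[tr.trial_id]
            te = tr.emg_times()
            for k, st in enumerate(strides_by_trial.get(tr.trial_id, [])):
                if not st.valid or st.side != "left":
                    continue  # electrodes are on the left lower limb
                base = {
                    "trial_id": tr.trial_id,
                    "participant_id": tr.participant_id,
                    "substrate_id": tr.substrate_id,
                    "muscle": muscle,
                    "stride_index": k,
                }
                iemg_rows.append(
                    {**base, "iemg": iemg_per_stride(nemg, te, st, tr.emg_rate)}
                )
                curve = nemg_cycle_curve(nemg, te, st)
                curve_rows.append({**base, **{f"node_{i}": curve[i] for i in range(N_NODES)}})
    return pd.DataFrame(iemg_rows), pd.DataFrame(curve_rows)
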