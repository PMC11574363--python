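"""Coordinate-based gait-event detection and stride segmentation.

Heel-strike is the local maximum of the heel's fore-aft position relative to
the sacrum (signed by travel direction); toe-off is the local minimum of the
hallux's relative position.  The relative signal is low-pass filtered
(zero-phase) before peak picking, and the minimum peak separation defaults to
half the signal's dominant period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt

from .core_io import DataError, MarkerSchema, TrialRecording, fill_gaps


@dataclass
class EventParams:
    lowpass_hz: float = 10.0  # zero-phase (4th-order effective) cutoff
    min_separation: float | None = None  # s; None -> 0.5 x dominant period
    max_gap_frames: int = 10


@dataclass
class GaitEventSet:
    """Per-side heel-strike and toe-off times (seconds, shared clock)."""

    heel_strikes: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]

    def validate(self) -> None:
        for side in self.heel_strikes:
            hs = self.heel_strikes[side]
            to = self.toe_offs.get(side, np.array([]))
            if not np.all(np.diff(hs) > 0) or not np.all(np.diff(to) > 0):
                raise DataError(f"{side}: event times must be strictly increasing")
            # between consecutive heel-strikes at most/exactly one toe-off is
            # checked at stride construction, where violations mark strides
            # invalid instead of failing the trial


@dataclass
class Stride:
    side: str
    start: float  # heel-strike, s
    end: float  # next ipsilateral heel-strike, s
    toe_off: float | None
    valid: bool = True
    reason: str = ""

    @property
    def duration(self) -> float:
        return self.end - self.start


def _dominant_period(x: np.ndarray, rate: float) -> float:
    """Period of the strongest non-DC Fourier component."""
    x = x - np.mean(x)
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), 1.0 / rate)
    if len(spec) < 2:
        raise DataError("signal too short to estimate a dominant period")
    k = 1 + int(np.argmax(spec[1:]))
    if freqs[k] <= 0:
        raise DataError("could not estimate dominant frequency")
    return 1.0 / freqs[k]


def _lowpass(x: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    if cutoff <= 0 or cutoff >= rate / 2:
        return x
    sos = butter(2, cutoff, btype="lowpass", fs=rate, output="sos")
    return sosfiltfilt(sos, x)


def _pick(signal: np.ndarray, t: np.ndarray, rate: float, min_sep: float | None) -> np.ndarray:
    if min_sep is None:
        min_sep = 0.5 * _dominant_period(signal, rate)
    distance = max(int(round(min_sep * rate)), 1)
    idx, props = find_peaks(signal, distance=distance, plateau_size=1)
    out = np.empty(len(idx), float)
    dt = 1.0 / rate
    left, right = props["left_edges"], props["right_edges"]
    for k, i in enumerate(idx):
        if left[k] != right[k]:
            # flat maximum: its centre is the best sub-frame estimate
            out[k] = 0.5 * (t[left[k]] + t[right[k]])
            continue
        if 0 < i < len(signal) - 1:
            # parabolic interpolation through the peak and its neighbours
            denom = signal[i - 1] - 2.0 * signal[i] + signal[i + 1]
            if denom < 0:
                delta = 0.5 * (signal[i - 1] - signal[i + 1]) / denom
                out[k] = t[i] + float(np.clip(delta, -0.5, 0.5)) * dt
                continue
        out[k] = t[i]
    return out


def detect_events(
    trial: TrialRecording,
    schema: MarkerSchema,
    params: EventParams | None = None,
) -> GaitEventSet:
    """Detect heel-strikes and toe-offs from foot positions relative to the pelvis."""
    params = params or EventParams()
    if trial.duration < 2.0:
        raise DataError("need at least 2 s of marker data for event detection")
    t = trial.marker_times()
    s = float(trial.travel_direction)
    sacr_x = fill_gaps(schema.series(trial, "SACR"), params.max_gap_frames)[0][:, 0]
    heel_strikes: dict[str, np.ndarray] = {}
    toe_offs: dict[str, np.ndarray] = {}
    for side, pre in (("left", "L"), ("right", "R")):
        heel_x = fill_gaps(schema.series(trial, pre + "HEE"), params.max_gap_frames)[0][:, 0]
        hall_x = fill_gaps(schema.series(trial, pre + "HALL"), params.max_gap_frames)[0][:, 0]
        rel_heel = _lowpass(s * (heel_x - sacr_x), trial.marker_rate, params.lowpass_hz)
        rel_hall = _lowpass(s * (hall_x - sacr_x), trial.marker_rate, params.lowpass_hz)
        hs = _pick(rel_heel, t, trial.marker_rate, params.min_separation)
        to = _pick(-rel_hall, t, trial.marker_rate, params.min_separation)
        if len(hs) < 2:
            raise DataError(f"fewer than 2 heel-strikes detected on {side} side")
        # discard partial cycles: toe-offs outside the heel-strike span
        to = to[(to > hs[0]) & (to < hs[-1])]
        heel_strikes[side] = hs
        toe_offs[side] = to
    out = GaitEventSet(heel_strikes, toe_offs)
    out.validate()
    return out


def build_strides(events: GaitEventSet, trial: TrialRecording, max_gap_frames: int = 10) -> list[Stride]:
    """One stride per consecutive ipsilateral heel-strike pair.

    A stride is marked invalid (with a reason) when it lacks exactly one
    interior toe-off or when a long marker gap overlaps it.
    """
    # locate long gaps once, over all markers
    gap_spans: list[tuple[float, float]] = []
    t = trial.marker_times()
    for xyz in trial.markers.values():
        for start, stop in fill_gaps(xyz, max_gap_frames)[1]:
            gap_spans.append((t[start], t[min(stop, len(t) - 1)]))
    strides: list[Stride] = []
    for side, hs in events.heel_strikes.items():
        to = np.asarray(events.toe_offs.get(side, []))
        for a, b in zip(hs[:-1], hs[1:]):
            inside = to[(to > a) & (to < b)]
            if len(inside) != 1:
                strides.append(
                    Stride(side, a, b, None, valid=False, reason=f"{len(inside)} toe-offs in stride")
                )
                continue
            stride = Stride(side, a, b, float(inside[0]))
            for g0, g1 in gap_spans:
                if g0 < b and g1 > a:
                    stride.valid = False
                    stride.reason = "long marker gap overlaps stride"
                    break
            strides.append(stride)
    return strides


def events_table(events: GaitEventSet, trial: TrialRecording) -> pd.DataFrame:
    """Exportable long table of events (trial, side, event_type, time, frame)."""
    rows = []
    for side in events.heel_strikes:
        for kind, times in (("heel_strike", events.heel_strikes[side]), ("toe_off", events.toe_offs[side])):
            for tt in times:
                rows.append(
                    {
                        "trial_id": trial.trial_id,
                        "side": side,
                        "event_type": kind,
                        "time_s": tt,
                        "frame": int(trial.time_to_frame(tt)),
                    }
                )
    return pd.DataFrame(rows)


def qc_report(
    events: GaitEventSet, mad_threshold: float = 3.0, min_scale: float = 0.01
) -> pd.DataFrame:
    """Flag cycle-time outliers (> mad_threshold robust deviations) per side.

    ``min_scale`` (s) floors the robust scale so that sub-centisecond jitter
    in an otherwise metronomic gait is never flagged.
    """
    rows = []
    for side, hs in events.heel_strikes.items():
        cycles = np.diff(hs)
        med = np.median(cycles) if len(cycles) else np.nan
        mad = np.median(np.abs(cycles - med)) if len(cycles) else np.nan
        for k, c in enumerate(cycles):
            scale = max(1.4826 * mad, min_scale) if np.isfinite(mad) else np.nan
            flagged = bool(np.isfinite(scale) and abs(c - med) / scale > mad_threshold)
            rows.append(
                {"side": side, "stride_index": k, "cycle_time": c, "outlier": flagged}
            )
    return pd.DataFrame(rows)
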