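"""Per-stride spatiotemporal parameters, foot sinkage and gait-variability CV.

Definitions (marker-based, config-overridable where the literature varies):

* cycle/stance/swing times from the heel-strike / toe-off events;
* speed = mean signed fore-aft sacrum velocity over the stride;
* stride length = ipsilateral heel fore-aft displacement between consecutive
  heel-strikes;
* stride width = mean absolute mediolateral heel separation at the stride's
  two contralateral heel-strike times;
* double support = total time within the stride with both feet in stance;
* sinkage depth (cm) = substrate surface height minus the lowest heel or
  hallux marker height within the stride (negative values are reported
  as-is and QC-flagged, never clipped).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import DataError, MarkerSchema, TrialRecording, fill_gaps
from .events import GaitEventSet, Stride

_OTHER = {"left": "right", "right": "left"}
_PRE = {"left": "L", "right": "R"}


def _stance_intervals(events: GaitEventSet, side: str) -> list[tuple[float, float]]:
    """(heel-strike, toe-off) contact intervals for one side.

    Each heel-strike is paired with the first subsequent toe-off; the final
    contact (no toe-off observed) is left open-ended to the last event time.
    """
    hs = np.asarray(events.heel_strikes.get(side, []))
    to = np.asarray(events.toe_offs.get(side, []))
    out = []
    for h in hs:
        nxt = to[to > h]
        out.append((h, float(nxt[0]) if len(nxt) else np.inf))
    return out


def _overlap(a0: float, a1: float, intervals) -> float:
    tot = 0.0
    for b0, b1 in intervals:
        tot += max(0.0, min(a1, b1) - max(a0, b0))
    return tot


def compute_spatiotemporal(
    trial: TrialRecording,
    strides: list[Stride],
    events: GaitEventSet,
    schema: MarkerSchema | None = None,
) -> pd.DataFrame:
    """One row of spatiotemporal parameters per valid stride."""

    def series(role: str):
        try:
            if schema is not None:
                return schema.series(trial, role)
            return trial.markers.get(role)
        except Exception:
            return None

    schema_like = {
        role: series(role) for role in ("LHEE", "RHEE") if series(role) is not None
    }
    t = trial.marker_times()
    sacr_x = series("SACR")
    rows = []
    sgn = float(trial.travel_direction)
    for k, st in enumerate(strides):
        if not st.valid or st.toe_off is None:
            continue
        cycle = st.end - st.start
        stance = st.toe_off - st.start
        swing = st.end - st.toe_off
        row: dict = {
            "participant_id": trial.participant_id,
            "trial_id": trial.trial_id,
            "substrate_id": trial.substrate_id,
            "side": st.side,
            "stride_index": k,
            "cycle_time": cycle,
            "stance_time": stance,
            "swing_time": swing,
            "duty_factor": stance / cycle,
        }
        i0, i1 = trial.time_to_frame(st.start), trial.time_to_frame(st.end)
        if sacr_x is not None and i1 > i0:
            row["speed"] = sgn * (sacr_x[i1, 0] - sacr_x[i0, 0]) / (t[i1] - t[i0])
        else:
            row["speed"] = np.nan
        pre = _PRE[st.side]
        heel = schema_like.get(pre + "HEE")
        if heel is not None:
            row["stride_length"] = abs(heel[i1, 0] - heel[i0, 0])
        else:
            row["stride_length"] = np.nan
        # contralateral-dependent quantities
        other = _OTHER[st.side]
        o_hs = np.asarray(events.heel_strikes.get(other, []))
        inside = o_hs[(o_hs > st.start) & (o_hs < st.end)]
        o_heel = schema_like.get(_PRE[other] + "HEE")
        if len(inside) and heel is not None and o_heel is not None:
            widths = []
            for oh in inside:
                j = trial.time_to_frame(oh)
                widths.append(abs(heel[j, 1] - o_heel[j, 1]))
            row["stride_width"] = float(np.mean(widths))
        else:
            row["stride_width"] = np.nan
            row["stride_width_reason"] = "no contralateral heel-strike in stride"
        o_stance = _stance_intervals(events, other)
        if o_stance:
            # both feet are down only while this side is in stance, so the
            # stride's two double-support phases are the overlaps of
            # (heel-strike, toe-off) with the contralateral contact intervals
            row["double_support_time"] = _overlap(st.start, st.toe_off, o_stance)
        else:
            row["double_support_time"] = np.nan
            row["double_support_reason"] = "contralateral events missing"
        rows.append(row)
    return pd.DataFrame(rows)


def compute_sinkage(
    trial: TrialRecording,
    strides: list[Stride],
    schema: MarkerSchema,
    max_gap_frames: int = 10,
) -> pd.DataFrame:
    """Per-stride heel and hallux sinkage depths (cm), per side.

    Depth = substrate surface height minus the stride's lowest marker height.
    A marker gap spanning the stride minimum yields a missing value with a
    reason; negative depths (marker minimum above the surface) are returned
    as-is with ``flagged=True``.
    """
    surface = trial.substrate_surface_z
    t = trial.marker_times()
    rows = []
    for k, st in enumerate(strides):
        if not st.valid:
            continue
        pre = _PRE[st.side]
        row: dict = {
            "trial_id": trial.trial_id,
            "participant_id": trial.participant_id,
            "substrate_id": trial.substrate_id,
            "side": st.side,
            "stride_index": k,
        }
        i0, i1 = trial.time_to_frame(st.start), trial.time_to_frame(st.end)
        for name, role in (("heel_sink_depth", pre + "HEE"), ("hallux_sink_depth", pre + "HALL")):
            xyz, gaps = fill_gaps(schema.series(trial, role), max_gap_frames)
            in_gap = any(g0 <= i1 and g1 >= i0 for g0, g1 in gaps)
            if in_gap:
                row[name] = np.nan
                row[name + "_reason"] = "marker gap spans stride"
                continue
            zmin = float(np.min(xyz[i0 : i1 + 1, 2]))
            depth_cm = (surface - zmin) * 100.0
            row[name] = depth_cm
            if depth_cm < 0:
                row[name + "_flagged"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def coefficient_of_variation(values: pd.Series, grouping: pd.Series) -> pd.DataFrame:
    """CV (sample sd / mean) of pooled strides per substrate group.

    Returns one row per group with mean, sd and cv; raises on zero means.
    """
    df = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(grouping)})
    df = df.dropna(subset=["value"])
    out = []
    for g, grp in df.groupby("group", sort=False):
        if len(grp) < 2:
            raise DataError(f"group {g!r}: need >= 2 values for a CV")
        mean = grp["value"].mean()
        if mean == 0:
            raise DataError(f"group {g!r}: CV undefined for zero mean")
        sd = grp["value"].std(ddof=1)
        out.append({"group": g, "n": len(grp), "mean": mean, "sd": sd, "cv": sd / mean})
    return pd.DataFrame(out)


def cv_relative_change(cv_table: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Percentage change of each group's CV relative to a reference group."""
    ref = cv_table.loc[cv_table["group"] == reference, "cv"]
    if ref.empty:
        raise DataError(f"reference group {reference!r} not in CV table")
    ref_cv = float(ref.iloc[0])
    out = cv_table.copy()
    out["cv_change_pct"] = 100.0 * (out["cv"] - ref_cv) / ref_cv
    return out
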