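"""Orchestration: simulate -> process -> stats as reproducible, configured runs."""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    AnthropometricTable,
    MarkerSchema,
    TrialRecording,
    default_anthropometric_table,
    write_stride_table,
)
from .emg import process_participant_emg
from .energetics import stride_exchange
from .events import EventParams, build_strides, detect_events, qc_report
from .kinematics import N_NODES, rom_per_trial, stride_angle_curves, trial_joint_angles
from .spatiotemporal import compute_sinkage, compute_spatiotemporal
from .stats import (
    LMMSpec,
    anova_tukey,
    fit_lmm,
    spearman_correlogram,
    spm_paired_test,
)
from .synthetic import GaitSimConfig, simulate_study, synthetic_schema

log = logging.getLogger("sandgait")

#: variables summarised per stride / per trial
SPATIOTEMPORAL_VARS = [
    "speed",
    "stride_length",
    "stride_width",
    "cycle_time",
    "stance_time",
    "swing_time",
    "double_support_time",
    "duty_factor",
]


@dataclass
class ProcessResult:
    stride_table: pd.DataFrame
    exchange: pd.DataFrame
    rom: pd.DataFrame
    angle_curves: pd.DataFrame
    iemg: pd.DataFrame
    nemg_curves: pd.DataFrame
    qc: pd.DataFrame
    errors: list[dict] = field(default_factory=list)


def run_process(
    trials: list[TrialRecording],
    schema: MarkerSchema | None = None,
    table: AnthropometricTable | None = None,
    event_params: EventParams | None = None,
    com_role: str | None = "COM",
) -> ProcessResult:
    """Run the full kinematic/EMG processing chain over a list of trials.

    A failing trial is recorded in ``errors`` and skipped; the remaining
    trials are processed.
    """
    schema = schema or synthetic_schema()
    table = table or default_anthropometric_table()
    stride_rows, exch_rows, rom_rows, curve_rows, qc_rows = [], [], [], [], []
    strides_by_trial: dict[str, list] = {}
    errors: list[dict] = []
    for trial in trials:
        try:
            events = detect_events(trial, schema, event_params)
            strides = build_strides(events, trial)
            strides_by_trial[trial.trial_id] = strides
            st = compute_spatiotemporal(trial, strides, events, schema)
            sk = compute_sinkage(trial, strides, schema)
            if not st.empty:
                merged = st.merge(
                    sk.drop(columns=["participant_id", "substrate_id"], errors="ignore"),
                    on=["trial_id", "side", "stride_index"],
                    how="left",
                )
                stride_rows.append(merged)
            exch_rows.extend(
                stride_exchange(trial, schema, table, strides, com_role=com_role)
            )
            angles = {
                joint: np.concatenate(
                    [trial_joint_angles(trial, schema, side)[joint] for side in ("left", "right")]
                )
                for joint in ("hip", "knee", "ankle")
            }
            rom = rom_per_trial(angles, trial.trial_id)
            rom["participant_id"] = trial.participant_id
            rom["substrate_id"] = trial.substrate_id
            rom_rows.append(rom)
            curve_rows.append(stride_angle_curves(trial, schema, strides))
            qc = qc_report(events)
            qc["trial_id"] = trial.trial_id
            qc_rows.append(qc)
        except Exception as exc:  # error isolation: keep processing other trials
            log.warning("trial %s failed: %s", trial.trial_id, exc)
            errors.append({"trial_id": trial.trial_id, "error": str(exc)})
    # EMG normalization is per participant, across all of their trials
    iemg_tabs, nemg_tabs = [], []
    by_participant: dict[str, list[TrialRecording]] = {}
    for trial in trials:
        if trial.emg and trial.trial_id in strides_by_trial:
            by_participant.setdefault(trial.participant_id, []).append(trial)
    for pid, ptrials in by_participant.items():
        try:
            iemg, nemg = process_participant_emg(ptrials, strides_by_trial)
            iemg_tabs.append(iemg)
            nemg_tabs.append(nemg)
        except Exception as exc:
            log.warning("EMG for participant %s failed: %s", pid, exc)
            errors.append({"trial_id": f"participant:{pid}", "error": str(exc)})

    def cat(frames):
        frames = [f for f in frames if f is not None and not f.empty]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    return ProcessResult(
        stride_table=cat(stride_rows),
        exchange=pd.DataFrame(exch_rows),
        rom=cat(rom_rows),
        angle_curves=cat(curve_rows),
        iemg=cat(iemg_tabs),
        nemg_curves=cat(nemg_tabs),
        qc=cat(qc_rows),
        errors=errors,
    )


# ---------------------------------------------------------------------------
# statistics stage


def participant_mean_curves(curves: pd.DataFrame, substrate: str, joint: str) -> pd.DataFrame:
    """Participant-mean 101-node curves for one substrate and joint."""
    node_cols = [f"node_{i}" for i in range(N_NODES)]
    sel = curves[(curves.substrate_id == substrate) & (curves.joint == joint)]
    return sel.groupby("participant_id")[node_cols].mean()


@dataclass
class StatsResult:
    lmm: dict
    spm: dict
    anova: dict
    correlograms: dict
    depth_correlograms: dict


def trial_means(result: ProcessResult) -> pd.DataFrame:
    """One row per trial: means of stride variables, R, ROMs and iEMG."""
    st = result.stride_table
    keys = ["participant_id", "trial_id", "substrate_id"]
    num_cols = [c for c in SPATIOTEMPORAL_VARS + ["heel_sink_depth", "hallux_sink_depth"] if c in st.columns]
    tm = st.groupby(keys, as_index=False)[num_cols].mean()
    if not result.exchange.empty:
        r = result.exchange.groupby("trial_id", as_index=False)[["r_pct", "ra", "co_pct"]].mean()
        tm = tm.merge(r, on="trial_id", how="left")
    if not result.rom.empty:
        rom = result.rom.pivot_table(index="trial_id", columns="joint", values="rom").add_suffix("_rom")
        tm = tm.merge(rom, on="trial_id", how="left")
    if not result.iemg.empty:
        iemg = result.iemg.pivot_table(index="trial_id", columns="muscle", values="iemg").add_prefix("iemg_")
        tm = tm.merge(iemg, on="trial_id", how="left")
    return tm


def run_stats(
    result: ProcessResult,
    alpha: float = 0.05,
    lmm_variables: list[str] | None = None,
    seed: int = 0,
) -> StatsResult:
    """The statistical battery over processed outputs.

    LMMs per variable; paired 1D-SPM per joint per substrate pair with
    Bonferroni across the pairs; ANOVA + Tukey on sinkage across the sand
    substrates; Spearman correlograms of trial means per substrate and
    combined, plus sinkage-vs-metric correlograms.
    """
    st = result.stride_table
    substrates = list(dict.fromkeys(st.substrate_id)) if not st.empty else []
    lmm_variables = lmm_variables or [v for v in SPATIOTEMPORAL_VARS if v in st.columns]
    lmm_out: dict = {}
    for var in lmm_variables:
        data = st.dropna(subset=[var])
        if data.empty or data["participant_id"].nunique() < 2:
            lmm_out[var] = {"skipped": "insufficient data"}
            continue
        covs = ["C(substrate_id)"]
        if "sex" in data.columns:
            covs.append("C(sex)")
        if "speed" in data.columns and var != "speed":
            covs.append("speed")
        try:
            fit = fit_lmm(LMMSpec(response=var, fixed=covs), data)
            lmm_out[var] = {
                "estimates": fit.estimates.to_dict(),
                "se": fit.se.to_dict(),
                "pvalues": fit.pvalues.to_dict(),
                "var_participant": fit.var_participant,
                "var_residual": fit.var_residual,
                "singular": fit.singular,
            }
        except Exception as exc:
            lmm_out[var] = {"skipped": str(exc)}

    # SPM per joint per substrate pair (participant-mean curves)
    spm_out: dict = {}
    pairs = list(itertools.combinations(substrates, 2))
    curves = result.angle_curves
    if not curves.empty:
        for joint in sorted(curves.joint.unique()):
            for a, b in pairs:
                ca = participant_mean_curves(curves, a, joint)
                cb = participant_mean_curves(curves, b, joint)
                common = ca.index.intersection(cb.index)
                if len(common) < 3:
                    continue
                res = spm_paired_test(
                    ca.loc[common].to_numpy(),
                    cb.loc[common].to_numpy(),
                    comparison=f"{joint}:{a}-vs-{b}",
                    alpha=alpha,
                    n_comparisons=len(pairs),
                )
                spm_out[res.comparison] = {
                    "df": res.df,
                    "fwhm": res.fwhm,
                    "t_critical": res.t_critical,
                    "alpha_effective": res.alpha_effective,
                    "clusters": res.clusters,
                    "t_field": res.t_field.tolist(),
                }

    # ANOVA + Tukey on sinkage across deformable substrates
    anova_out: dict = {}
    for var in ("heel_sink_depth", "hallux_sink_depth"):
        if var not in st.columns:
            continue
        groups = {
            s: st.loc[(st.substrate_id == s), var].dropna().to_numpy()
            for s in substrates
            if s != "hard_floor"
        }
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(groups) >= 2:
            res = anova_tukey(groups)
            anova_out[var] = {
                "f": res.f,
                "p": res.p,
                "tukey": [
                    {"pair": f"{t.group_a}|{t.group_b}", "diff": t.diff, "p": t.p}
                    for t in res.tukey
                ],
            }

    # correlograms on trial means
    tm = trial_means(result)
    corr_vars = [
        c
        for c in tm.columns
        if c not in ("participant_id", "trial_id", "substrate_id", "heel_sink_depth", "hallux_sink_depth")
    ]
    corr_out: dict = {}
    for scope in substrates + ["combined"]:
        sel = tm if scope == "combined" else tm[tm.substrate_id == scope]
        sub = sel[corr_vars].dropna(axis=1, how="all")
        if sub.shape[0] >= 5 and sub.shape[1] >= 2:
            try:
                cm = spearman_correlogram(sub)
                corr_out[scope] = {
                    "variables": cm.variables,
                    "order": [cm.variables[i] for i in cm.order],
                    "rho": cm.rho.tolist(),
                    "p": cm.p.tolist(),
                }
            except Exception as exc:
                corr_out[scope] = {"skipped": str(exc)}

    depth_out: dict = {}
    depth_vars = [c for c in ("heel_sink_depth", "hallux_sink_depth") if c in tm.columns]
    if depth_vars:
        sand = tm[tm.substrate_id != "hard_floor"]
        for scope in [s for s in substrates if s != "hard_floor"] + ["combined"]:
            sel = sand if scope == "combined" else sand[sand.substrate_id == scope]
            sub = sel[depth_vars + corr_vars].dropna(axis=1, how="all")
            if sub.shape[0] >= 5 and sub.shape[1] >= 2:
                try:
                    cm = spearman_correlogram(sub)
                    depth_out[scope] = {
                        "variables": cm.variables,
                        "order": [cm.variables[i] for i in cm.order],
                        "rho": cm.rho.tolist(),
                        "p": cm.p.tolist(),
                    }
                except Exception as exc:
                    depth_out[scope] = {"skipped": str(exc)}

    return StatsResult(lmm_out, spm_out, anova_out, corr_out, depth_out)


# ---------------------------------------------------------------------------
# manifests and file output


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_process_outputs(result: ProcessResult, outdir: Path, cfg: dict) -> Path:
    """Write every stage output plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    outputs = {}

    def emit(name: str, df: pd.DataFrame):
        path = outdir / f"{name}.csv"
        if name == "stride_table":
            write_stride_table(df, path)
        else:
            df.to_csv(path, index=False)
        outputs[name] = path.name

    for name in ("stride_table", "exchange", "rom", "angle_curves", "iemg", "nemg_curves", "qc"):
        emit(name, getattr(result, name))
    manifest = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "config": cfg,
        "outputs": outputs,
        "errors": result.errors,
        "elapsed_s": round(time.time() - started, 3),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    return mpath


def write_stats_outputs(stats: StatsResult, outdir: Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "stats.json"
    path.write_text(
        json.dumps(
            {
                "lmm": stats.lmm,
                "spm": stats.spm,
                "anova": stats.anova,
                "correlograms": stats.correlograms,
                "depth_correlograms": stats.depth_correlograms,
            },
            indent=2,
            default=str,
        )
    )
    return path


def simulate_and_process(cfg: GaitSimConfig) -> tuple[ProcessResult, list]:
    """Convenience: run the generator and the processing chain in one call."""
    trials, truths = simulate_study(cfg)
    result = run_process(trials)
    # carry participant sex into the stride table for the mixed models
    sex_map = {t.participant_id: t.sex for t in trials}
    if not result.stride_table.empty:
        result.stride_table["sex"] = result.stride_table.participant_id.map(sex_map)
    return result, truths
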