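"""Whole-body CoM, mechanical energies and pendular exchange statistics.

During walking the centre of mass behaves like an inverted pendulum:
gravitational potential energy E_pot = m g z and kinetic energy
E_kin = 1/2 m |v|^2 oscillate out of phase, and part of the mechanical
energy is conserved by their exchange.  Per stride this module computes,
from positive increments over consecutive samples,

    W_v   = sum of positive increments of E_pot
    W_f   = sum of positive increments of E_kin
    W_ext = sum of positive increments of E_tot = E_pot + E_kin
    R     = 100 (W_v + W_f - W_ext) / (W_v + W_f)      (percent recovery)
    RA    = ptp(E_pot) / ptp(E_kin)                     (relative amplitude)
    CO    = 100 x fraction of samples whose E_pot and E_kin increments share
            a sign, among samples where both increments are non-zero
            (congruity percent)

R = 100 exactly when E_tot is constant (ideal pendulum); R = 0 and CO = 100
when the two energies move perfectly in phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core_io import (
    AnthropometricTable,
    DataError,
    MarkerSchema,
    SchemaError,
    TrialRecording,
)

G = 9.81  # m s^-2
_ZERO_INCREMENT = 1e-12  # J; increments below this count as "not moving"


@dataclass
class EnergySeries:
    """Per-stride E_pot / E_kin / E_tot traces (J) on a common time base."""

    time: np.ndarray
    e_pot: np.ndarray
    e_kin: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.e_pot) == len(self.e_kin)):
            raise DataError("energy series must have equal lengths")

    @property
    def e_tot(self) -> np.ndarray:
        return self.e_pot + self.e_kin


@dataclass
class ExchangeMetrics:
    r: float  # %
    ra: float  # unitless
    co: float  # %


def body_com(
    trial: TrialRecording,
    schema: MarkerSchema,
    table: AnthropometricTable,
    *,
    com_role: str | None = None,
) -> np.ndarray:
    """Whole-body CoM (n, 3) from the segmental anthropometric model.

    Each segment CoM is ``proximal + f * (distal - proximal)``; the body CoM
    is the mass-fraction weighted sum.  If ``com_role`` names a precomputed
    CoM channel present in the trial, that channel is returned directly
    (direct-CoM bypass).
    """
    if com_role is not None and schema.has(trial, com_role):
        return schema.series(trial, com_role)
    missing = []
    total = np.zeros((trial.n_frames, 3))
    for seg in table.segments:
        try:
            prox = schema.series(trial, seg.proximal)
            dist = schema.series(trial, seg.distal)
        except SchemaError:
            missing.append(seg.name)
            continue
        total += seg.mass_fraction * (prox + seg.com_fraction * (dist - prox))
    if missing:
        raise SchemaError(f"segments with missing endpoint roles: {missing}")
    return total


def energies(
    com: np.ndarray,
    body_mass: float,
    rate: float,
    *,
    lowpass_hz: float | None = 6.0,
    components: str = "xyz",
) -> EnergySeries:
    """E_pot/E_kin/E_tot of the CoM over a (whole-trial or stride) window.

    Velocity comes from central differences (one-sided at the ends) on the
    optionally low-pass filtered CoM; ``components`` may restrict E_kin to
    e.g. the sagittal plane ("xz").
    """
    com = np.asarray(com, float)
    if com.ndim != 2 or com.shape[1] != 3 or len(com) < 5:
        raise DataError("com must be an (n >= 5, 3) array")
    if rate <= 0:
        raise DataError("rate must be positive")
    if lowpass_hz is not None and 0 < lowpass_hz < rate / 2:
        sos = butter(2, lowpass_hz, btype="lowpass", fs=rate, output="sos")
        com = sosfiltfilt(sos, com, axis=0)
    vel = np.gradient(com, 1.0 / rate, axis=0)
    idx = ["xyz".index(c) for c in components]
    e_kin = 0.5 * body_mass * np.sum(vel[:, idx] ** 2, axis=1)
    e_pot = body_mass * G * com[:, 2]
    time = np.arange(len(com)) / rate
    return EnergySeries(time=time, e_pot=e_pot, e_kin=e_kin)


def crop(es: EnergySeries, i0: int, i1: int) -> EnergySeries:
    return EnergySeries(es.time[i0 : i1 + 1], es.e_pot[i0 : i1 + 1], es.e_kin[i0 : i1 + 1])


def exchange_metrics(es: EnergySeries) -> ExchangeMetrics:
    """Pendular exchange statistics R / RA / CO for one stride (vectorised)."""
    dp = np.diff(es.e_pot)
    dk = np.diff(es.e_kin)
    dtot = dp + dk
    w_v = dp[dp > 0].sum()
    w_f = dk[dk > 0].sum()
    w_ext = dtot[dtot > 0].sum()
    if w_v + w_f == 0:
        raise DataError("R undefined: both energy series are constant")
    if np.ptp(es.e_kin) == 0:
        raise DataError("RA undefined: E_kin is constant")
    r = 100.0 * (w_v + w_f - w_ext) / (w_v + w_f)
    ra = float(np.ptp(es.e_pot) / np.ptp(es.e_kin))
    moving = (np.abs(dp) > _ZERO_INCREMENT) & (np.abs(dk) > _ZERO_INCREMENT)
    same = moving & (dp * dk > 0)
    co = 100.0 * same.sum() / moving.sum() if moving.any() else float("nan")
    return ExchangeMetrics(r=float(r), ra=ra, co=float(co))


def stride_exchange(
    trial: TrialRecording,
    schema: MarkerSchema,
    table: AnthropometricTable,
    strides,
    *,
    com_role: str | None = "COM",
    lowpass_hz: float | None = 6.0,
    components: str = "xyz",
):
    """Per-stride ExchangeMetrics for a trial (rows as dicts, ready for a table)."""
    com = body_com(trial, schema, table, com_role=com_role)
    es = energies(com, trial.body_mass, trial.marker_rate, lowpass_hz=lowpass_hz, components=components)
    rows = []
    for k, st in enumerate(strides):
        if not getattr(st, "valid", True):
            continue
        i0, i1 = trial.time_to_frame(st.start), trial.time_to_frame(st.end)
        metrics = exchange_metrics(crop(es, int(i0), int(i1)))
        rows.append(
            {
                "trial_id": trial.trial_id,
                "participant_id": trial.participant_id,
                "substrate_id": trial.substrate_id,
                "side": st.side,
                "stride_index": k,
                "r_pct": metrics.r,
                "ra": metrics.ra,
                "co_pct": metrics.co,
            }
        )
    return rows
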