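"""Synthetic longitudinal iNPH cohort at the measurement level.

Emulates a shunt-surgery cohort: truncated-normal baselines for five 2D
indices and the seven intracranial compartments (with a shared head-size
factor coupling the volumes), a three-phase follow-up schedule with partial
attendance, per-phase multiplicative effects encoding the staged CSF
redistribution after shunting, lognormal per-scan trajectory noise, and
outcome / Alzheimer-comorbidity strata. Every derived quantity (totals,
volume ratios, CVR) is recomputed from simulated components, so the
volumetric conservation identities hold in every record by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .longitudinal_stats import assign_phase
from .volume_model import COMPARTMENT_ROLES, ParameterError

__all__ = [
    "DRAWN_INDICES",
    "DERIVED_MEASURES",
    "CohortParams",
    "ScanRecord",
    "attendance_mask",
    "simulate_cohort",
]

#: Indices drawn directly at baseline (CVR is always derived from volumes).
DRAWN_INDICES: tuple[str, ...] = (
    "evans",
    "z_evans",
    "callosal_angle",
    "bvr_ac",
    "bvr_pc",
)

#: Quantities recomputed from components in every record.
DERIVED_MEASURES: tuple[str, ...] = (
    "cvr",
    "total_ventricles",
    "total_sas",
    "total_csf",
    "tiv",
)

SIMULATED_MEASURES: tuple[str, ...] = DRAWN_INDICES + COMPARTMENT_ROLES

PHASES: tuple[str, ...] = ("early", "mid", "late")


def _default_baseline_mean() -> dict[str, float]:
    return {
        "evans": 0.32,
        "z_evans": 0.44,
        "callosal_angle": 63.5,
        "bvr_ac": 0.72,
        "bvr_pc": 0.89,
        "brain_parenchyma": 1107.0,
        "lateral_ventricles": 155.0,
        "third_ventricle": 5.2,
        "fourth_ventricle": 3.6,
        "convexity_sas": 72.3,
        "sylvian_basal": 130.2,
        "posterior_fossa_sas": 70.6,
    }


def _default_baseline_sd() -> dict[str, float]:
    # index SDs as reported; volume SDs expressed via volume_cv + size_sd
    return {
        "evans": 0.06,
        "z_evans": 0.06,
        "callosal_angle": 18.5,
        "bvr_ac": 0.17,
        "bvr_pc": 0.23,
    }


def _default_volume_cv() -> dict[str, float]:
    return {
        "brain_parenchyma": 0.05,
        "lateral_ventricles": 0.35,
        "third_ventricle": 0.35,
        "fourth_ventricle": 0.35,
        "convexity_sas": 0.30,
        "sylvian_basal": 0.30,
        "posterior_fossa_sas": 0.30,
    }


def _default_phase_effects() -> dict[str, tuple[float, float, float]]:
    """Per-phase multipliers: ratios of published phase means to baseline."""
    pre = _default_baseline_mean()
    means = {
        "evans": (0.31, 0.33, 0.34),
        "z_evans": (0.42, 0.41, 0.41),
        "callosal_angle": (72.0, 83.5, 84.5),
        "bvr_ac": (0.79, 0.83, 0.84),
        "bvr_pc": (1.10, 1.07, 1.09),
        "brain_parenchyma": (1131.0, 1116.0, 1099.0),
        "lateral_ventricles": (136.3, 134.1, 135.8),
        "third_ventricle": (4.8, 4.3, 4.1),
        "fourth_ventricle": (3.3, 2.9, 2.5),
        "convexity_sas": (80.2, 88.1, 92.7),
        "sylvian_basal": (120.7, 116.1, 100.1),
        "posterior_fossa_sas": (68.9, 63.5, 56.5),
    }
    return {
        m: tuple(v / pre[m] for v in phase_means) for m, phase_means in means.items()
    }


def _default_traj_sd() -> dict[str, float]:
    return {m: 0.06 for m in SIMULATED_MEASURES}


@dataclass(frozen=True)
class CohortParams:
    """Generator parameters; the defaults encode the study conditions
    (54 patients, full early attendance then 28/54 and 16/54, outcome split
    43:11:0, 19/54 Alzheimer comorbidity)."""

    n_patients: int = 54
    baseline_mean: Mapping[str, float] = field(default_factory=_default_baseline_mean)
    baseline_sd: Mapping[str, float] = field(default_factory=_default_baseline_sd)
    volume_cv: Mapping[str, float] = field(default_factory=_default_volume_cv)
    size_sd: float = 0.10
    phase_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=_default_phase_effects
    )
    traj_sd: Mapping[str, float] = field(default_factory=_default_traj_sd)
    outcome_proportions: tuple[float, float, float] = (43 / 54, 11 / 54, 0.0)
    outcome_attenuation: float = 0.5
    ad_proportion: float = 19 / 54
    ad_shifts: Mapping[str, float] = field(
        default_factory=lambda: {"evans": -0.04, "bvr_pc": 0.18}
    )
    attendance: tuple[float, float, float] = (1.0, 28 / 54, 16 / 54)
    day_windows: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"early": (5, 29), "mid": (31, 365), "late": (366, 1270)}
    )
    day_medians: Mapping[str, int] = field(
        default_factory=lambda: {"early": 11, "mid": 178, "late": 559}
    )
    baseline_day_range: tuple[int, int] = (-120, -5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ParameterError("n_patients must be >= 2")
        if abs(sum(self.outcome_proportions) - 1.0) > 1e-9:
            raise ParameterError("outcome proportions must sum to 1")
        for p in (*self.outcome_proportions, self.ad_proportion, *self.attendance):
            if not 0 <= p <= 1:
                raise ParameterError(f"proportion {p} outside [0, 1]")
        for name, sd in {**dict(self.baseline_sd), **dict(self.traj_sd)}.items():
            if sd < 0:
                raise ParameterError(f"SD for {name} is negative")
        if self.size_sd < 0 or self.outcome_attenuation < 0:
            raise ParameterError("size_sd and outcome_attenuation must be >= 0")
        for m in SIMULATED_MEASURES:
            if m not in self.baseline_mean:
                raise ParameterError(f"baseline mean missing for {m}")
            if m not in self.phase_effects:
                raise ParameterError(f"phase effects missing for {m}")

    def null(self) -> "CohortParams":
        """A copy with all phase effects set to 1 (no true change)."""
        return replace(
            self, phase_effects={m: (1.0, 1.0, 1.0) for m in SIMULATED_MEASURES}
        )


@dataclass(frozen=True)
class ScanRecord:
    """One MRI measurement occasion of one simulated patient."""

    patient_id: int
    days_since_shunt: int
    phase: str
    outcome: str
    ad_comorbid: bool
    measures: Mapping[str, float]


def _draw_days(rng: np.random.Generator, params: CohortParams, phase: str, n: int):
    lo, hi = params.day_windows[phase]
    med = params.day_medians[phase]
    span = hi - lo
    return lo + rng.binomial(span, (med - lo) / span, size=n)


def attendance_mask(
    params: CohortParams, seed: int | None = None
) -> pd.DataFrame:
    """Per-patient phase attendance with visit days.

    Early follow-up is attended with the configured probability (default:
    everyone); mid and late phases are independent Bernoulli draws.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rows = []
    n = params.n_patients
    for phase, prob in zip(PHASES, params.attendance):
        attends = rng.random(n) < prob
        days = _draw_days(rng, params, phase, n)
        for pid in range(n):
            rows.append(
                {
                    "patient_id": pid,
                    "phase": phase,
                    "attends": bool(attends[pid]),
                    "days_since_shunt": int(days[pid]),
                }
            )
    return pd.DataFrame(rows)


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray, lo, hi
) -> np.ndarray:
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    out = np.where(sd > 0, np.nan, mean).astype(float)
    pos = sd > 0
    if np.any(pos):
        a = (np.asarray(lo) - mean) / np.where(pos, sd, 1.0)
        b = (np.asarray(hi) - mean) / np.where(pos, sd, 1.0)
        draws = truncnorm.rvs(a, b, loc=mean, scale=np.where(pos, sd, 1.0),
                              random_state=rng)
        out = np.where(pos, draws, mean)
    return out


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a cohort; returns one row per scan (tidy table).

    Baselines are truncated normals (truncated at 1% of the mean so all
    quantities stay physiologic); each attended follow-up multiplies every
    simulated measure by its phase effect (attenuated for 'good' outcomes)
    times lognormal noise. CVR, totals, TIV and volume ratios are always
    derived from the simulated components.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    outcome = rng.choice(
        np.array(["excellent", "good", "unsatisfactory"]),
        size=n,
        p=params.outcome_proportions,
    )
    ad = rng.random(n) < params.ad_proportion
    size = np.clip(rng.normal(1.0, params.size_sd, size=n), 0.5, None)

    baseline: dict[str, np.ndarray] = {}
    for m in DRAWN_INDICES:
        shift = params.ad_shifts.get(m, 0.0)
        mean = params.baseline_mean[m] + shift * (
            ad.astype(float) - params.ad_proportion
        )
        sd = np.full(n, params.baseline_sd[m])
        hi = 0.99 if m in ("evans", "z_evans") else (179.0 if m == "callosal_angle" else np.inf)
        baseline[m] = _truncated_normal(rng, mean, sd, 0.01 * mean, hi)
    for m in COMPARTMENT_ROLES:
        shift = params.ad_shifts.get(m, 0.0)
        mean = (params.baseline_mean[m] + shift * (ad.astype(float) - params.ad_proportion)) * size
        sd = params.volume_cv[m] * mean
        baseline[m] = _truncated_normal(rng, mean, sd, 0.01 * mean, np.inf)

    att = attendance_mask(params, seed=int(rng.integers(0, 2**31 - 1)))
    base_days = rng.integers(
        params.baseline_day_range[0], params.baseline_day_range[1] + 1, size=n
    )

    pids = np.arange(n)
    blocks = [
        _block(pids, base_days, outcome, ad, {m: baseline[m] for m in SIMULATED_MEASURES})
    ]
    soften = np.where(outcome == "good", params.outcome_attenuation, 1.0)
    for phase_i, phase in enumerate(PHASES):
        sub = att[(att.phase == phase) & att.attends]
        idx = sub.patient_id.to_numpy()
        if idx.size == 0:
            continue
        vals = {}
        for m in SIMULATED_MEASURES:
            eff = 1.0 + (params.phase_effects[m][phase_i] - 1.0) * soften[idx]
            noise = np.exp(rng.normal(0.0, params.traj_sd[m], size=idx.size))
            vals[m] = baseline[m][idx] * eff * noise
        blocks.append(
            _block(idx, sub.days_since_shunt.to_numpy(), outcome[idx], ad[idx], vals)
        )

    df = pd.concat(blocks, ignore_index=True)
    return df.sort_values(["patient_id", "days_since_shunt"]).reset_index(drop=True)


def _block(pids, days, outcome, ad, vals: dict) -> pd.DataFrame:
    tv = vals["lateral_ventricles"] + vals["third_ventricle"] + vals["fourth_ventricle"]
    ts = vals["convexity_sas"] + vals["sylvian_basal"] + vals["posterior_fossa_sas"]
    return pd.DataFrame(
        {
            "patient_id": np.asarray(pids, int),
            "days_since_shunt": np.asarray(days, int),
            "phase": [assign_phase(d) for d in np.asarray(days, int)],
            "outcome": outcome,
            "ad_comorbid": ad,
            **{m: vals[m] for m in SIMULATED_MEASURES},
            "cvr": vals["convexity_sas"] / tv,
            "total_ventricles": tv,
            "total_sas": ts,
            "total_csf": tv + ts,
            "tiv": vals["brain_parenchyma"] + tv + ts,
        }
    )
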