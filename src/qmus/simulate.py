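"""Synthetic cohort generator.

Draws subject-level cohorts whose group sizes, demographics, per-muscle
thickness distributions, and fasciculation frequencies match the study's
published group-wise summaries.  Thickness marginals are independent
truncated normals per muscle (inter-muscle correlation is not
recoverable from the published summaries; the generator targets the
pre-truncation parameters, so heavily truncated cells sit slightly above
their configured mean).

Per-muscle fasciculation probabilities are calibrated by moment matching
from the published mean muscle counts: the two proximal muscles share
the proximal mean count, the six distal muscles share the remainder of
the all-muscle mean count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from .cohort import (
    CONTRACTED_CAPABLE,
    PROXIMAL_MUSCLES,
    CohortTable,
    Group,
    MuscleId,
    Sex,
    Side,
    SubjectRecord,
    MRC_MOVEMENTS,
)
from .reference import ThicknessState

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "default_config",
    "simulate_cohort",
    "config_to_json",
    "config_from_json",
]


@dataclass
class GroupSpec:
    """Generating parameters for one diagnosis group."""

    group: Group
    n: int
    age_mean: float
    age_sd: float
    female_fraction: float
    bmi_mean: Optional[float] = None
    bmi_sd: Optional[float] = None
    duration_mean: Optional[float] = None
    duration_sd: Optional[float] = None
    thickness_params: dict[tuple[MuscleId, ThicknessState], tuple[float, float]] = field(
        default_factory=dict
    )
    fasc_prob: dict[MuscleId, float] = field(default_factory=dict)
    mrc_params: Optional[dict[str, tuple[float, float]]] = None
    clinical_scale: Optional[tuple[str, float, float]] = None  # (name, mean, sd)

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"{self.group.name}: n must be >= 0")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError(f"{self.group.name}: female_fraction outside [0,1]")
        if self.age_sd < 0:
            raise ValueError(f"{self.group.name}: negative age_sd")
        for key, (_, sd) in self.thickness_params.items():
            if sd < 0:
                raise ValueError(f"{self.group.name}: negative sd for {key}")
        for muscle, p in self.fasc_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(
                    f"{self.group.name}: fasc_prob[{muscle.name}] outside [0,1]"
                )
        if self.group is Group.CONTROL and self.duration_mean is not None:
            raise ValueError("CONTROL group cannot have a disease duration")


@dataclass
class SimulationConfig:
    groups: list[GroupSpec]
    seed: int = 0
    thickness_floor: float = 0.05
    age_range: tuple[float, float] = (18.0, 90.0)

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group spec required")
        if self.thickness_floor < 0:
            raise ValueError("thickness_floor must be >= 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        for spec in self.groups:
            spec.validate()


# Published group-wise summaries used as generating parameters.
# Tuples are (CONTROL, MYO, PNP, ALS, SMA) in that fixed order.
_GROUP_ORDER = (Group.CONTROL, Group.MYO, Group.PNP, Group.ALS, Group.SMA)
_N = (65, 22, 36, 91, 31)
_AGE = ((47, 16), (54, 18), (52, 18), (63, 13), (34, 11))
_FEMALE_PCT = (63, 59, 58, 44, 58)
_BMI = ((26, 5), (25, 6), (26, 5), (25, 4), (25, 7))
_DURATION = (None, (16, 1), (7, 8), (3, 2), (30, 13))

_RELAXED = {
    MuscleId.BICEPS: ((2.51, 0.52), (1.42, 1.10), (2.35, 0.57), (1.81, 0.70), (1.25, 0.84)),
    MuscleId.FDI: ((1.13, 0.20), (0.94, 0.20), (0.87, 0.55), (0.75, 0.33), (0.66, 0.23)),
    MuscleId.APB: ((0.44, 0.08), (0.37, 0.10), (0.32, 0.11), (0.26, 0.12), (0.32, 0.13)),
    MuscleId.ADM: ((0.97, 0.18), (0.96, 0.18), (0.93, 0.22), (0.84, 0.25), (0.69, 0.22)),
    MuscleId.QUADRICEPS: ((2.13, 0.55), (1.05, 0.92), (1.89, 0.48), (1.55, 0.75), (1.23, 0.78)),
    MuscleId.TIBIALIS_ANTERIOR: ((2.12, 0.32), (1.08, 1.24), (1.69, 0.93), (1.52, 1.03), (0.70, 0.82)),
    MuscleId.AHB: ((1.19, 0.20), (0.93, 0.18), (0.83, 0.18), (0.97, 0.17), (0.95, 0.27)),
    MuscleId.EDB: ((0.76, 0.14), (0.54, 0.26), (0.32, 0.25), (0.46, 0.24), (0.54, 0.29)),
}
_CONTRACTED = {
    MuscleId.BICEPS: ((3.52, 0.65), (2.31, 1.65), (3.45, 0.46), (2.77, 0.90), (1.88, 1.26)),
    MuscleId.APB: ((0.60, 0.12), (0.49, 0.15), (0.42, 0.16), (0.35, 0.18), (0.44, 0.17)),
    MuscleId.QUADRICEPS: ((3.09, 0.70), (1.58, 1.32), (2.70, 0.60), (2.20, 0.94), (1.36, 0.86)),
    MuscleId.TIBIALIS_ANTERIOR: ((2.68, 0.34), (1.29, 1.48), (1.99, 1.11), (1.77, 1.19), (0.79, 0.95)),
}

# Mean number of fasciculating muscles: over all 8 muscles, and over the
# two proximal muscles only.
_FASC_MEAN_ALL8 = (0.91, 0.09, 0.41, 2.5, 0.94)
_FASC_MEAN_PROXIMAL = (0.02, 0.0, 0.03, 0.97, 0.16)

_MRC = {
    "shoulder_abd": ((4.3, 0.8), (4.9, 0.3), (3.3, 1.8), (3.3, 1.4)),
    "elbow_flex": ((4.2, 0.8), (5.0, 0.2), (3.7, 1.7), (3.8, 1.0)),
    "elbow_ext": ((4.3, 0.8), (5.0, 0.2), (3.9, 1.5), (3.5, 1.2)),
    "finger_abd": ((4.3, 0.6), (3.8, 1.4), (2.4, 1.9), (3.5, 1.1)),
    "finger_ext": ((4.3, 0.6), (4.2, 1.1), (3.1, 1.6), (3.6, 1.0)),
    "hip_flex": ((3.5, 1.3), (4.8, 0.5), (3.5, 1.7), (1.4, 0.9)),
    "knee_ext": ((4.2, 1.4), (5.0, 0.2), (4.1, 1.6), (1.4, 1.2)),
    "dorsiflex": ((3.4, 1.8), (3.4, 2.0), (3.2, 2.1), (3.4, 1.5)),
    "plantarflex": ((4.4, 1.5), (4.5, 1.4), (4.2, 1.6), (4.3, 1.0)),
    # big-toe extension is not tested in SMA
    "bigtoe_ext": ((3.8, 1.9), (2.9, 2.1), (3.1, 2.1), None),
}
_CLINICAL = {Group.ALS: ("ALSFRS-R", 30.0, 9.0), Group.SMA: ("HFMSE", 21.0, 18.0)}


def _fasc_probs(all8_mean: float, proximal_mean: float) -> dict[MuscleId, float]:
    """Moment-matched per-muscle presence probabilities.

    The proximal mean count is split evenly over the 2 proximal muscles,
    the remainder of the all-muscle mean count over the 6 distal ones.
    """
    p_prox = min(max(proximal_mean / 2.0, 0.0), 1.0)
    p_dist = min(max((all8_mean - proximal_mean) / 6.0, 0.0), 1.0)
    return {
        m: (p_prox if m in PROXIMAL_MUSCLES else p_dist) for m in MuscleId
    }


def default_config(seed: int = 0) -> SimulationConfig:
    """Simulation config with all parameters at the published study values."""
    groups = []
    for i, group in enumerate(_GROUP_ORDER):
        thickness: dict[tuple[MuscleId, ThicknessState], tuple[float, float]] = {}
        for muscle, rows in _RELAXED.items():
            thickness[(muscle, ThicknessState.RELAXED)] = rows[i]
        for muscle, rows in _CONTRACTED.items():
            thickness[(muscle, ThicknessState.CONTRACTED)] = rows[i]
        mrc_params = None
        if group is not Group.CONTROL:
            mrc_params = {
                movement: rows[i - 1]
                for movement, rows in _MRC.items()
                if rows[i - 1] is not None
            }
        groups.append(
            GroupSpec(
                group=group,
                n=_N[i],
                age_mean=float(_AGE[i][0]),
                age_sd=float(_AGE[i][1]),
                female_fraction=_FEMALE_PCT[i] / 100.0,
                bmi_mean=float(_BMI[i][0]),
                bmi_sd=float(_BMI[i][1]),
                duration_mean=None if _DURATION[i] is None else float(_DURATION[i][0]),
                duration_sd=None if _DURATION[i] is None else float(_DURATION[i][1]),
                thickness_params=thickness,
                fasc_prob=_fasc_probs(_FASC_MEAN_ALL8[i], _FASC_MEAN_PROXIMAL[i]),
                mrc_params=mrc_params,
                clinical_scale=_CLINICAL.get(group),
            )
        )
    return SimulationConfig(groups=groups, seed=seed)


def _draw_truncated(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float,
    high: float = np.inf,
    size: int = 1,
) -> np.ndarray:
    if sd <= 0:
        return np.full(size, min(max(mean, low), high))
    a = (low - mean) / sd
    b = (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _round_half(values: np.ndarray) -> np.ndarray:
    return np.round(values * 2.0) / 2.0


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw a full cohort; deterministic for a fixed ``config.seed``.

    Draws are vectorized per group and variable in a fixed order, so a
    fixed seed yields a bitwise-identical serialized table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    age_low, age_high = config.age_range
    records: list[SubjectRecord] = []
    for spec in config.groups:
        n = spec.n
        if n == 0:
            continue
        ages = _draw_truncated(rng, spec.age_mean, spec.age_sd, age_low, age_high, n)
        # keep the rounded age strictly inside the configured range
        ages = np.clip(np.round(ages, 1), age_low, age_high - 0.1)
        is_female = rng.random(n) < spec.female_fraction
        bmis = None
        if spec.bmi_mean is not None:
            bmis = np.round(
                _draw_truncated(rng, spec.bmi_mean, spec.bmi_sd or 0.0, 10.0, size=n), 1
            )
        durations = None
        if spec.duration_mean is not None:
            durations = np.round(
                _draw_truncated(rng, spec.duration_mean, spec.duration_sd or 0.0, 0.0,
                                size=n),
                1,
            )
        thickness: dict[tuple[MuscleId, ThicknessState], np.ndarray] = {}
        for muscle in MuscleId:
            for state in (ThicknessState.RELAXED, ThicknessState.CONTRACTED):
                if state is ThicknessState.CONTRACTED and muscle not in CONTRACTED_CAPABLE:
                    continue
                params = spec.thickness_params.get((muscle, state))
                if params is not None:
                    thickness[(muscle, state)] = np.round(
                        _draw_truncated(
                            rng, params[0], params[1], config.thickness_floor, size=n
                        ),
                        2,
                    )
        fasc = {
            muscle: rng.random(n) < spec.fasc_prob.get(muscle, 0.0)
            for muscle in MuscleId
        }
        mrc_draws = None
        if spec.mrc_params:
            mrc_draws = {
                movement: _round_half(_draw_truncated(rng, mean, sd, 0.0, 5.0, size=n))
                for movement, (mean, sd) in spec.mrc_params.items()
            }
        scale_values = None
        if spec.clinical_scale is not None:
            name, mean, sd = spec.clinical_scale
            hi = {"ALSFRS-R": 48.0, "HFMSE": 69.0}.get(name, np.inf)
            scale_values = np.round(_draw_truncated(rng, mean, sd, 0.0, hi, size=n))

        for k in range(n):
            relaxed = {
                m: float(v[k])
                for (m, s), v in thickness.items()
                if s is ThicknessState.RELAXED
            }
            contracted = {
                m: float(v[k])
                for (m, s), v in thickness.items()
                if s is ThicknessState.CONTRACTED
            }
            records.append(
                SubjectRecord(
                    subject_id=f"SIM-{spec.group.name}-{k + 1:03d}",
                    group=spec.group,
                    age=float(ages[k]),
                    sex=Sex.F if is_female[k] else Sex.M,
                    side=Side.RIGHT,
                    bmi=None if bmis is None else float(bmis[k]),
                    disease_duration=None if durations is None else float(durations[k]),
                    relaxed_thickness=relaxed,
                    contracted_thickness=contracted,
                    fasciculation_present={m: bool(v[k]) for m, v in fasc.items()},
                    mrc=None
                    if mrc_draws is None
                    else {mv: float(v[k]) for mv, v in mrc_draws.items()},
                    clinical_scale_name=None if scale_values is None else spec.clinical_scale[0],
                    clinical_scale_value=None if scale_values is None else float(scale_values[k]),
                )
            )
    table = CohortTable(records=records, provenance=f"simulated(seed={config.seed})")
    table.validate()
    return table


# -- JSON config round trip ------------------------------------------------


def config_to_json(config: SimulationConfig) -> str:
    def spec_dict(spec: GroupSpec) -> dict:
        return {
            "group": spec.group.name,
            "n": spec.n,
            "age_mean": spec.age_mean,
            "age_sd": spec.age_sd,
            "female_fraction": spec.female_fraction,
            "bmi_mean": spec.bmi_mean,
            "bmi_sd": spec.bmi_sd,
            "duration_mean": spec.duration_mean,
            "duration_sd": spec.duration_sd,
            "thickness_params": {
                f"{state.value}:{muscle.value}": list(params)
                for (muscle, state), params in spec.thickness_params.items()
            },
            "fasc_prob": {m.value: p for m, p in spec.fasc_prob.items()},
            "mrc_params": None
            if spec.mrc_params is None
            else {mv: list(p) for mv, p in spec.mrc_params.items()},
            "clinical_scale": None
            if spec.clinical_scale is None
            else list(spec.clinical_scale),
        }

    return json.dumps(
        {
            "seed": config.seed,
            "thickness_floor": config.thickness_floor,
            "age_range": list(config.age_range),
            "groups": [spec_dict(s) for s in config.groups],
        },
        indent=2,
    )


def config_from_json(text: str) -> SimulationConfig:
    payload = json.loads(text)
    by_value = {m.value: m for m in MuscleId}
    groups = []
    for sd in payload["groups"]:
        thickness = {}
        for key, params in sd["thickness_params"].items():
            state_s, muscle_s = key.split(":")
            thickness[(by_value[muscle_s], ThicknessState(state_s))] = (
                float(params[0]),
                float(params[1]),
            )
        groups.append(
            GroupSpec(
                group=Group[sd["group"]],
                n=int(sd["n"]),
                age_mean=float(sd["age_mean"]),
                age_sd=float(sd["age_sd"]),
                female_fraction=float(sd["female_fraction"]),
                bmi_mean=sd["bmi_mean"],
                bmi_sd=sd["bmi_sd"],
                duration_mean=sd["duration_mean"],
                duration_sd=sd["duration_sd"],
                thickness_params=thickness,
                fasc_prob={by_value[m]: float(p) for m, p in sd["fasc_prob"].items()},
                mrc_params=None
                if sd["mrc_params"] is None
                else {mv: (float(p[0]), float(p[1])) for mv, p in sd["mrc_params"].items()},
                clinical_scale=None
                if sd["clinical_scale"] is None
                else (sd["clinical_scale"][0], float(sd["clinical_scale"][1]),
                      float(sd["clinical_scale"][2])),
            )
        )
    config = SimulationConfig(
        groups=groups,
        seed=int(payload["seed"]),
        thickness_floor=float(payload["thickness_floor"]),
        age_range=(float(payload["age_range"][0]), float(payload["age_range"][1])),
    )
    config.validate()
    return config
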