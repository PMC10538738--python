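"""Decision rules applied to single subjects.

Per-muscle thickness flags (strictly below the normative cutoff =
abnormal), the multi-muscle reduced-thickness rules, the proximal-distal
thickness differential, the strength differential, and the fasciculation
count criteria.  Unmeasured muscles are excluded from every count; a
subject with no usable observations gets a missing verdict, never a
negative one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from .cohort import (
    CONTRACTED_CAPABLE,
    PROXIMAL_MUSCLES,
    MuscleId,
    SubjectRecord,
)
from .reference import NormativeReference, ThicknessState

__all__ = [
    "Flag",
    "RuleConfig",
    "AbnormalityProfile",
    "flag_muscle",
    "classify_subject",
    "classify_cohort",
    "biceps_minus_edb",
    "mrc_differential",
    "has_normal_strength",
    "write_profiles",
]


class Flag(str, Enum):
    ABNORMAL = "ABNORMAL"
    NORMAL = "NORMAL"
    MISSING = "MISSING"


@dataclass(frozen=True)
class RuleConfig:
    """Constants of the decision rules.

    Defaults: one reduced muscle suffices for a positive thickness rule;
    the fasciculation rule over all eight muscles requires >= 2
    fasciculating muscles, the proximal rule >= 1 of {biceps, quadriceps};
    observations come from a 15-second scan window.
    """

    min_abnormal_muscles: int = 1
    fasc_threshold_all8: int = 2
    fasc_threshold_proximal: int = 1
    proximal_set: frozenset[MuscleId] = PROXIMAL_MUSCLES
    scan_window_s: float = 15.0

    def __post_init__(self) -> None:
        if self.min_abnormal_muscles < 1:
            raise ValueError("min_abnormal_muscles must be >= 1")
        if self.fasc_threshold_all8 < 1 or self.fasc_threshold_proximal < 1:
            raise ValueError("fasciculation thresholds must be >= 1")
        if not self.proximal_set <= set(MuscleId):
            raise ValueError("proximal_set must be a subset of the studied muscles")
        if self.scan_window_s <= 0:
            raise ValueError("scan_window_s must be positive")


@dataclass
class AbnormalityProfile:
    """Classifier output for one subject.

    ``None`` marks a verdict that could not be evaluated because every
    relevant observation was missing.
    """

    subject_id: str
    relaxed_flags: dict[MuscleId, Flag] = field(default_factory=dict)
    contracted_flags: dict[MuscleId, Flag] = field(default_factory=dict)
    relaxed_positive: Optional[bool] = None
    contracted_positive: Optional[bool] = None
    biceps_minus_edb_cm: Optional[float] = None
    mrc_elbowflex_minus_bigtoe: Optional[float] = None
    fasc_count_all8: Optional[int] = None
    fasc_count_proximal: Optional[int] = None
    fasc_positive_all8: Optional[bool] = None
    fasc_positive_proximal: Optional[bool] = None


def flag_muscle(thickness: float, cutoff: float) -> Flag:
    """ABNORMAL iff thickness is strictly below the cutoff.

    A thickness exactly equal to the cutoff is NORMAL ("lower than" is
    strict).
    """
    if thickness < 0:
        raise ValueError(f"negative thickness {thickness}")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    return Flag.ABNORMAL if thickness < cutoff else Flag.NORMAL


def biceps_minus_edb(record: SubjectRecord) -> Optional[float]:
    """Relaxed biceps minus EDB thickness (cm); missing if either is absent.

    May legitimately be negative.
    """
    biceps = record.relaxed_thickness.get(MuscleId.BICEPS)
    edb = record.relaxed_thickness.get(MuscleId.EDB)
    if biceps is None or edb is None:
        return None
    return biceps - edb


def mrc_differential(record: SubjectRecord) -> Optional[float]:
    """Elbow-flexion MRC minus big-toe-extension MRC; missing if either absent."""
    if record.mrc is None:
        return None
    elbow = record.mrc.get("elbow_flex")
    bigtoe = record.mrc.get("bigtoe_ext")
    if elbow is None or bigtoe is None:
        return None
    return elbow - bigtoe


def has_normal_strength(record: SubjectRecord) -> bool:
    """True when every recorded MRC movement scores 5 and >= 1 is recorded."""
    if not record.mrc:
        return False
    return all(score == 5 for score in record.mrc.values())


def _rule_verdict(flags: dict[MuscleId, Flag], threshold: int) -> Optional[bool]:
    observed = [f for f in flags.values() if f is not Flag.MISSING]
    if not observed:
        return None
    return sum(f is Flag.ABNORMAL for f in observed) >= threshold


def classify_subject(
    record: SubjectRecord,
    ref: NormativeReference,
    config: RuleConfig = RuleConfig(),
) -> AbnormalityProfile:
    """Evaluate all decision rules for one subject.

    The relaxed rule runs over the 8-muscle set and the contracted rule
    over the 4 contracted-capable muscles.  Age outside the reference
    strata propagates as :class:`~qmus.reference.AgeOutOfRangeError`.
    """
    profile = AbnormalityProfile(subject_id=record.subject_id)

    for muscle in MuscleId:
        thickness = record.relaxed_thickness.get(muscle)
        if thickness is None:
            profile.relaxed_flags[muscle] = Flag.MISSING
        else:
            cutoff = ref.lookup_cutoff(
                muscle, ThicknessState.RELAXED, record.sex, record.age
            )
            profile.relaxed_flags[muscle] = flag_muscle(thickness, cutoff)
        if muscle in CONTRACTED_CAPABLE:
            thickness = record.contracted_thickness.get(muscle)
            if thickness is None:
                profile.contracted_flags[muscle] = Flag.MISSING
            else:
                cutoff = ref.lookup_cutoff(
                    muscle, ThicknessState.CONTRACTED, record.sex, record.age
                )
                profile.contracted_flags[muscle] = flag_muscle(thickness, cutoff)

    profile.relaxed_positive = _rule_verdict(
        profile.relaxed_flags, config.min_abnormal_muscles
    )
    profile.contracted_positive = _rule_verdict(
        profile.contracted_flags, config.min_abnormal_muscles
    )

    profile.biceps_minus_edb_cm = biceps_minus_edb(record)
    profile.mrc_elbowflex_minus_bigtoe = mrc_differential(record)

    observed_fasc = record.fasciculation_present
    if observed_fasc:
        profile.fasc_count_all8 = sum(observed_fasc.values())
        profile.fasc_positive_all8 = (
            profile.fasc_count_all8 >= config.fasc_threshold_all8
        )
    proximal_observed = {
        m: v for m, v in observed_fasc.items() if m in config.proximal_set
    }
    if proximal_observed:
        profile.fasc_count_proximal = sum(proximal_observed.values())
        profile.fasc_positive_proximal = (
            profile.fasc_count_proximal >= config.fasc_threshold_proximal
        )
    return profile


def classify_cohort(
    cohort: Iterable[SubjectRecord],
    ref: NormativeReference,
    config: RuleConfig = RuleConfig(),
) -> list[AbnormalityProfile]:
    return [classify_subject(rec, ref, config) for rec in cohort]


_PROFILE_COLUMNS = (
    ("subject_id",)
    + tuple(f"relaxed_flag_{m.value}" for m in MuscleId)
    + tuple(f"contracted_flag_{m.value}" for m in MuscleId if m in CONTRACTED_CAPABLE)
    + (
        "relaxed_positive",
        "contracted_positive",
        "biceps_minus_edb_cm",
        "mrc_elbowflex_minus_bigtoe",
        "fasc_count_all8",
        "fasc_count_proximal",
        "fasc_positive_all8",
        "fasc_positive_proximal",
    )
)


def write_profiles(
    profiles: Iterable[AbnormalityProfile], path: str | Path, delimiter: str = ","
) -> None:
    """Write profiles as delimited text: booleans true/false, missing empty."""

    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, bool):
            return "true" if value else "false"
        if isinstance(value, Flag):
            return value.value
        return str(value)

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(_PROFILE_COLUMNS)
        for p in profiles:
            row = [p.subject_id]
            row += [fmt(p.relaxed_flags.get(m)) for m in MuscleId]
            row += [
                fmt(p.contracted_flags.get(m))
                for m in MuscleId
                if m in CONTRACTED_CAPABLE
            ]
            row += [
                fmt(p.relaxed_positive),
                fmt(p.contracted_positive),
                fmt(p.biceps_minus_edb_cm),
                fmt(p.mrc_elbowflex_minus_bigtoe),
                fmt(p.fasc_count_all8),
                fmt(p.fasc_count_proximal),
                fmt(p.fasc_positive_all8),
                fmt(p.fasc_positive_proximal),
            ]
            writer.writerow(row)
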