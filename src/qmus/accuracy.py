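"""Diagnostic accuracy: sensitivities, specificity, and AUC estimators.

Three AUC routes are provided and never conflated:

* ``auc_binary`` — the single-threshold trapezoidal identity
  ``(Se + Sp) / 2`` for a binary rule;
* ``auc_empirical`` — the rank-based (Mann-Whitney) estimator, ties
  counted one half, with no automatic orientation flipping;
* ``auc_binormal`` — the closed form ``Phi(dmu / sqrt(sd1^2 + sd0^2))``
  under Gaussian score distributions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .cohort import CONTRACTED_CAPABLE, CohortTable, Group, MuscleId
from .rules import AbnormalityProfile, Flag

__all__ = [
    "AucMethod",
    "Proportion",
    "DiagnosticAccuracy",
    "sensitivity_by_group",
    "pool_rates",
    "auc_binary",
    "auc_empirical",
    "auc_binormal",
    "evaluate_rule",
    "cohort_report",
]


class AucMethod(str, Enum):
    BINARY_IDENTITY = "BINARY_IDENTITY"
    EMPIRICAL_RANK = "EMPIRICAL_RANK"
    BINORMAL = "BINORMAL"


@dataclass(frozen=True)
class Proportion:
    """A proportion that keeps its counts so it can always be re-derived."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError(
                f"invalid proportion {self.numerator}/{self.denominator}"
            )

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        """Value on the 0-100 scale, rounded to the nearest integer."""
        return round(100.0 * self.value)


@dataclass
class DiagnosticAccuracy:
    """Accuracy summary of one decision rule over a cohort."""

    rule_name: str
    per_group_sensitivity: dict[Group, Proportion] = field(default_factory=dict)
    control_specificity: Optional[Proportion] = None
    pooled_sensitivity: Optional[Proportion] = None
    auc: Optional[float] = None
    auc_method: Optional[AucMethod] = None

    def to_dict(self) -> dict:
        def prop(p: Optional[Proportion]):
            if p is None:
                return None
            return {
                "numerator": p.numerator,
                "denominator": p.denominator,
                "value": p.value,
                "percent": p.percent,
            }

        return {
            "rule_name": self.rule_name,
            "per_group_sensitivity": {
                g.name: prop(p) for g, p in self.per_group_sensitivity.items()
            },
            "control_specificity": prop(self.control_specificity),
            "pooled_sensitivity": prop(self.pooled_sensitivity),
            "auc": None if self.auc is None else round(self.auc, 2),
            "auc_raw": self.auc,
            "auc_method": None if self.auc_method is None else self.auc_method.value,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def sensitivity_by_group(
    pairs: Iterable[tuple[Group, Optional[bool]]],
) -> dict[Group, Proportion]:
    """Positive-verdict rate per group from (group, verdict) pairs.

    Missing verdicts are excluded from both numerator and denominator.
    For CONTROL the returned rate is the false-positive rate; specificity
    is one minus it.  Groups with no usable verdict are omitted with a
    warning.
    """
    positives: dict[Group, int] = {}
    totals: dict[Group, int] = {}
    seen: set[Group] = set()
    for group, verdict in pairs:
        seen.add(group)
        if verdict is None:
            continue
        totals[group] = totals.get(group, 0) + 1
        positives[group] = positives.get(group, 0) + int(verdict)
    for group in seen - set(totals):
        warnings.warn(
            f"group {group.name}: no non-missing verdicts; omitted", stacklevel=2
        )
    return {g: Proportion(positives.get(g, 0), n) for g, n in totals.items()}


def pool_rates(rates: Sequence[float], weights: Sequence[int | float]) -> float:
    """Weighted mean of per-group rates (e.g. sensitivities by group size)."""
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if rates.shape != weights.shape or rates.size == 0:
        raise ValueError("rates and weights must be non-empty and aligned")
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    return float(np.average(rates, weights=weights))


def auc_binary(sensitivity: float, specificity: float) -> float:
    """Trapezoidal ROC area of a single binary threshold: (Se + Sp) / 2."""
    if not 0 <= sensitivity <= 1 or not 0 <= specificity <= 1:
        raise ValueError(
            f"sensitivity and specificity must be in [0,1], got "
            f"({sensitivity}, {specificity})"
        )
    return (sensitivity + specificity) / 2.0


def auc_empirical(scores: Sequence[float], labels: Sequence[int | bool]) -> float:
    """Rank-based AUC: fraction of case-control pairs ordered correctly.

    Ties count one half (the normalized Mann-Whitney statistic).  The
    orientation is fixed by the caller: label 1 is the positive class and
    higher scores are taken to indicate positivity.  No flipping is done,
    so values below 0.5 are returned as-is.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    rank_sum_pos = ranks[labels].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_binormal(
    mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float
) -> float:
    """Closed-form AUC assuming Gaussian scores in both classes."""
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError(f"standard deviations must be positive, got "
                         f"({sd_pos}, {sd_neg})")
    return float(norm.cdf((mu_pos - mu_neg) / np.hypot(sd_pos, sd_neg)))


def _profile_verdicts(
    cohort: CohortTable,
    profiles: Iterable[AbnormalityProfile],
    verdict_field: str,
) -> list[tuple[Group, object]]:
    by_id = {p.subject_id: p for p in profiles}
    out = []
    for rec in cohort:
        profile = by_id.get(rec.subject_id)
        if profile is None:
            continue
        out.append((rec.group, getattr(profile, verdict_field)))
    return out


def evaluate_rule(
    cohort: CohortTable,
    profiles: Iterable[AbnormalityProfile],
    verdict_field: str,
    positive_groups: Iterable[Group],
    negative_groups: Iterable[Group],
    rule_name: Optional[str] = None,
) -> DiagnosticAccuracy:
    """Full accuracy summary of one profile field over a cohort.

    Boolean verdict fields (the rule outputs) use the BINARY_IDENTITY
    AUC from pooled sensitivity and specificity; numeric marker fields
    (e.g. the proximal-distal differential) use the EMPIRICAL_RANK AUC
    with higher scores treated as positive.
    """
    positive_groups = set(positive_groups)
    negative_groups = set(negative_groups)
    if positive_groups & negative_groups:
        raise ValueError("positive and negative classes overlap")
    if not positive_groups or not negative_groups:
        raise ValueError("both classes must be non-empty")

    pairs = [
        (g, v)
        for g, v in _profile_verdicts(cohort, profiles, verdict_field)
        if g in positive_groups or g in negative_groups
    ]
    usable = [(g, v) for g, v in pairs if v is not None]
    if not any(g in positive_groups for g, _ in usable):
        raise ValueError("positive class has no subjects with a usable verdict")
    if not any(g in negative_groups for g, _ in usable):
        raise ValueError("negative class has no subjects with a usable verdict")

    result = DiagnosticAccuracy(rule_name=rule_name or verdict_field)
    values = [v for _, v in usable]
    if all(isinstance(v, bool) for v in values):
        by_group = sensitivity_by_group(pairs)
        result.per_group_sensitivity = {
            g: p for g, p in by_group.items() if g in positive_groups
        }
        pos_n = sum(p.denominator for p in result.per_group_sensitivity.values())
        pos_hits = sum(p.numerator for p in result.per_group_sensitivity.values())
        result.pooled_sensitivity = Proportion(pos_hits, pos_n)
        neg = [(g, v) for g, v in usable if g in negative_groups]
        true_negatives = sum(not v for _, v in neg)
        result.control_specificity = Proportion(true_negatives, len(neg))
        result.auc = auc_binary(
            result.pooled_sensitivity.value, result.control_specificity.value
        )
        result.auc_method = AucMethod.BINARY_IDENTITY
    else:
        scores = [float(v) for _, v in usable]
        labels = [g in positive_groups for g, _ in usable]
        result.auc = auc_empirical(scores, labels)
        result.auc_method = AucMethod.EMPIRICAL_RANK
    return result


def _flag_rates(
    groups_flags: list[tuple[Group, Flag]]
) -> dict[Group, Proportion]:
    totals: dict[Group, int] = {}
    abnormal: dict[Group, int] = {}
    for group, flag in groups_flags:
        if flag is Flag.MISSING:
            continue
        totals[group] = totals.get(group, 0) + 1
        abnormal[group] = abnormal.get(group, 0) + (flag is Flag.ABNORMAL)
    return {g: Proportion(abnormal.get(g, 0), n) for g, n in totals.items()}


def cohort_report(
    cohort: CohortTable,
    profiles: Iterable[AbnormalityProfile],
) -> dict:
    """Full accuracy report over a classified cohort.

    Per (muscle, state): percent flagged abnormal in each group, with the
    binary-identity AUC (patients pooled vs controls).  Plus the overall
    thickness rules (patients vs controls) and the two fasciculation
    rules (ALS vs everyone else).  A cohort without patients degrades to
    control false-positive rates with a warning.
    """
    profiles = list(profiles)
    by_id = {p.subject_id: p for p in profiles}
    patient_groups = [g for g in Group if g is not Group.CONTROL]
    present = {rec.group for rec in cohort}
    have_patients = any(g in present for g in patient_groups)
    have_controls = Group.CONTROL in present

    def prop_dict(p: Proportion) -> dict:
        return {
            "numerator": p.numerator,
            "denominator": p.denominator,
            "value": p.value,
            "percent": p.percent,
        }

    report: dict = {"n_subjects": len(cohort), "per_muscle": {}, "rules": {}}
    report["group_sizes"] = {g.name: n for g, n in cohort.group_counts().items() if n}

    for state, attr in (("RELAXED", "relaxed_flags"), ("CONTRACTED", "contracted_flags")):
        muscles = list(MuscleId) if state == "RELAXED" else [
            m for m in MuscleId if m in CONTRACTED_CAPABLE
        ]
        for muscle in muscles:
            pairs = []
            for rec in cohort:
                profile = by_id.get(rec.subject_id)
                if profile is None:
                    continue
                flag = getattr(profile, attr).get(muscle, Flag.MISSING)
                pairs.append((rec.group, flag))
            rates = _flag_rates(pairs)
            entry: dict = {
                "rates": {g.name: prop_dict(p) for g, p in rates.items()}
            }
            patient_props = [rates[g] for g in patient_groups if g in rates]
            if patient_props and Group.CONTROL in rates:
                se = Proportion(
                    sum(p.numerator for p in patient_props),
                    sum(p.denominator for p in patient_props),
                )
                sp = Proportion(
                    rates[Group.CONTROL].denominator - rates[Group.CONTROL].numerator,
                    rates[Group.CONTROL].denominator,
                )
                entry["auc"] = round(auc_binary(se.value, sp.value), 2)
            report["per_muscle"][f"{state.lower()}_{muscle.value}"] = entry

    rule_specs = [
        ("relaxed_positive", patient_groups, [Group.CONTROL]),
        ("contracted_positive", patient_groups, [Group.CONTROL]),
        ("fasc_positive_all8", [Group.ALS], [g for g in Group if g is not Group.ALS]),
        ("fasc_positive_proximal", [Group.ALS], [g for g in Group if g is not Group.ALS]),
    ]
    for verdict_field, pos, neg in rule_specs:
        try:
            result = evaluate_rule(cohort, profiles, verdict_field, pos, neg)
            report["rules"][verdict_field] = result.to_dict()
        except ValueError as exc:
            # degrade gracefully (e.g. control-only cohort): keep the
            # observable side of the rule
            warnings.warn(f"rule {verdict_field}: {exc}", stacklevel=2)
            pairs = _profile_verdicts(cohort, profiles, verdict_field)
            neg_pairs = [(g, v) for g, v in pairs if g in neg and v is not None]
            entry = {"rule_name": verdict_field, "warning": str(exc)}
            if neg_pairs:
                sp = Proportion(
                    sum(not v for _, v in neg_pairs), len(neg_pairs)
                )
                entry["control_specificity"] = prop_dict(sp)
            report["rules"][verdict_field] = entry
    if not have_patients:
        report["warning"] = "cohort contains no patient groups; sensitivities omitted"
    if not have_controls:
        report["warning"] = "cohort contains no controls; specificity omitted"
    return report
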