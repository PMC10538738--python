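"""Age/sex-stratified normative thickness cutoffs built from healthy controls.

A cutoff is the configured lower percentile (default 5) of control
thickness within each (muscle, state, sex, age-stratum) cell.  Two
estimators are available:

``EMPIRICAL_QUANTILE``
    Linear interpolation between order statistics at position
    ``p*(n-1)+1`` (the conventional "type 7" rule, numpy's default).

``GAUSSIAN_PARAMETRIC``
    ``mean + z_p * sd`` with ``z_p`` the standard-normal quantile of
    ``p/100`` (for the 5th percentile, ``mean - 1.6449*sd``).

Strata thinner than ``min_stratum_n`` fall back to the parametric
estimator with a warning, unless ``allow_fallback=False``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .cohort import CONTRACTED_CAPABLE, CohortTable, Group, MuscleId, Sex

__all__ = [
    "ThicknessState",
    "CutoffMethod",
    "Stratum",
    "CutoffCell",
    "NormativeReference",
    "ReferenceError",
    "AgeOutOfRangeError",
    "DEFAULT_AGE_BINS",
    "build_reference",
]

DEFAULT_AGE_BINS: tuple[float, ...] = (18.0, 40.0, 60.0, 90.0)


class ThicknessState(str, Enum):
    RELAXED = "RELAXED"
    CONTRACTED = "CONTRACTED"


class CutoffMethod(str, Enum):
    EMPIRICAL_QUANTILE = "EMPIRICAL_QUANTILE"
    GAUSSIAN_PARAMETRIC = "GAUSSIAN_PARAMETRIC"


class ReferenceError(ValueError):
    """Raised for invalid reference construction or queries."""


class AgeOutOfRangeError(ReferenceError):
    """Raised when a queried age falls outside every configured stratum."""


@dataclass(frozen=True)
class Stratum:
    """Half-open age bin for one sex: ``age_low <= age < age_high``."""

    sex: Sex
    age_low: float
    age_high: float

    def __post_init__(self) -> None:
        if not self.age_low < self.age_high:
            raise ReferenceError(
                f"stratum requires age_low < age_high, got [{self.age_low}, {self.age_high})"
            )

    def contains(self, sex: Sex, age: float) -> bool:
        return sex is self.sex and self.age_low <= age < self.age_high

    def describe(self) -> str:
        return f"{self.sex.name}/[{self.age_low:g},{self.age_high:g})"


@dataclass(frozen=True)
class CutoffCell:
    cutoff_cm: float
    n: int
    method: CutoffMethod


@dataclass
class NormativeReference:
    """Lower-percentile thickness cutoffs per (muscle, state, stratum)."""

    percentile: float
    method: CutoffMethod
    strata: list[Stratum]
    cutoffs: dict[tuple[MuscleId, ThicknessState, int], CutoffCell] = field(
        default_factory=dict
    )

    def validate(self) -> None:
        if not 0 < self.percentile < 100:
            raise ReferenceError(f"percentile must be in (0,100), got {self.percentile}")
        for sex in Sex:
            bins = sorted(
                (s for s in self.strata if s.sex is sex), key=lambda s: s.age_low
            )
            for a, b in zip(bins, bins[1:]):
                if b.age_low < a.age_high:
                    raise ReferenceError(
                        f"overlapping strata {a.describe()} and {b.describe()}"
                    )
        for (muscle, state, idx), cell in self.cutoffs.items():
            if state is ThicknessState.CONTRACTED and muscle not in CONTRACTED_CAPABLE:
                raise ReferenceError(
                    f"contracted cutoff stored for non-contracted muscle {muscle.name}"
                )
            if not 0 <= idx < len(self.strata):
                raise ReferenceError(f"stratum index {idx} out of range")
            if not cell.cutoff_cm > 0:
                raise ReferenceError(
                    f"non-positive cutoff {cell.cutoff_cm} for {muscle.name}/{state.name}"
                )

    def stratum_for(self, sex: Sex, age: float) -> int:
        for i, stratum in enumerate(self.strata):
            if stratum.contains(sex, age):
                return i
        covered = ", ".join(s.describe() for s in self.strata if s.sex is sex)
        raise AgeOutOfRangeError(
            f"age {age} ({sex.name}) outside configured strata: {covered}"
        )

    def lookup_cutoff(
        self, muscle: MuscleId, state: ThicknessState, sex: Sex, age: float
    ) -> float:
        """Return the cutoff (cm) for one muscle/state at a given sex and age."""
        if state is ThicknessState.CONTRACTED and muscle not in CONTRACTED_CAPABLE:
            raise ReferenceError(
                f"{muscle.name} has no contracted cutoff (not contracted-capable)"
            )
        idx = self.stratum_for(sex, age)
        try:
            return self.cutoffs[(muscle, state, idx)].cutoff_cm
        except KeyError:
            raise ReferenceError(
                f"no cutoff for {muscle.name}/{state.name} in stratum "
                f"{self.strata[idx].describe()}"
            ) from None

    # -- JSON serialization -------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "percentile": self.percentile,
            "method": self.method.value,
            "strata": [
                {"sex": s.sex.name, "age_low": s.age_low, "age_high": s.age_high}
                for s in self.strata
            ],
            "cutoffs": [
                {
                    "muscle": muscle.name,
                    "state": state.value,
                    "stratum_index": idx,
                    "cutoff_cm": cell.cutoff_cm,
                    "n": cell.n,
                    "method": cell.method.value,
                }
                for (muscle, state, idx), cell in sorted(
                    self.cutoffs.items(),
                    key=lambda kv: (kv[0][0].name, kv[0][1].value, kv[0][2]),
                )
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NormativeReference":
        payload = json.loads(text)
        strata = [
            Stratum(Sex[s["sex"]], float(s["age_low"]), float(s["age_high"]))
            for s in payload["strata"]
        ]
        cutoffs = {
            (
                MuscleId[c["muscle"]],
                ThicknessState(c["state"]),
                int(c["stratum_index"]),
            ): CutoffCell(
                float(c["cutoff_cm"]), int(c["n"]), CutoffMethod(c["method"])
            )
            for c in payload["cutoffs"]
        }
        ref = cls(
            percentile=float(payload["percentile"]),
            method=CutoffMethod(payload["method"]),
            strata=strata,
            cutoffs=cutoffs,
        )
        ref.validate()
        return ref

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "NormativeReference":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _empirical_quantile(values: np.ndarray, percentile: float) -> float:
    # numpy's "linear" method is exactly the type-7 rule
    return float(np.quantile(values, percentile / 100.0, method="linear"))


def _gaussian_cutoff(values: np.ndarray, percentile: float) -> float:
    z = norm.ppf(percentile / 100.0)
    return float(values.mean() + z * values.std(ddof=1))


def build_reference(
    controls: CohortTable,
    age_bins: Sequence[float] = DEFAULT_AGE_BINS,
    percentile: float = 5.0,
    method: CutoffMethod = CutoffMethod.EMPIRICAL_QUANTILE,
    min_stratum_n: int = 8,
    allow_fallback: bool = True,
) -> NormativeReference:
    """Build per-stratum lower-percentile cutoffs from a control cohort.

    Parameters
    ----------
    controls
        Cohort containing only CONTROL records.
    age_bins
        Increasing bin edges shared by both sexes; consecutive pairs form
        half-open strata ``[low, high)``.
    percentile
        Percentile in (0, 100); default 5.
    method
        Requested estimator; thin strata may fall back (see module docs).
    min_stratum_n
        Minimum controls per cell for the empirical estimator.
    allow_fallback
        If False, a stratum below ``min_stratum_n`` raises instead of
        falling back to the parametric estimator.
    """
    if not 0 < percentile < 100:
        raise ReferenceError(f"percentile must be in (0,100), got {percentile}")
    if len(age_bins) < 2 or any(a >= b for a, b in zip(age_bins, age_bins[1:])):
        raise ReferenceError(f"age_bins must be strictly increasing, got {age_bins}")
    non_control = [r.subject_id for r in controls if r.group is not Group.CONTROL]
    if non_control:
        raise ReferenceError(
            f"non-CONTROL records present: {', '.join(non_control[:5])}"
        )
    if len(controls) == 0:
        raise ReferenceError("control cohort is empty")

    strata = [
        Stratum(sex, float(lo), float(hi))
        for sex in Sex
        for lo, hi in zip(age_bins, age_bins[1:])
    ]
    ref = NormativeReference(percentile=percentile, method=method, strata=strata)

    membership: list[list[int]] = [[] for _ in strata]
    for rec_idx, rec in enumerate(controls):
        for s_idx, stratum in enumerate(strata):
            if stratum.contains(rec.sex, rec.age):
                membership[s_idx].append(rec_idx)
                break

    records = list(controls)

    def extract(members, muscle: MuscleId, state: ThicknessState) -> np.ndarray:
        source = (
            "relaxed_thickness"
            if state is ThicknessState.RELAXED
            else "contracted_thickness"
        )
        return np.array(
            [
                getattr(r, source)[muscle]
                for r in members
                if muscle in getattr(r, source)
            ],
            dtype=float,
        )

    for s_idx, stratum in enumerate(strata):
        members = [records[i] for i in membership[s_idx]]
        for muscle in MuscleId:
            states = [ThicknessState.RELAXED]
            if muscle in CONTRACTED_CAPABLE:
                states.append(ThicknessState.CONTRACTED)
            for state in states:
                values = extract(members, muscle, state)
                if len(values) < 2 and allow_fallback:
                    # too thin even for the parametric estimator: pool both
                    # sexes in the same age bin, then all controls
                    pooled = extract(
                        [
                            r
                            for r in records
                            if stratum.age_low <= r.age < stratum.age_high
                        ],
                        muscle,
                        state,
                    )
                    if len(pooled) < 2:
                        pooled = extract(records, muscle, state)
                    if len(pooled) >= 2:
                        warnings.warn(
                            f"stratum {stratum.describe()}: only {len(values)} "
                            f"control(s) for {muscle.name}/{state.name}; cutoff "
                            f"estimated from {len(pooled)} pooled controls",
                            stacklevel=2,
                        )
                        values = pooled
                cell = _build_cell(
                    values, percentile, method, min_stratum_n, allow_fallback, stratum,
                    muscle, state,
                )
                if cell is not None:
                    ref.cutoffs[(muscle, state, s_idx)] = cell
    ref.validate()
    return ref


def _build_cell(
    values: np.ndarray,
    percentile: float,
    method: CutoffMethod,
    min_stratum_n: int,
    allow_fallback: bool,
    stratum: Stratum,
    muscle: MuscleId,
    state: ThicknessState,
) -> CutoffCell | None:
    n = len(values)
    if n == 0:
        return None
    cell_method = method
    if n < min_stratum_n:
        if not allow_fallback:
            raise ReferenceError(
                f"stratum {stratum.describe()} has only {n} controls for "
                f"{muscle.name}/{state.name} (minimum {min_stratum_n})"
            )
        if n < 2:
            warnings.warn(
                f"stratum {stratum.describe()}: {muscle.name}/{state.name} has a "
                f"single control; cell left unpopulated",
                stacklevel=2,
            )
            return None
        if method is CutoffMethod.EMPIRICAL_QUANTILE:
            cell_method = CutoffMethod.GAUSSIAN_PARAMETRIC
            warnings.warn(
                f"stratum {stratum.describe()}: n={n} < {min_stratum_n} for "
                f"{muscle.name}/{state.name}; falling back to GAUSSIAN_PARAMETRIC",
                stacklevel=2,
            )
    if cell_method is CutoffMethod.EMPIRICAL_QUANTILE:
        cutoff = _empirical_quantile(values, percentile)
    else:
        cutoff = _gaussian_cutoff(values, percentile)
    if cutoff <= 0:
        raise ReferenceError(
            f"computed non-positive cutoff {cutoff:.4f} for {muscle.name}/"
            f"{state.name} in stratum {stratum.describe()}"
        )
    return CutoffCell(cutoff_cm=cutoff, n=n, method=cell_method)
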