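"""Relative-age dating of TE amplification bursts.

A family cannot be dated absolutely from divergence alone without a
substitution rate, but two families in the *same* genome share that
rate. If a calibration family's expansion age is bracketed by
phylogenetic events — e.g. a family present across placentals but
essentially absent from marsupials must have expanded between the
marsupial/placental split (190 MYA) and the placental radiation
(~100 MYA) — then any other family in that genome is dated by scaling
the calibration window by the ratio of family divergences:

    age_bound = (d_family / d_calibration) * calibration_age_bound

A zero-width calibration window (a single "common ancestor" age) yields
an upper bound only ("the family expanded at most X MYA"). Independent
phylogenetic constraints (e.g. "a placental family cannot predate the
placental radiation") are applied afterwards as explicit caps, never
silently: a cap below the estimate's lower bound is an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "CalibrationWindow",
    "AgeEstimate",
    "estimate_age_range",
    "apply_constraint",
    "date_all",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CalibrationWindow:
    """Age bounds (MYA) for a calibration family in one genome.

    ``divergence_genome`` names the genome in which the calibration
    family's divergence was measured; it defaults to ``genome`` but may
    differ when a shared clade-wide rate is assumed (e.g. dating ant
    families against a calibration family observed in a third ant
    genome).
    """

    family: str
    genome: str
    age_min: float
    age_max: float
    rationale: str = ""
    divergence_genome: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.age_min <= self.age_max):
            raise ValueError("need 0 <= age_min <= age_max")

    @property
    def source_genome(self) -> str:
        return self.divergence_genome or self.genome

    @property
    def is_point(self) -> bool:
        return self.age_min == self.age_max

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.age_min + self.age_max)


@dataclass
class AgeEstimate:
    """A dated family: raw (unrounded) and reported integer MYA bounds."""

    family: str
    genome: str
    raw_min: float
    raw_max: float
    reported_min: int
    reported_max: int
    upper_bound_only: bool = False
    constraint_applied: Optional[float] = None

    def __post_init__(self) -> None:
        if self.raw_min > self.raw_max:
            raise ValueError("raw_min must not exceed raw_max")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.raw_min + self.raw_max)

    def describe(self) -> str:
        if self.upper_bound_only and self.constraint_applied is None:
            return f"at most ~{self.reported_max} MYA"
        return f"{self.reported_max} to {self.reported_min} MYA"


def estimate_age_range(d_family: float, d_calib: float, calib: CalibrationWindow) -> AgeEstimate:
    """Scale the calibration window by the divergence ratio.

    ``d_family`` and ``d_calib`` are family divergences in the same
    units (percent or substitutions/site — only their ratio matters).
    A point calibration (age_min == age_max) marks the result as an
    upper bound only.
    """
    if d_calib <= 0:
        raise ValueError("calibration divergence must be positive")
    if d_family < 0:
        raise ValueError("family divergence must be non-negative")
    ratio = d_family / d_calib
    raw_min = ratio * calib.age_min
    raw_max = ratio * calib.age_max
    return AgeEstimate(
        family="",
        genome=calib.genome,
        raw_min=raw_min,
        raw_max=raw_max,
        reported_min=round_half_up(raw_min),
        reported_max=round_half_up(raw_max),
        upper_bound_only=calib.is_point,
    )


def apply_constraint(est: AgeEstimate, cap: float) -> AgeEstimate:
    """Cap the reported upper bound at an external phylogenetic limit.

    The lower bound is untouched. A cap that excludes the whole estimate
    (cap < reported lower bound) is surfaced as an error rather than
    silently clipped.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if cap < est.reported_min:
        raise ValueError(
            f"constraint excludes estimate: cap {cap} MYA < lower bound {est.reported_min} MYA"
        )
    if est.reported_max <= cap:
        return est
    return AgeEstimate(
        family=est.family,
        genome=est.genome,
        raw_min=est.raw_min,
        raw_max=est.raw_max,
        reported_min=est.reported_min,
        reported_max=round_half_up(min(est.reported_max, cap)),
        upper_bound_only=est.upper_bound_only,
        constraint_applied=cap,
    )


def date_all(
    families: pd.DataFrame,
    calibrations: Mapping[str, CalibrationWindow],
    caps: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Date every observed family against its genome's calibration.

    ``families`` needs columns ``family``, ``genome``, ``divergence_pct``.
    Calibration rows themselves (the family named in the genome's
    :class:`CalibrationWindow`) are not dated. ``caps`` maps family name
    to an upper phylogenetic cap in MYA. Returns one row per dated
    (family, genome) with raw and reported bounds; deterministic.
    """
    caps = caps or {}
    required = {"family", "genome", "divergence_pct"}
    if not required <= set(families.columns):
        raise ValueError(f"families table needs columns {sorted(required)}")
    calib_sources = {(c.family, c.source_genome) for c in calibrations.values()}
    rows = []
    for _, row in families.iterrows():
        genome = row["genome"]
        if (row["family"], genome) in calib_sources:
            continue
        if genome not in calibrations:
            raise ValueError(f"no calibration for genome: {genome}")
        calib = calibrations[genome]
        if row["family"] == calib.family:
            continue
        src = calib.source_genome
        calib_rows = families[(families["family"] == calib.family) & (families["genome"] == src)]
        if calib_rows.empty:
            raise ValueError(f"calibration family {calib.family} has no divergence row in genome {src}")
        d_calib = float(calib_rows["divergence_pct"].iloc[0])
        est = estimate_age_range(float(row["divergence_pct"]), d_calib, calib)
        est.family = row["family"]
        if row["family"] in caps:
            est = apply_constraint(est, caps[row["family"]])
        rows.append(
            dict(
                family=est.family,
                genome=genome,
                raw_min=est.raw_min,
                raw_max=est.raw_max,
                reported_min=est.reported_min,
                reported_max=est.reported_max,
                upper_bound_only=est.upper_bound_only,
                constraint_applied=est.constraint_applied if est.constraint_applied is not None else float("nan"),
                reported=est.describe(),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family", "genome", "raw_min", "raw_max", "reported_min",
            "reported_max", "upper_bound_only", "constraint_applied", "reported",
        ],
    )
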