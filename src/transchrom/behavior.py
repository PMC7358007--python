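"""Behavioral statistics: probe-trial chance geometry, retained memory,
and transmission rate.

Water-maze probe trials score the fraction of time an animal spends in
a target zone; performance is judged against the geometric chance
level, i.e. the fraction of the arena the zone covers. For a circular
tank with the target defined as the largest circle inscribed in the
platform quadrant, that fraction is the closed form (sqrt(2) - 1)^2 =
3 - 2*sqrt(2) ~ 17%. For a square open field with a centered square
zone it is simply (zone_side / field_side)^2.

The retained-memory statistic quantifies forgetting in a
reversal-reference water maze: each animal's first-probe-day
time-in-old-target-zone is normalized to 100%, and later probe days are
expressed relative to it (values above 100% are possible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ArenaGeometry",
    "chance_level_circular",
    "chance_level_square",
    "retained_memory",
    "retained_memory_summary",
    "transmission_rate",
]


@dataclass(frozen=True)
class ArenaGeometry:
    """Arena and target-zone dimensions for chance-level computation."""

    shape: str  # circular_tank | square_field
    tank_diameter: float | None = None
    field_side: float | None = None
    zone_side: float | None = None

    def chance_level(self) -> float:
        if self.shape == "circular_tank":
            return chance_level_circular()
        if self.shape == "square_field":
            if self.field_side is None or self.zone_side is None:
                raise ValueError("square_field needs field_side and zone_side")
            return chance_level_square(self.field_side, self.zone_side)
        raise ValueError(f"unknown arena shape {self.shape!r}")


def chance_level_circular() -> float:
    """Fraction of a circular tank covered by the largest circle
    inscribed in one quadrant.

    The largest circle tangent to both bounding radii of a quarter-disc
    of radius R and to its arc has its center on the quadrant bisector
    at distance d from the tank center, with radius r = d/sqrt(2)
    (tangency to the radii) and d + r = R (tangency to the arc). Hence
    r = R/(1+sqrt(2)) = R(sqrt(2)-1) and the area fraction is
    (sqrt(2)-1)^2 = 3 - 2*sqrt(2) ~ 0.1716, i.e. the ~17% chance level.
    Dimensionless: independent of tank diameter.
    """
    return 3.0 - 2.0 * math.sqrt(2.0)


def chance_level_square(field_side: float, zone_side: float) -> float:
    """Area fraction of a centered square zone in a square field."""
    if field_side <= 0 or zone_side <= 0:
        raise ValueError("dimensions must be positive")
    if zone_side > field_side:
        raise ValueError("zone cannot exceed the field")
    return (zone_side / field_side) ** 2


def retained_memory(
    trials: pd.DataFrame, zone_label: str = "SE"
) -> pd.Series:
    """Per-day retained-memory percentages for one animal.

    ``trials`` holds one animal's probe trials (columns day,
    time_fraction_in_zone, zone_label). Day 1 is the baseline and is
    defined as 100%; day d is (fraction day d / fraction day 1) x 100.
    Scale-invariant in the fractions; a zero baseline is an error (the
    normalization is undefined), never an infinity.
    """
    t = trials[trials["zone_label"] == zone_label].sort_values("day")
    if t["day"].duplicated().any():
        raise ValueError("multiple trials per day; supply trial-1 rows only")
    days = t["day"].to_numpy()
    if len(days) == 0 or days[0] != 1:
        raise ValueError("day-1 baseline trial required")
    fractions = t["time_fraction_in_zone"].to_numpy(dtype=float)
    baseline = fractions[0]
    if baseline <= 0:
        raise ValueError("day-1 time-in-zone fraction must be positive")
    return pd.Series(fractions / baseline * 100.0, index=days, name="retained_pct")


def retained_memory_summary(
    trials: pd.DataFrame, zone_label: str = "SE"
) -> pd.DataFrame:
    """Group retained memory: per-animal normalization, then the mean
    and SEM across animals per day."""
    per_animal = (
        trials.groupby("animal_id", sort=True)
        .apply(retained_memory, zone_label=zone_label, include_groups=False)
    )
    # per_animal: rows animals, columns days
    mean = per_animal.mean(axis=0)
    sem = per_animal.sem(axis=0)
    return pd.DataFrame(
        {"day": mean.index, "mean_retained_pct": mean.values, "sem": sem.values}
    ).reset_index(drop=True)


def transmission_rate(
    n_offspring: int, n_positive: int, conf: float = 0.95
) -> dict:
    """Germline transmission of the extra chromosome.

    Returns the transmitted proportion, its Wilson interval, and the
    two-sided exact binomial p-value against the Mendelian expectation
    of 50% transmission.
    """
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    if not 0 <= n_positive <= n_offspring:
        raise ValueError("n_positive must be in [0, n_offspring]")
    ci_low, ci_high = proportion_confint(
        n_positive, n_offspring, alpha=1.0 - conf, method="wilson"
    )
    p_value = float(
        stats.binomtest(n_positive, n_offspring, 0.5, alternative="two-sided").pvalue
    )
    return {
        "proportion": n_positive / n_offspring,
        "ci_low": float(ci_low),
        "ci_high": float(ci_high),
        "p_value_vs_mendelian": p_value,
        "n_offspring": n_offspring,
    }
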