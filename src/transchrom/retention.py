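"""Mosaicism / chromosome-retention estimation from per-cell counts.

An engineered freely segregating chromosome may be lost in a subset of
cells (mosaicism). Scoring a fixed number of cells per tissue for the
chromosome (FISH, flow cytometry, or immunostaining) gives binomial
data; retention is the per-tissue detection proportion. Wilson score
intervals are used throughout because the observed proportions sit
near the p = 1 boundary where Wald intervals degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TissueRetention",
    "RetentionEstimate",
    "estimate_retention",
    "pool_retention",
    "test_mosaicism",
]


@dataclass(frozen=True)
class TissueRetention:
    """Cells scored and cells positive for the chromosome in one tissue."""

    tissue: str
    n_cells: int
    n_positive: int
    method: str = "FISH"  # FISH | FCM | IHC

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if not 0 <= self.n_positive <= self.n_cells:
            raise ValueError("n_positive must be in [0, n_cells]")


@dataclass(frozen=True)
class RetentionEstimate:
    """Point estimate and Wilson confidence bounds for a retention rate."""

    p_hat: float
    ci_low: float
    ci_high: float
    n_cells: int


def estimate_retention(obs: TissueRetention, conf: float = 0.95) -> RetentionEstimate:
    """Retention proportion with a Wilson score interval."""
    ci_low, ci_high = proportion_confint(
        obs.n_positive, obs.n_cells, alpha=1.0 - conf, method="wilson"
    )
    p_hat = obs.n_positive / obs.n_cells
    # guard against float fuzz at the k=0 / k=n boundaries
    return RetentionEstimate(
        p_hat=p_hat,
        ci_low=min(max(float(ci_low), 0.0), p_hat),
        ci_high=max(min(float(ci_high), 1.0), p_hat),
        n_cells=obs.n_cells,
    )


def pool_retention(
    observations: Sequence[TissueRetention], conf: float = 0.95
) -> tuple[RetentionEstimate, dict[str, RetentionEstimate]]:
    """Pooled retention over tissues plus the per-tissue estimates.

    Counts are summed across tissues before estimation (cells are
    treated as exchangeable draws at a common retention rate).
    """
    if not observations:
        raise ValueError("need at least one tissue observation")
    per_tissue = {o.tissue: estimate_retention(o, conf=conf) for o in observations}
    pooled = TissueRetention(
        tissue="pooled",
        n_cells=sum(o.n_cells for o in observations),
        n_positive=sum(o.n_positive for o in observations),
        method=observations[0].method,
    )
    return estimate_retention(pooled, conf=conf), per_tissue


def test_mosaicism(
    obs: TissueRetention, threshold: float = 0.9, alpha: float = 0.05
) -> dict:
    """Exact one-sided binomial test for retention below ``threshold``.

    Tests H0: p >= threshold against H1: p < threshold; the tissue is
    flagged mosaic-suspect when H0 is rejected at ``alpha``. With
    threshold 0 the alternative is empty and nothing is flagged.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if threshold == 0.0:
        return {"tissue": obs.tissue, "p_value": 1.0, "mosaic_suspect": False}
    p_value = float(
        stats.binomtest(
            obs.n_positive, obs.n_cells, threshold, alternative="less"
        ).pvalue
    )
    return {
        "tissue": obs.tissue,
        "p_value": p_value,
        "mosaic_suspect": p_value < alpha,
    }


# not a pytest case despite the statistical-test name
test_mosaicism.__test__ = False  # type: ignore[attr-defined]
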