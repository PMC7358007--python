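"""Transchromosome representation, deletion calling, and variant cross-check.

The transferred human chromosome arm is present in a single copy, so a
true deletion shows essentially zero read depth rather than the 50%
drop of a heterozygous deletion in a diploid genome. The caller
therefore thresholds median-normalized binned depth at a low fraction
(default 0.25) and reports maximal low-depth runs.

Coordinates: all public interfaces use 1-based inclusive base-pair
coordinates (as printed in genome browsers); BED output is 0-based
half-open via the converters in :mod:`transchrom.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "DeletionCall",
    "VariantRecord",
    "transchromosome_span",
    "normalize_depth",
    "call_deletions",
    "annotate_deletions",
    "classify_variants",
]


@dataclass
class DepthProfile:
    """Binned read depth along one chromosome.

    ``origin`` is the 1-based start of the first bin; bin ``i`` covers
    ``[origin + i*bin_size, origin + (i+1)*bin_size - 1]``.
    """

    chrom: str
    bin_size: int
    origin: int
    bin_counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_counts = np.asarray(self.bin_counts, dtype=float)
        if self.bin_counts.ndim != 1 or len(self.bin_counts) < 1:
            raise ValueError("bin_counts must be a non-empty 1-D sequence")
        if np.any(self.bin_counts < 0):
            raise ValueError("bin counts must be non-negative")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        return len(self.bin_counts)

    def bin_interval(self, i: int) -> tuple[int, int]:
        """1-based inclusive (start, end) of bin ``i``."""
        start = self.origin + i * self.bin_size
        return start, start + self.bin_size - 1


@dataclass
class DeletionCall:
    """One called deletion (bin-aligned, 1-based inclusive)."""

    chrom: str
    start: int
    end: int
    mean_normalized_depth: float
    n_bins: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant on the transchromosome."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    known: bool | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def transchromosome_span(start_bp: int, end_bp: int) -> tuple[int, int]:
    """Length of the arm in bp and rounded megabases.

    Returns ``end_bp - start_bp`` (the printed-coordinate difference)
    and that length divided by 1e6, rounded half-up to integer Mb. The
    characterized arm runs 13,021,348..46,691,226 giving 33,669,878 bp
    = 34 Mb.
    """
    length = end_bp - start_bp
    if length <= 0:
        raise ValueError("end_bp must exceed start_bp")
    mb = int(np.floor(length / 1e6 + 0.5))  # round half up
    return length, mb


def normalize_depth(profile: DepthProfile) -> DepthProfile:
    """Divide every bin by the median of positive-depth bins.

    After normalization the median of positive bins is exactly 1, so a
    single-copy region sits near 1 and deletions near 0 regardless of
    sequencing depth.
    """
    positive = profile.bin_counts[profile.bin_counts > 0]
    if len(positive) == 0:
        raise ValueError("cannot normalize an all-zero depth profile")
    med = float(np.median(positive))
    return DepthProfile(
        chrom=profile.chrom,
        bin_size=profile.bin_size,
        origin=profile.origin,
        bin_counts=profile.bin_counts / med,
    )


def call_deletions(
    profile: DepthProfile,
    threshold: float = 0.25,
    min_bins: int = 3,
    merge_gap_bins: int = 1,
) -> list[DeletionCall]:
    """Call deletions as maximal runs of low-depth bins.

    A bin is *low* if its normalized depth is strictly below
    ``threshold``. Consecutive low runs separated by at most
    ``merge_gap_bins`` non-low bins are merged; a merged run is reported
    if it contains at least ``min_bins`` low bins. Calls span from the
    first to the last low bin of the run, are sorted by start, and never
    overlap.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_bins < 1 or merge_gap_bins < 0:
        raise ValueError("min_bins >= 1 and merge_gap_bins >= 0 required")
    low = profile.bin_counts < threshold
    # maximal runs of low bins: (first_idx, last_idx)
    runs: list[list[int]] = []
    i = 0
    n = profile.n_bins
    while i < n:
        if low[i]:
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    # merge runs across small gaps
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap_bins:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    calls = []
    for first, last in merged:
        n_low = int(np.sum(low[first : last + 1]))
        if n_low < min_bins:
            continue
        start, _ = profile.bin_interval(first)
        _, end = profile.bin_interval(last)
        calls.append(
            DeletionCall(
                chrom=profile.chrom,
                start=start,
                end=end,
                mean_normalized_depth=float(
                    np.mean(profile.bin_counts[first : last + 1])
                ),
                n_bins=last - first + 1,
            )
        )
    return calls


def annotate_deletions(
    calls: Sequence[DeletionCall],
    annotation: pd.DataFrame,
    span_bp: int | None = None,
) -> dict:
    """Intersect deletion calls with the gene annotation.

    A gene is *deleted* iff its interval overlaps any call by at least
    one base pair (any-overlap convention; both in 1-based inclusive
    coordinates). Returns per-call gene lists and totals: numbers of
    deleted protein-coding and non-coding genes and the fraction of the
    transchromosome span covered by calls.

    ``span_bp`` defaults to the annotated extent (min start to max end).
    """
    for call in calls:
        mismatched = annotation.loc[annotation["chrom"] != call.chrom]
        if len(mismatched) and len(mismatched) == len(annotation):
            raise ValueError(
                f"coordinate-system mismatch: calls on {call.chrom!r}, "
                f"annotation on {annotation['chrom'].iloc[0]!r}"
            )
    if span_bp is None:
        if len(annotation):
            span_bp = int(annotation["end"].max() - annotation["start"].min() + 1)
        else:
            span_bp = 0

    starts = annotation["start"].to_numpy()
    ends = annotation["end"].to_numpy()
    per_call: list[list[str]] = []
    deleted_mask = np.zeros(len(annotation), dtype=bool)
    for call in calls:
        hit = (starts <= call.end) & (ends >= call.start)
        deleted_mask |= hit
        per_call.append(sorted(annotation.loc[hit, "gene_id"]))

    deleted = annotation.loc[deleted_mask]
    total_deleted_bp = sum(c.length for c in calls)
    return {
        "per_call_genes": per_call,
        "deleted_genes": sorted(deleted["gene_id"]),
        "n_deleted_pcg": int((deleted["biotype"] == "PCG").sum()),
        "n_deleted_npcg": int((deleted["biotype"] == "nonPCG").sum()),
        "fraction_span_deleted": (total_deleted_bp / span_bp) if span_bp else 0.0,
    }


def classify_variants(
    variants: Iterable[VariantRecord],
    known_catalog: Iterable[tuple[str, int, str, str]] | pd.DataFrame,
) -> tuple[dict[str, int], list[VariantRecord]]:
    """Label each variant known/novel by exact catalog key match.

    The catalog is keyed by (chrom, pos, ref, alt). Duplicate variant
    keys in the input are an error. Returns ``({'known': k, 'novel':
    m}, annotated_variants)``.
    """
    if isinstance(known_catalog, pd.DataFrame):
        keys = set(
            zip(
                known_catalog["chrom"],
                known_catalog["pos"].astype(int),
                known_catalog["ref"],
                known_catalog["alt"],
            )
        )
    else:
        keys = {(c, int(p), r, a) for c, p, r, a in known_catalog}

    seen: set[tuple[str, int, str, str]] = set()
    annotated: list[VariantRecord] = []
    counts = {"known": 0, "novel": 0}
    for v in variants:
        if v.key in seen:
            raise ValueError(f"duplicate variant key {v.key}")
        seen.add(v.key)
        is_known = v.key in keys
        counts["known" if is_known else "novel"] += 1
        annotated.append(
            VariantRecord(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, known=is_known)
        )
    return counts, annotated
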