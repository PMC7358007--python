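"""Format adapters: bedGraph, BED, TSV tables, VCF, truth JSON.

Coordinate conventions: public tables and printed coordinates are
1-based inclusive; BED and bedGraph files are 0-based half-open, with
explicit converters used at every boundary. All writers produce plain
text that round-trips through the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import DeletionCall, DepthProfile, VariantRecord
from .simulate import SyntheticTruth

__all__ = [
    "to_bed_interval",
    "from_bed_interval",
    "read_bedgraph",
    "write_bedgraph",
    "write_bed",
    "read_bed",
    "read_annotation",
    "write_annotation",
    "write_annotation_bed6",
    "read_counts",
    "write_counts",
    "read_library_sizes",
    "write_library_sizes",
    "read_vcf",
    "write_vcf",
    "read_known_catalog",
    "read_cells",
    "write_cells",
    "read_trials",
    "write_trials",
    "read_truth",
    "write_truth",
    "FormatError",
]


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def to_bed_interval(start_1: int, end_1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1 - 1, end_1


def from_bed_interval(start_0: int, end_0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start_0 + 1, end_0


# ---------------------------------------------------------------- depth


def write_bedgraph(profile: DepthProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, count in enumerate(profile.bin_counts):
            s1, e1 = profile.bin_interval(i)
            s0, e0 = to_bed_interval(s1, e1)
            fh.write(f"{profile.chrom}\t{s0}\t{e0}\t{count:.6g}\n")


def read_bedgraph(path: str | Path) -> DepthProfile:
    """Read a uniform-bin bedGraph back into a DepthProfile."""
    chroms, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                chroms.append(parts[0])
                starts.append(int(parts[1]))
                ends.append(int(parts[2]))
                values.append(float(parts[3]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    if not values:
        raise FormatError(f"{path}: empty bedGraph")
    if len(set(chroms)) != 1:
        raise FormatError(f"{path}: multiple chromosomes in one profile")
    widths = np.array(ends) - np.array(starts)
    bin_size = int(widths[0]) if len(widths) == 1 else int(widths[:-1].max())
    origin, _ = from_bed_interval(starts[0], ends[0])
    return DepthProfile(
        chrom=chroms[0],
        bin_size=bin_size,
        origin=origin,
        bin_counts=np.array(values),
    )


# ---------------------------------------------------------------- BED


def write_bed(calls: Sequence[DeletionCall], path: str | Path) -> None:
    """Deletion calls as BED4 with the mean normalized depth as score."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls, start=1):
            s0, e0 = to_bed_interval(c.start, c.end)
            fh.write(f"{c.chrom}\t{s0}\t{e0}\tdeletion_{i}\t{c.mean_normalized_depth:.6g}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Generic BED reader: chrom, start, end (1-based inclusive), name, score."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                s1, e1 = from_bed_interval(int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            rows.append(
                {
                    "chrom": parts[0],
                    "start": s1,
                    "end": e1,
                    "name": parts[3] if len(parts) > 3 else "",
                    "score": float(parts[4]) if len(parts) > 4 else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- annotation

_ANNOT_COLS = ["gene_id", "chrom", "start", "end", "biotype", "family", "ortholog_id", "length"]


def write_annotation(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=_ANNOT_COLS)


def read_annotation(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"ortholog_id": str}, keep_default_na=False)
    missing = set(_ANNOT_COLS) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    return table


def write_annotation_bed6(table: pd.DataFrame, path: str | Path) -> None:
    """Annotation as BED6 (0-based half-open, strand '.')."""
    with open(path, "w") as fh:
        for row in table.itertuples():
            s0, e0 = to_bed_interval(row.start, row.end)
            fh.write(f"{row.chrom}\t{s0}\t{e0}\t{row.gene_id}\t0\t.\n")


# ---------------------------------------------------------------- counts


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "length"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if not any(c.startswith("count_") for c in table.columns):
        raise FormatError(f"{path}: no count_<rep> columns")
    return table


def write_library_sizes(sizes: dict[str, float], path: str | Path) -> None:
    pd.Series(sizes, name="library_size").rename_axis("sample").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_library_sizes(path: str | Path) -> dict[str, float]:
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table["sample"], table["library_size"].astype(float)))


# ---------------------------------------------------------------- VCF

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(variants: Sequence[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read SNVs from an uncompressed VCF 4.x file.

    Records without an ALT allele (or that pysam cannot parse) raise
    :class:`FormatError` with the 1-based line number.
    """
    path = str(path)
    with open(path) as fh:
        n_header = sum(1 for line in fh if line.startswith("#"))
    variants: list[VariantRecord] = []
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable VCF ({exc})") from None
    with vf:
        for idx, rec in enumerate(vf.fetch()):
            lineno = n_header + idx + 1
            if not rec.alts:
                raise FormatError(f"{path}:{lineno}: record has no ALT allele")
            for alt in rec.alts:
                variants.append(
                    VariantRecord(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt)
                )
    return variants


def read_known_catalog(path: str | Path) -> pd.DataFrame:
    """Known-allele catalog TSV with columns chrom, pos, ref, alt."""
    table = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "ref", "alt"} - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing catalog columns {sorted(missing)}")
    return table


# ---------------------------------------------------------------- cells / trials


def write_cells(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"tissue", "detected"} - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing cell-table columns {sorted(missing)}")
    return table


def write_trials(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"animal_id", "day", "zone_label", "time_fraction_in_zone"} - set(
        table.columns
    )
    if missing:
        raise FormatError(f"{path}: missing trial columns {sorted(missing)}")
    return table


# ---------------------------------------------------------------- truth JSON


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth.from_dict(json.load(fh))
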