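"""Gene-dosage accounting for a single-copy human transchromosome.

In a trisomic-equivalent animal carrying one human chromosome arm on
top of the disomic mouse genome, the ideal expectation for any ortholog
pair is that total expression (human transgene + mouse ortholog) rises
to 1.5x the euploid mouse level. Three cis metrics quantify this per
pair, all on FPKM scale relative to the euploid ortholog F_m(Eu):

    R_h   = F_h(Tc) / F_m(Eu)          human contribution
    R_m   = F_m(Tc) / F_m(Eu)          ortholog response
    R_tot = (F_h(Tc) + F_m(Tc)) / F_m(Eu) = R_h + R_m   total dosage

Dosage classes band R_tot around 1.5 (low < 1.3, expected 1.3-1.7,
high > 1.7); the ortholog band checks R_m against 80-120% of euploid.
Genome-wide trans-effects are threshold counts of host genes with
Tc/Eu FPKM ratio < 0.8 (down) or > 1.2 (up) among genes expressed at
FPKM >= 1 in euploid. Strict/closed boundaries follow the printed
inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_fpkm",
    "assign_expression_tier",
    "filter_expressed",
    "compute_dosage_ratios",
    "classify_dosage",
    "classify_ortholog_band",
    "count_dysregulated",
    "validate_deleted_silence",
    "validation_correlation",
    "fpkm_table",
    "dosage_records",
    "summarize_dosage",
    "DosageRecord",
]

EXPRESSION_FILTER_FPKM = 1.0


@dataclass
class DosageRecord:
    """Per ortholog pair: FPKM values, ratio metrics, and classes."""

    human_gene_id: str
    mouse_ortholog_id: str
    f_h_tc: float
    f_m_tc: float
    f_m_eu: float
    r_h: float
    r_m: float
    r_tot: float
    dosage_class: str
    ortholog_band: str


def compute_fpkm(count, length_bp, library_size):
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM = count * 1e9 / (length_bp * library_size). Accepts scalars or
    arrays (broadcast).
    """
    length_bp = np.asarray(length_bp, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("gene length must be positive")
    if np.any(library_size <= 0):
        raise ValueError("library size must be positive")
    out = np.asarray(count, dtype=float) * 1e9 / (length_bp * library_size)
    return float(out) if out.ndim == 0 else out


def assign_expression_tier(fpkm: float) -> str:
    """Tier a gene by expression: off (<= 0.5), medium (0.5, 5], high (> 5)."""
    if fpkm < 0:
        raise ValueError("FPKM must be non-negative")
    if fpkm > 5.0:
        return "high"
    if fpkm > 0.5:
        return "medium"
    return "off"


def filter_expressed(
    eu_fpkm: pd.Series | dict, min_fpkm: float = EXPRESSION_FILTER_FPKM
) -> set[str]:
    """Genes whose mean euploid FPKM is >= min_fpkm (inclusive)."""
    if isinstance(eu_fpkm, dict):
        eu_fpkm = pd.Series(eu_fpkm)
    return set(eu_fpkm.index[eu_fpkm >= min_fpkm])


def compute_dosage_ratios(
    f_h_tc: float,
    f_m_tc: float,
    f_m_eu: float,
    min_fpkm: float = EXPRESSION_FILTER_FPKM,
) -> tuple[float, float, float]:
    """The three cis ratio metrics (R_h, R_m, R_tot) for one pair.

    The euploid-ortholog denominator must pass the expression filter;
    an unfiltered (near-zero) denominator is an error, never infinity.
    The identity R_tot = R_h + R_m holds exactly by construction.
    """
    if f_m_eu < min_fpkm:
        raise ValueError(
            f"euploid ortholog FPKM {f_m_eu} below expression filter "
            f"{min_fpkm}; ratios undefined"
        )
    r_h = f_h_tc / f_m_eu
    r_m = f_m_tc / f_m_eu
    return r_h, r_m, r_h + r_m


def classify_dosage(r_tot: float) -> str:
    """Band the total-dosage ratio: low < 1.3 <= expected <= 1.7 < high."""
    if r_tot < 0:
        raise ValueError("R_tot must be non-negative")
    if r_tot < 1.3:
        return "low"
    if r_tot <= 1.7:
        return "expected"
    return "high"


def classify_ortholog_band(r_m: float) -> str:
    """Band the ortholog response: reduced < 0.8 <= within_80_120 <= 1.2 < elevated."""
    if r_m < 0:
        raise ValueError("R_m must be non-negative")
    if r_m < 0.8:
        return "reduced"
    if r_m <= 1.2:
        return "within_80_120"
    return "elevated"


def fpkm_table(counts: pd.DataFrame, library_sizes: dict[str, float]) -> pd.Series:
    """Mean FPKM per gene over the replicate count columns of a table.

    ``counts`` needs columns gene_id, length and one ``count_<rep>``
    column per replicate; ``library_sizes`` maps each count column's
    sample key (e.g. ``Eu_1``) to its total mapped fragments, matched by
    replicate suffix order.
    """
    count_cols = [c for c in counts.columns if c.startswith("count_")]
    if not count_cols:
        raise ValueError("no count_<rep> columns found")
    keys = sorted(library_sizes)
    if len(keys) != len(count_cols):
        raise ValueError(
            f"{len(count_cols)} count columns but {len(keys)} library sizes"
        )
    fpkms = np.column_stack(
        [
            compute_fpkm(
                counts[col].to_numpy(),
                counts["length"].to_numpy(),
                library_sizes[key],
            )
            for col, key in zip(sorted(count_cols), keys)
        ]
    )
    return pd.Series(fpkms.mean(axis=1), index=counts["gene_id"].to_numpy())


def dosage_records(
    pairs: pd.DataFrame,
    f_h_tc: pd.Series,
    f_m_tc: pd.Series,
    f_m_eu: pd.Series,
    min_fpkm: float = EXPRESSION_FILTER_FPKM,
    exclude: set[str] | None = None,
) -> list[DosageRecord]:
    """Build dosage records for every pair passing the expression filter.

    ``pairs`` needs columns gene_id (human) and ortholog_id (mouse);
    the FPKM series are indexed by the respective gene ids. KRTAP-family
    pairs should be excluded upstream (they are never expressed), and
    human genes lost to deletions belong in ``exclude``: the dosage
    bands describe intact genes, a deleted gene sits trivially at
    R_tot ~ 1.
    """
    exclude = exclude or set()
    records = []
    for row in pairs.itertuples():
        if row.gene_id in exclude:
            continue
        fme = float(f_m_eu.get(row.ortholog_id, 0.0))
        if fme < min_fpkm:
            continue
        fht = float(f_h_tc.get(row.gene_id, 0.0))
        fmt = float(f_m_tc.get(row.ortholog_id, 0.0))
        r_h, r_m, r_tot = compute_dosage_ratios(fht, fmt, fme, min_fpkm=min_fpkm)
        records.append(
            DosageRecord(
                human_gene_id=row.gene_id,
                mouse_ortholog_id=row.ortholog_id,
                f_h_tc=fht,
                f_m_tc=fmt,
                f_m_eu=fme,
                r_h=r_h,
                r_m=r_m,
                r_tot=r_tot,
                dosage_class=classify_dosage(r_tot),
                ortholog_band=classify_ortholog_band(r_m),
            )
        )
    return records


def summarize_dosage(records: list[DosageRecord]) -> dict:
    """Class proportions, 80-120% band count, and pair count."""
    n = len(records)
    classes = pd.Series([r.dosage_class for r in records])
    bands = pd.Series([r.ortholog_band for r in records])
    props = {
        c: (float((classes == c).sum()) / n if n else 0.0)
        for c in ("low", "expected", "high")
    }
    return {
        "n_pairs": n,
        "dosage_class_proportions": props,
        "n_within_80_120": int((bands == "within_80_120").sum()),
        "n_reduced": int((bands == "reduced").sum()),
        "n_elevated": int((bands == "elevated").sum()),
    }


def count_dysregulated(
    eu_fpkm: pd.Series,
    tc_fpkm: pd.Series,
    min_fpkm: float = EXPRESSION_FILTER_FPKM,
    low: float = 0.8,
    high: float = 1.2,
) -> dict[str, int]:
    """Genome-wide trans-effect counts over host genes.

    Tested genes are those with euploid FPKM >= min_fpkm; a tested gene
    counts down if Tc/Eu < low (strict) and up if Tc/Eu > high
    (strict). The inputs must contain host-genome genes only.
    """
    common = eu_fpkm.index.intersection(tc_fpkm.index)
    eu = eu_fpkm.loc[common]
    tc = tc_fpkm.loc[common]
    tested = eu >= min_fpkm
    ratio = tc[tested] / eu[tested]
    return {
        "n_tested": int(tested.sum()),
        "n_down": int((ratio < low).sum()),
        "n_up": int((ratio > high).sum()),
        "down_genes": sorted(ratio.index[ratio < low]),
        "up_genes": sorted(ratio.index[ratio > high]),
    }


def validate_deleted_silence(
    f_h_tc: pd.Series,
    deleted_genes: set[str],
    max_fpkm: float = 0.5,
) -> dict:
    """Check that human genes in deleted regions are transcriptionally silent.

    Flags every deleted gene whose trisomic human FPKM exceeds
    ``max_fpkm``. Returns a pass/fail report with the violating genes.
    """
    violations = sorted(
        g
        for g in deleted_genes
        if float(f_h_tc.get(g, 0.0)) > max_fpkm
    )
    return {
        "passed": not violations,
        "n_checked": len(deleted_genes),
        "violations": violations,
    }


def validation_correlation(ct_values, fpkm_values) -> float:
    """Pearson r between RT-PCR CT values and log10(FPKM).

    CT is inversely related to transcript abundance, so a faithful
    quantification gives a strong negative correlation; the coefficient
    is returned as computed (magnitude is what is compared).
    """
    ct = np.asarray(ct_values, dtype=float)
    fpkm = np.asarray(fpkm_values, dtype=float)
    if len(ct) != len(fpkm):
        raise ValueError("CT and FPKM vectors must be paired")
    if len(ct) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any(fpkm <= 0):
        raise ValueError("FPKM values must be positive for log10")
    log_fpkm = np.log10(fpkm)
    if np.std(ct) == 0 or np.std(log_fpkm) == 0:
        raise ValueError("zero variance in CT or log10(FPKM)")
    r, _ = stats.pearsonr(ct, log_fpkm)
    return float(r)
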