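import numpy as np
import pytest

from transchrom.simulate import (
    SimulationConfig,
    generate_annotation,
    generate_expression_counts,
)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down configuration for fast end-to-end tests."""
    return SimulationConfig(
        seed=7,
        n_pcg=60,
        n_npcg=80,
        n_krtap=10,
        n_host_genes=500,
        n_tissues=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Annotation + truth + count tables for the scaled-down config."""
    annotation, truth = generate_annotation(small_config)
    eu, tc, libs = generate_expression_counts(small_config, annotation, truth)
    return {
        "config": small_config,
        "annotation": annotation,
        "truth": truth,
        "eu": eu,
        "tc": tc,
        "libs": libs,
    }


def per_base_deleted_oracle(annotation, deletions):
    """Brute-force per-base overlap: a gene is deleted iff any of its
    bases falls in a planted deletion (1-based inclusive)."""
    deleted_bases = set()
    for s, e in deletions:
        deleted_bases.update(range(s, e + 1))
    out = set()
    for row in annotation.itertuples():
        if any(b in deleted_bases for b in range(row.start, row.end + 1)):
            out.add(row.gene_id)
    return out


def run_scan_oracle(depth, threshold, min_bins, merge_gap_bins):
    """Independent deletion-caller oracle on normalized depth values.

    Groups the indices of sub-threshold bins wherever consecutive low
    indices are separated by at most merge_gap_bins high bins, and
    keeps groups with at least min_bins low bins. Returns (first_bin,
    last_bin) index pairs.
    """
    low_idx = [i for i, d in enumerate(depth) if d < threshold]
    groups = []
    for i in low_idx:
        if groups and i - groups[-1][-1] - 1 <= merge_gap_bins:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [(g[0], g[-1]) for g in groups if len(g) >= min_bins]


def wilson_interval_oracle(k, n, conf=0.95):
    """Textbook Wilson score interval closed form."""
    from scipy.stats import norm

    z = norm.ppf(1 - (1 - conf) / 2)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def binom_tail_oracle(k, n, p, alternative):
    """Exact binomial tail by direct pmf summation."""
    from scipy.stats import binom

    pmf = binom.pmf(np.arange(n + 1), n, p)
    if alternative == "less":
        return float(pmf[: k + 1].sum())
    if alternative == "greater":
        return float(pmf[k:].sum())
    # two-sided: sum of outcomes no more probable than the observed one
    return float(pmf[pmf <= pmf[k] * (1 + 1e-12)].sum())
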