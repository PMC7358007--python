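# Methods

`transchrom` characterizes a transchromosomic mouse model — an animal
carrying one freely segregating copy of a human chromosome arm on a
mouse-artificial-chromosome vector — from four kinds of evidence:
binned whole-genome read depth (deletion mapping), bulk RNA-seq counts
(cis dosage and trans dysregulation), per-cell chromosome detection
(mosaicism), and water-maze probe trials (memory statistics). Every
stage is exercised against a synthetic-data generator that plants
ground truth, so the pipeline's recovery properties are testable
without the original sequencing data.

## Deletion mapping

The transferred arm is single-copy, so a genuine deletion removes all
template and depth falls to a mismapping background, not to the 50%
of a heterozygous diploid deletion. Depth is binned (default 10 kb),
divided by the median of positive bins (so single-copy coverage sits
at 1 regardless of sequencing depth), and scanned for maximal runs of
bins below a threshold:

* `threshold = 0.25` — far below single-copy depth, far above the
  simulated 2% mismapping background; tolerant of moderate noise.
* `min_bins = 3` — suppresses single-bin dropouts (mappability holes).
* `merge_gap_bins = 1` — bridges an isolated high bin inside a
  deletion (e.g. a repeat attracting mismapped reads).

Calls span the first to last low bin and are therefore bin-aligned; a
breakpoint is only known to bin resolution. A gene counts as deleted
if it overlaps any call by at least one base pair (any-overlap
convention, 1-based inclusive intervals; an abutting gene is not
deleted). Any-overlap is deliberately conservative: a gene losing even
terminal exons is unlikely to yield a functional transcript.

Coordinates: all public interfaces use 1-based inclusive coordinates
as printed in genome browsers; BED/bedGraph files are 0-based
half-open, converted explicitly in `transchrom.io`. The span helper
returns `end − start` for printed coordinate pairs (the convention
used for the 33,669,878 bp arm) with megabases rounded half-up; the
simulator's internal inclusive span is one base larger.

## Dosage accounting

For a human gene *h* with mouse ortholog *m*, with FPKM
`F = count · 10⁹ / (length · library_size)` averaged over replicates
per genotype (Tc = transchromosomic, Eu = euploid):

    R_h   = F_h(Tc) / F_m(Eu)
    R_m   = F_m(Tc) / F_m(Eu)
    R_tot = (F_h(Tc) + F_m(Tc)) / F_m(Eu) = R_h + R_m

The single-extra-copy expectation is R_tot = 1.5. Bands follow the
printed inequalities literally: dosage class low < 1.3 ≤ expected ≤
1.7 < high; ortholog band reduced < 0.8 ≤ within ≤ 1.2 < elevated
(closed middle intervals — the open-ended inequalities are strict, so
the endpoints fall inward). Expression tiers: off ≤ 0.5 < medium ≤ 5 <
high (FPKM).

Ratios are computed only for pairs whose euploid ortholog passes the
expression filter (mean Eu FPKM ≥ 1, inclusive); an unfiltered
denominator raises an error rather than producing an infinity, and no
pseudocounts are used. Replicates are averaged per genotype before
ratios (the per-replicate path exists in `fpkm_table` by passing
single-sample library maps). Deleted human genes are excluded from the
class analysis — the bands describe intact genes; a deleted gene sits
trivially at R_tot ≈ 1 — and are instead checked by
`validate_deleted_silence` (any deleted gene with trisomic FPKM > 0.5
is a violation). KRTAP-family genes are excluded from pair analysis
via the annotation family tag (the cluster is silent in brain).

Genome-wide trans-effects are threshold counts, not hypothesis tests:
among host genes with Eu FPKM ≥ 1, down if Tc/Eu < 0.8 and up if
Tc/Eu > 1.2, strict. No multiple-testing machinery is appropriate or
used. With noisy counts these strict thresholds necessarily pick up
some neutral genes near the boundaries; counts are exact when
measurement dispersion is zero.

## Retention / mosaicism

Per-tissue cell scoring is modeled as binomial. The estimator is the
sample proportion with a Wilson score interval (default 95%): near the
p → 1 boundary where these data live, the Wald interval collapses to
zero width at p̂ = 1 while Wilson remains sensible. Pooling sums
counts across tissues before estimating (cells exchangeable at a
common rate). The mosaicism screen is an exploratory exact one-sided
binomial test of p < 0.9 per tissue at α = 0.05; "≥96% retention" is
interpreted as the minimum across tissues, which the report exposes as
`min_tissue_p_hat`.

## Behavioral statistics

*Chance levels.* For a circular tank with the target zone defined as
the largest circle inscribed in the platform quadrant: the zone circle
is tangent to both bounding radii (center on the bisector, radius
r = d/√2 at center distance d) and to the arc (d + r = R), giving
r = R(√2−1) and area fraction (√2−1)² = 3−2√2 ≈ 0.1716 → 17%. For a
square field with a centered square zone, (zone/field)²; 21.6 cm in
37 cm gives 34.1%.

*Retained memory.* Per animal, the day-1 probe fraction in the old
target zone is the 100% baseline; day d is (fraction_d / fraction_1) ×
100, which may exceed 100%. Normalization is per animal, then averaged
across the group (mean ± SEM). A zero baseline is an error by
construction; the generator resamples such animals. The statistic is
scale-invariant in the fractions.

*Transmission.* Offspring carrying the chromosome out of total, with
Wilson interval and a two-sided exact binomial test against the
Mendelian 50% expectation for a freely segregating element.

## Synthetic-data generator

Defaults are the study conditions: arm 13,021,348–46,691,226 bp
(~33.7 Mb); 213 protein-coding genes (49 in a contiguous silent KRTAP
block) and 487 non-coding genes placed uniformly without overlap; four
planted deletions totalling 9.8 Mb (~29% of the arm), breakpoints
aligned to the 10 kb bin grid; 160/164 non-KRTAP coding genes given a
mouse ortholog; two replicates per genotype at 30 M mapped fragments;
200 cells per tissue in 5 tissues at 96% retention.

Count model: negative binomial with var = μ + αμ², the standard bulk
RNA-seq choice, with α = 0.01 for expression (chosen so the ortholog
Tc/Eu ratio has log-sd ≈ 0.1, reproducing the observed tightness of
the 80–120% band, ~9 of 10 pairs within) and α = 0.005 for depth
(per-bin CV ≈ 7.5% at 1700 reads per 10 kb bin, ≈25× coverage with
150 bp reads). α = 0 is the deterministic limit — counts equal rounded
means — so zero-noise recovery tests are exact rather than
approximate. Depth inside deletions is Poisson at 2% of the normal
mean (mismapping background); at zero noise it is exactly 0.

Baseline euploid ortholog expression is log-normal (log₂ FPKM ~
N(2, 3)), putting ~75% of pairs past the FPKM ≥ 1 filter, matching the
expressed fraction of ortholog pairs. The per-pair total-dosage target
is log-normal with median 1.5 and log-sd 0.35, reproducing the
heavy two-sided spread around the 1.5× expectation (~34/30/36% band
occupancy); draws below 1 are clipped to 1 (the extra copy cannot
subtract expression), and the human mean is (R_tot − 1) × ortholog
mean. Host genes are simulated as the *tested* universe (13,976 genes
with Eu FPKM ≥ 1, truncated ≥ 1.25 so noise cannot cross the filter);
planted down/up fractions 712/13976 and 1191/13976 with scale factors
drawn strictly inside (0.40, 0.75) and (1.30, 2.50) so zero-noise
recovery is exact.

All randomness flows from one seed through named per-stage substreams
(annotation, depth, expression, cells, trials), so identical configs
produce byte-identical outputs and individual stages can be re-run in
isolation.

What the generator does **not** emulate: read-level data (no
sequences, mappability structure, or GC bias — depth is drawn per
bin), clustered gene positions (placement is uniform apart from the
KRTAP block, so the real model's "deletions fall in gene-poor regions"
geometry is not reproduced — deleted-gene counts here scale with
deleted span), correlated expression between neighbors, compositional
effects of the transgene on library size, and tissue heterogeneity in
retention. Passing tests therefore demonstrate correctness of the
estimators and callers under the stated stochastic model, not
robustness to real-data artifacts such as mappability holes or batch
effects.

## Numerical choices and degenerate inputs

* Median normalization uses positive bins only; an all-zero profile is
  an error.
* Wilson bounds are clamped to [0, 1] and to contain p̂ (statsmodels
  can return a lower bound of ~5e-17 at k = 0).
* Dosage ratios with an unfiltered denominator, negative inputs to
  classifiers, zero-variance inputs to the CT–FPKM correlation, n < 3
  correlation samples, zero probe-trial baselines, and infeasible gene
  packing all raise `ValueError` rather than returning NaN/inf.
* Megabase rounding is half-up (floor(x + 0.5)).
* Pipeline reports are JSON with sorted keys and rounded floats, so
  determinism is byte-level.

## Problem sizes

Default simulations (3,367 depth bins, ~14k genes, 700-gene
annotation) run in well under a second; the test suite uses the
defaults where a property demands them (planted-deletion recovery,
dosage calibration at 2,000 pairs, Wilson coverage over 2,000
replicate tissues) and a scaled-down configuration (140 genes, 400
host genes, 3 tissues) for end-to-end determinism and CLI contracts.

## Known limitations

* Deletion boundaries are bin-aligned; sub-bin breakpoints are
  systematically widened to the enclosing bins.
* The caller assumes a mostly single-copy profile; if more than ~half
  of bins were deleted, median normalization would misanchor.
* Trans-effect threshold counts are biased upward by measurement noise
  (boundary leakage), exactly as raw threshold counts on real data
  are; they are exact only in the zero-dispersion limit.
* The mosaicism test controls per-tissue error only; no multiplicity
  correction across tissues, as the screen is exploratory.
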