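"""Cross-check transchromosome SNVs against a known-allele catalog.

Builds 91 synthetic single-nucleotide variants, 90 of which appear in
the catalog of previously reported alternative alleles, and classifies
each by exact (chrom, pos, ref, alt) match.
"""

import numpy as np
import pandas as pd

from transchrom.genome import VariantRecord, classify_variants

rng = np.random.default_rng(1)
positions = sorted(rng.choice(np.arange(13_021_348, 46_691_226), 91, replace=False))
variants = [VariantRecord("HSA21q", int(p), "C", "A") for p in positions]

# catalog of previously reported alleles: all but one variant
catalog = pd.DataFrame(
    {
        "chrom": "HSA21q",
        "pos": [v.pos for v in variants[:-1]],
        "ref": "C",
        "alt": "A",
    }
)

counts, annotated = classify_variants(variants, catalog)
print(f"{counts['known']} of {len(variants)} SNVs previously reported; "
      f"{counts['novel']} novel")
for v in annotated:
    if not v.known:
        print(f"novel variant: {v.chrom}:{v.pos:,} {v.ref}>{v.alt}")
# Nearly all variants matching native alternative alleles indicates the
# transferred chromosome is intact apart from normal polymorphism.
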