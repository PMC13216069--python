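"""Tn5 insertion offset schemes and variant effect prediction.

First simulates fragments sharing transposition events and compares the
+4/-4 and legacy +4/-5 offset schemes: under the standard 0-based
end-exclusive convention only +4/-4 maps both mates of one event to a
single consensus insertion site.  Then scores a single-nucleotide variant
that completes a planted motif match.
"""

import math

import numpy as np

from motifsyntax import PlantedModel, make_background_library, simulate_fragments, variant_effect
from motifsyntax.io import mate_consistency_check

rng = np.random.default_rng(5)
centers, c = [], 500
for _ in range(1_002):
    c += int(rng.integers(20, 120))
    centers.append(c)
fragments, _ = simulate_fragments([("chr1", x, "cell0") for x in centers])

for scheme in ("+4/-4", "+4/-5"):
    diffs = mate_consistency_check(fragments, scheme=scheme)
    print(f"scheme {scheme}: mate mismatch = {diffs.mean():.1f} bp "
          f"(constant: {diffs.min()}..{diffs.max()}, n={len(diffs)})")

# variant effect: an A>T substitution completes GATAACCG (+0.5 log counts)
model = PlantedModel(baseline=2.0, motif_effects={"GATAACCG": 0.5},
                     window_length=2114, n_folds=5, seed=3)
bg = make_background_library(n=1, length=2114, gc_target=0.5, tolerance=0.05,
                             forbidden_motifs=["GATAACCG"], seed=4).sequences[0]
broken = "GATTACCG"  # one base off the consensus
seq = bg[:1053] + broken + bg[1061:]
ve = variant_effect(model, seq, 1056, "T", "A", variant_id="rs_example")

print(f"variant {ve.variant_id}: log2 FC of total counts = {ve.log2fc_counts:.4f} "
      f"(expected 0.5/ln2 = {0.5 / math.log(2):.4f})")
print(f"count difference in 100-bp window = {ve.delta_counts_100bp:.2f}")
# The legacy scheme leaves a constant 1-bp mate mismatch; the variant that
# completes the planted motif raises predicted counts by the planted effect,
# 0.5 natural-log units = 0.72 in log2.
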