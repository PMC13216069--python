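"""Detect planted motif synergy by in silico marginalization.

Builds a planted accessibility model in which two 8-bp motifs act
additively everywhere except at one hard arrangement (A plus-strand, B
minus-strand, 5 bp apart, +0.4 log counts), marginalizes the pair over all
orientations and gaps against 100 GC-matched backgrounds, and classifies
the composite.
"""

from motifsyntax import (
    InteractionRule,
    PlantedModel,
    classify_composite,
    make_background_library,
    marginalize_pair,
)

A, B = "GATAACCG", "CCGGTAAT"

model = PlantedModel(
    baseline=2.0,
    motif_effects={A: 0.5, B: 0.7},
    interactions=[InteractionRule(A, B, "hard", 0.4, orientation="A+B-", gap=5)],
    fold_jitter_sd=0.05,
    window_length=2114,
    n_folds=5,
    seed=1,
)
library = make_background_library(
    n=100, length=2114, gc_target=0.5, tolerance=0.05,
    forbidden_motifs=[A, B], seed=2,
)

table = marginalize_pair(model, library, A, B, gaps=range(0, 201, 5))
call = classify_composite(table, composite_id=f"{A}_{B}")

print(f"records in effect table : {len(table)}")
print(f"optimal arrangement     : {call.orientation} at gap {call.gap} bp "
      f"(centre distance {call.center_distance:.1f} bp)")
print(f"mean dJ - dS at optimum : {call.mean_diff:.3f} log counts")
print(f"adjusted P (Wilcoxon)   : {call.p_adj:.2e}")
print(f"max arrangement z-score : {call.z_max:.1f}")
print(f"classification          : {call.class_label}")
# The optimum matches the planted (A+B-, 5); the excess over the
# log-additive expectation (~0.4) is the planted interaction magnitude, and
# the z-score far above 4 marks the spike as hard syntax.
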