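"""Directional eQTL enrichment in positive vs negative motif instances.

Simulates fine-mapped variant-gene pairs whose effect directions follow the
planted motif polarities perfectly (variants in accessibility-promoting
motifs downregulate expression; variants in accessibility-reducing motifs
upregulate it), then recovers the directional enrichment by aFC shuffling
and summarizes with a two-sided Fisher meta-test.
"""

import numpy as np

from motifsyntax import (
    MotifInstance,
    fisher_meta,
    permutation_enrichment,
    simulate_eqtl_table,
)

instances, polarity = [], {}
for k in range(3):
    instances.append(MotifInstance("chr1", 1_000 * (k + 1), 1_000 * (k + 1) + 10,
                                   "+", f"POS{k}", 0.95))
    polarity[f"POS{k}"] = "positive"
    instances.append(MotifInstance("chr1", 20_000 + 1_000 * k, 20_010 + 1_000 * k,
                                   "+", f"NEG{k}", 0.95))
    polarity[f"NEG{k}"] = "negative"

pairs = simulate_eqtl_table(
    instances, polarity, n_variants=500, frac_in_instances=0.6,
    direction_fidelity=1.0, seed=11,
)
result = permutation_enrichment(pairs, instances, polarity,
                                n_shuffles=10_000, seed=13)

sig = result[result["significant"]]
print(sig[["label", "polarity", "direction", "observed",
           "enrichment_score", "p", "fdr"]].to_string(index=False))

# meta-test: enriched-for-down vs enriched-for-up among positive motifs
pos = result[result["polarity"] == "positive"]
table = [
    [int(((pos["direction"] == "down") & pos["significant"]).sum()),
     int(((pos["direction"] == "down") & ~pos["significant"]).sum())],
    [int(((pos["direction"] == "up") & pos["significant"]).sum()),
     int(((pos["direction"] == "up") & ~pos["significant"]).sum())],
]
p, odds = fisher_meta(table)
print(f"positive-motif meta-test: P={p:.3g}, OR={odds}")
# At full fidelity every positive motif is enriched only for downregulating
# variants and every negative motif only for upregulating ones, mirroring
# the expected coupling between accessibility effects and expression.
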