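"""Call motif instances from a contribution track and footprint them.

Plants two motif-shaped bumps in a per-base contribution track, recovers
them with the greedy hit caller, deduplicates overlapping calls, then
simulates dense Tn5 fragments with a protected (insertion-free) span at one
instance and plots its footprint depth.
"""

import numpy as np

from motifsyntax import (
    dedup_overlaps,
    footprint_metaplot,
    greedy_hit_caller,
    simulate_fragments,
)

rng = np.random.default_rng(0)
cwm_a = rng.normal(size=(4, 6))
cwm_b = rng.normal(size=(4, 7))

track = np.zeros((4, 300))
track[:, 40:46] = 1.5 * cwm_a
track[:, 200:207] = cwm_b

hits = greedy_hit_caller(track, {"motifA": cwm_a, "motifB": cwm_b},
                         min_similarity=0.9, chrom="chr1")
hits = dedup_overlaps(hits)
for h in hits:
    print(f"hit: {h.label:7s} {h.chrom}:{h.start}-{h.end} ({h.strand}) "
          f"r={h.hit_correlation:.3f}")

# footprint: uniform insertions everywhere except a protected 20-bp core
chrom_len = 60_000
centers = rng.integers(500, chrom_len - 500, size=80_000)
protected = (29_990, 30_010)
events = [("chr1", int(c), f"bc{i % 64}") for i, c in enumerate(centers)
          if not protected[0] <= c < protected[1]]
_, tracks = simulate_fragments(events)

from motifsyntax import MotifInstance
anchor = [MotifInstance("chr1", 29_995, 30_005, "+", "motifA", 0.95)]
profile = footprint_metaplot(tracks, anchor)
flank = np.concatenate([profile[:50], profile[-50:]]).mean()
print(f"footprint flank level  : {flank:.2f} (normalized)")
print(f"footprint core level   : {profile[245:255].mean():.2f}")
# The two planted bumps are recovered at their exact coordinates with
# correlation ~1; the protected span shows up as a central dip (~0) against
# flanks normalized to ~1 — the classic bound-factor footprint shape.
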