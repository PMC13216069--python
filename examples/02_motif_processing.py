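"""Trim a contribution weight matrix and extract its consensus.

Builds a 10-position motif whose flanks carry little contribution, trims at
30% of the maximum per-position total, converts the PPM to counts, and
compares the motif to its own reverse complement.
"""

import numpy as np

from motifsyntax import (
    Motif,
    cwm_similarity,
    ppm_to_pfm,
    reverse_complement,
    trim_cwm,
)

consensus = "AGATAAGA"
L = len(consensus) + 2
cwm = np.zeros((4, L))
for j, base in enumerate(consensus):
    cwm["ACGT".index(base), j + 1] = 0.6
cwm[:, 0] = 0.02   # weak flanks fall below the 30% threshold
cwm[:, -1] = 0.03
ppm = np.full((4, L), 0.1)
for j, base in enumerate(consensus):
    ppm["ACGT".index(base), j + 1] = 0.7
ppm /= ppm.sum(axis=0, keepdims=True)

motif = Motif(label="GATA-like", cwm=cwm, ppm=ppm, n_seqlets=500)
trimmed = trim_cwm(motif, frac=0.3)

print(f"parent length          : {motif.length} positions")
print(f"trimmed span           : offset {trimmed.offset}, length {trimmed.length}")
print(f"consensus              : {trimmed.consensus}")
print(f"PFM column totals      : {ppm_to_pfm(trimmed.ppm, motif.n_seqlets).sum(axis=0)[0]:.0f} seqlets")
sim = cwm_similarity(trimmed.cwm, reverse_complement(trimmed.cwm))
print(f"self vs reverse comp.  : r={sim.correlation:.3f} on strand '{sim.strand}'")
# Trimming removes only the weak flanks; the consensus is the planted core,
# and the motif matches its own reverse complement perfectly on the minus
# strand, as any motif must.
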