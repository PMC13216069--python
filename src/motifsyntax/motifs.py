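"""Motif matrix containers and deterministic transformations.

A motif in this package is the pairing of a contribution weight matrix
(CWM) — the mean per-base attribution score of a sequence-to-accessibility
model over the seqlets supporting the motif — with a position probability
matrix (PPM) describing the base composition of those seqlets.  Matrices
are 4 x L numpy arrays with rows ordered A, C, G, T.

The operations here are the standard post-discovery transformations:
flank trimming at a fraction of the maximum per-position contribution,
consensus extraction, reverse complementation, PPM -> PFM conversion, and
offset/strand-maximized Pearson similarity between matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Union

import numpy as np

__all__ = [
    "BASES",
    "Motif",
    "TrimmedMotif",
    "DegenerateMotifError",
    "trim_cwm",
    "consensus_sequence",
    "consensus_from_cwm",
    "reverse_complement",
    "ppm_to_pfm",
    "cwm_similarity",
    "SimilarityResult",
]

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: row permutation implementing A<->T, C<->G on a 4 x L matrix
_COMPLEMENT_ROWS = np.array([3, 2, 1, 0])


class DegenerateMotifError(ValueError):
    """Raised when an operation receives an all-zero or empty matrix."""


def _as_matrix(m) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != 4:
        raise ValueError(f"motif matrices must be 4 x L, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("motif matrix contains non-finite entries")
    return a


@dataclass(frozen=True)
class Motif:
    """A lexicon motif: CWM + PPM + polarity + supporting seqlet count.

    Polarity records the sign of the motif's aggregate contribution to
    predicted accessibility: ``positive`` motifs promote accessibility,
    ``negative`` motifs reduce it.
    """

    label: str
    cwm: np.ndarray
    ppm: np.ndarray
    polarity: str = "positive"
    n_seqlets: int = 0

    def __post_init__(self):
        cwm = _as_matrix(self.cwm)
        ppm = _as_matrix(self.ppm)
        object.__setattr__(self, "cwm", cwm)
        object.__setattr__(self, "ppm", ppm)
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")
        if cwm.shape != ppm.shape:
            raise ValueError("cwm and ppm must have identical dimensions")
        if cwm.shape[1] < 3:
            raise ValueError("motifs must span at least 3 positions")
        if self.n_seqlets < 0:
            raise ValueError("n_seqlets must be non-negative")
        if np.any(ppm < -1e-9) or np.any(ppm > 1 + 1e-9):
            raise ValueError(f"ppm entries outside [0, 1] for motif {self.label!r}")
        colsums = ppm.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValueError(f"ppm columns of motif {self.label!r} do not sum to 1")

    @property
    def length(self) -> int:
        return self.cwm.shape[1]


@dataclass(frozen=True)
class TrimmedMotif:
    """The retained high-contribution span of a parent motif."""

    parent_label: str
    cwm: np.ndarray
    ppm: np.ndarray
    offset: int
    consensus: str
    polarity: str = "positive"

    def __post_init__(self):
        object.__setattr__(self, "cwm", _as_matrix(self.cwm))
        object.__setattr__(self, "ppm", _as_matrix(self.ppm))
        if self.cwm.shape[1] < 1:
            raise ValueError("trimmed motif must retain at least one position")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")
        if set(self.consensus) - set(BASES):
            raise ValueError("consensus contains non-ACGT characters")

    @property
    def length(self) -> int:
        return self.cwm.shape[1]


def trim_cwm(motif: Motif, frac: float = 0.3) -> TrimmedMotif:
    """Trim motif flanks at ``frac`` of the maximum per-position contribution.

    Per-position totals are the sum of absolute CWM entries across bases;
    the retained span runs contiguously from the first to the last position
    whose total reaches ``frac * max``.  Interior positions below threshold
    are retained (flank trimming keeps motifs gapless).
    """
    if not 0 < frac < 1:
        raise ValueError(f"frac must lie in (0, 1), got {frac}")
    totals = np.abs(motif.cwm).sum(axis=0)
    if not np.any(totals > 0):
        raise DegenerateMotifError(f"motif {motif.label!r} has an all-zero CWM")
    threshold = frac * totals.max()
    passing = np.nonzero(totals >= threshold)[0]
    lo, hi = int(passing[0]), int(passing[-1]) + 1
    cwm = motif.cwm[:, lo:hi]
    ppm = motif.ppm[:, lo:hi]
    return TrimmedMotif(
        parent_label=motif.label,
        cwm=cwm,
        ppm=ppm,
        offset=lo,
        consensus=consensus_from_cwm(cwm, motif.polarity),
        polarity=motif.polarity,
    )


def consensus_from_cwm(cwm: np.ndarray, polarity: str = "positive") -> str:
    """Base with the highest contribution per column; |contribution| for
    negative-polarity motifs.  Ties resolve to the earlier base in A<C<G<T.
    """
    cwm = _as_matrix(cwm)
    if cwm.shape[1] == 0:
        raise DegenerateMotifError("cannot take the consensus of an empty matrix")
    scores = np.abs(cwm) if polarity == "negative" else cwm
    # np.argmax returns the first maximal row, i.e. the A<C<G<T tie-break
    return "".join(BASES[i] for i in np.argmax(scores, axis=0))


def consensus_sequence(trimmed: TrimmedMotif) -> str:
    """Consensus of a trimmed motif (recomputed from its matrices)."""
    return consensus_from_cwm(trimmed.cwm, trimmed.polarity)


def reverse_complement(x: Union[str, np.ndarray, Motif]) -> Union[str, np.ndarray, Motif]:
    """Reverse complement of a DNA string, a 4 x L matrix, or a Motif.

    For matrices the A/T and C/G rows are swapped and the column order
    reversed; ``reverse_complement`` is an involution for every kind.
    """
    if isinstance(x, str):
        try:
            return "".join(_COMPLEMENT[b] for b in reversed(x))
        except KeyError as exc:
            raise ValueError(f"non-ACGT character in sequence: {exc.args[0]!r}") from None
    if isinstance(x, Motif):
        return Motif(
            label=x.label,
            cwm=reverse_complement(x.cwm),
            ppm=reverse_complement(x.ppm),
            polarity=x.polarity,
            n_seqlets=x.n_seqlets,
        )
    a = _as_matrix(x)
    return a[_COMPLEMENT_ROWS, ::-1]


def ppm_to_pfm(ppm: np.ndarray, n_seqlets: int) -> np.ndarray:
    """Convert a probability matrix to counts by scaling with the seqlet total."""
    if n_seqlets < 0:
        raise ValueError("n_seqlets must be non-negative")
    return _as_matrix(ppm) * float(n_seqlets)


class SimilarityResult(NamedTuple):
    correlation: float
    offset: int
    strand: str  # '+' or '-'
    degenerate: bool


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = math.sqrt(float(u @ u) * float(v @ v))
    if denom == 0:
        return float("nan")
    return float(u @ v) / denom


def _aligned_vectors(a: np.ndarray, b: np.ndarray, off: int):
    """Zero-pad a and b onto their union span with b shifted by ``off``."""
    la, lb = a.shape[1], b.shape[1]
    lo = min(0, off)
    hi = max(la, off + lb)
    span = hi - lo
    ua = np.zeros((4, span))
    ub = np.zeros((4, span))
    ua[:, -lo : la - lo] = a
    ub[:, off - lo : off - lo + lb] = b
    return ua.ravel(), ub.ravel()


def cwm_similarity(a: np.ndarray, b: np.ndarray, allow_rc: bool = True) -> SimilarityResult:
    """Maximum Pearson correlation between two matrices over ungapped offsets.

    Offsets are restricted to alignments where at least half of the shorter
    matrix overlaps the other; entries outside the overlap are zero-padded.
    With ``allow_rc`` the reverse complement of ``b`` is also searched.
    Zero-variance inputs yield a correlation of 0 flagged degenerate.
    """
    a = _as_matrix(a)
    b = _as_matrix(b)
    la, lb = a.shape[1], b.shape[1]
    if la == 0 or lb == 0:
        raise ValueError("matrices must have at least one column")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return SimilarityResult(0.0, 0, "+", True)
    min_overlap = max(1, math.ceil(0.5 * min(la, lb)))
    candidates = [(b, "+")]
    if allow_rc:
        candidates.append((reverse_complement(b), "-"))
    best = SimilarityResult(-np.inf, 0, "+", False)
    saw_valid = False
    for mat, strand in candidates:
        for off in range(-(lb - min_overlap), la - min_overlap + 1):
            overlap = min(la, off + lb) - max(0, off)
            if overlap < min_overlap:
                continue
            u, v = _aligned_vectors(a, mat, off)
            r = _pearson(u, v)
            if math.isnan(r):
                continue
            saw_valid = True
            if r > best.correlation:
                best = SimilarityResult(r, off, strand, False)
    if not saw_valid:
        return SimilarityResult(0.0, 0, "+", True)
    return best
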