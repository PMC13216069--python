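"""In silico marginalization against a sequence-to-accessibility predictor.

The marginal effect of a short sequence is estimated by substituting it into
the centre of a library of non-accessible background windows and averaging
the change in predicted natural-log total counts.  For a pair of motifs the
two consensus blocks are inserted jointly at every *arrangement* — a
combination of relative orientation and edge-to-edge gap — yielding, per
background sequence and model fold:

    dA = yA - y0,  dB = yB - y0,  dJ = yJ - y0,  dS = dA + dB

where ``dS`` is the log-additive expectation for independent effects and an
excess of ``dJ`` over ``dS`` indicates synergy.

A *predictor* is any object with ``predict(sequence, fold) -> (log_counts,
profile)`` and ``contributions(sequence, fold) -> per-base scores``; a cheap
``predict_log_counts`` method is used when available.  See
:mod:`motifsyntax.synthetic` for the planted-effect oracle used in tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .motifs import reverse_complement

__all__ = [
    "ORIENTATIONS_IDENTICAL",
    "ORIENTATIONS_DISTINCT",
    "Arrangement",
    "enumerate_orientations",
    "oriented_blocks",
    "canonical_pair_code",
    "build_edited_sequence",
    "marginalize_single",
    "marginalize_pair",
    "variant_effect",
    "VariantEffect",
    "ablate_instances",
    "EFFECT_COLUMNS",
]

#: canonical orientation order; also the tie-break order for optima
ORIENTATIONS_IDENTICAL = ("tandem", "head_to_head", "tail_to_tail")
ORIENTATIONS_DISTINCT = ("A+B+", "A+B-", "A-B+", "A-B-")

EFFECT_COLUMNS = [
    "seq_idx", "fold", "orientation", "gap", "center_distance",
    "y0", "yA", "yB", "yJ", "dA", "dB", "dJ", "dS",
]


@dataclass(frozen=True)
class Arrangement:
    """One relative placement of a motif pair.

    ``gap`` is the edge-to-edge spacing in bp between the two inserted
    blocks (0 = abutting); ``center_distance`` is the derived distance
    between block centres, ``gap + (lenA + lenB) / 2``.
    """

    orientation: str
    gap: int
    len_a: int
    len_b: int

    def __post_init__(self):
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if self.orientation not in ORIENTATIONS_IDENTICAL + ORIENTATIONS_DISTINCT:
            raise ValueError(f"unknown orientation code {self.orientation!r}")

    @property
    def center_distance(self) -> float:
        return self.gap + (self.len_a + self.len_b) / 2


def _check_dna(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    if set(seq) - set("ACGT"):
        raise ValueError(f"{name} contains non-ACGT characters")
    return seq


def oriented_blocks(seq_a: str, seq_b: str, orientation: str) -> tuple[str, str]:
    """Left and right inserted block for one orientation code.

    Identical pairs use {tandem, head_to_head, tail_to_tail}; distinct
    pairs use codes like ``A+B-`` meaning A on the plus strand placed left
    of B on the minus strand.
    """
    rc_a, rc_b = reverse_complement(seq_a), reverse_complement(seq_b)
    table = {
        "tandem": (seq_a, seq_a),
        "head_to_head": (seq_a, rc_a),
        "tail_to_tail": (rc_a, seq_a),
        "A+B+": (seq_a, seq_b),
        "A+B-": (seq_a, rc_b),
        "A-B+": (rc_a, seq_b),
        "A-B-": (rc_a, rc_b),
    }
    return table[orientation]


def canonical_pair_code(
    left_is_a: bool, strand_left: str, strand_right: str, identical: bool
) -> str:
    """Canonical orientation code of a realized left/right placement.

    Arrangements are identified modulo reverse complement of the whole
    insert; distinct pairs are canonicalized with motif A on the left.
    """
    if identical:
        if strand_left == strand_right:
            return "tandem"
        return "head_to_head" if strand_left == "+" else "tail_to_tail"
    flip = {"+": "-", "-": "+"}
    if left_is_a:
        return f"A{strand_left}B{strand_right}"
    # (B, s_l, A, s_r) rc-> (A, flip(s_r), B, flip(s_l))
    return f"A{flip[strand_right]}B{flip[strand_left]}"


def enumerate_orientations(seq_a: str, seq_b: str, dedup: bool = False) -> list[str]:
    """Unique orientation codes for a motif pair.

    Three codes for an identical pair, four for a distinct pair.  With
    ``dedup`` codes whose inserted blocks are string-identical (modulo
    reverse complement of the whole insert) collapse, e.g. a perfect
    palindrome admits a single orientation.
    """
    _check_dna(seq_a, "seq_a")
    _check_dna(seq_b, "seq_b")
    codes = ORIENTATIONS_IDENTICAL if seq_a == seq_b else ORIENTATIONS_DISTINCT
    if not dedup:
        return list(codes)
    seen, out = set(), []
    for code in codes:
        left, right = oriented_blocks(seq_a, seq_b, code)
        rc_key = (reverse_complement(right), reverse_complement(left))
        key = min((left, right), rc_key)
        if key not in seen:
            seen.add(key)
            out.append(code)
    return out


def build_edited_sequence(
    background: str,
    seq_a: str,
    seq_b: Optional[str] = None,
    arrangement: Optional[Arrangement] = None,
) -> str:
    """Substitute one motif (centred) or an oriented pair into a background.

    The pair is centred as a whole; the ``gap`` bases between the blocks
    retain the original background sequence, so each insertion is an
    independent substitution.
    """
    _check_dna(background, "background")
    _check_dna(seq_a, "seq_a")
    n = len(background)
    if seq_b is None:
        if len(seq_a) > n:
            raise ValueError("motif longer than background window")
        start = (n - len(seq_a)) // 2
        return background[:start] + seq_a + background[start + len(seq_a):]
    if arrangement is None:
        raise ValueError("pair mode requires an arrangement")
    _check_dna(seq_b, "seq_b")
    left, right = oriented_blocks(seq_a, seq_b, arrangement.orientation)
    span = len(left) + arrangement.gap + len(right)
    if span > n:
        raise ValueError(
            f"inserted span of {span} bp exceeds background length {n}"
        )
    start = (n - span) // 2
    right_start = start + len(left) + arrangement.gap
    assert right_start >= start + len(left)
    return (
        background[:start]
        + left
        + background[start + len(left): right_start]
        + right
        + background[right_start + len(right):]
    )


def pair_insert_mask(
    background_length: int, seq_a: str, seq_b: str, arrangement: Arrangement
) -> np.ndarray:
    """Boolean mask over the window marking the inserted block positions."""
    left, right = oriented_blocks(seq_a, seq_b, arrangement.orientation)
    span = len(left) + arrangement.gap + len(right)
    start = (background_length - span) // 2
    mask = np.zeros(background_length, dtype=bool)
    mask[start: start + len(left)] = True
    rs = start + len(left) + arrangement.gap
    mask[rs: rs + len(right)] = True
    return mask


def _log_counts(predictor, seq: str, fold: int) -> float:
    fn = getattr(predictor, "predict_log_counts", None)
    if fn is not None:
        return float(fn(seq, fold))
    return float(predictor.predict(seq, fold)[0])


def _n_folds(predictor) -> int:
    return int(getattr(predictor, "n_folds", 1))


class SingleEffect(NamedTuple):
    table: pd.DataFrame  # columns seq_idx, fold, y0, yA, dA
    mean_effect: float


def marginalize_single(predictor, library, seq: str) -> SingleEffect:
    """Marginal effect of one sequence: per-(background, fold) dA and mean."""
    sequences = list(getattr(library, "sequences", library))
    if not sequences:
        raise ValueError("background library is empty")
    _check_dna(seq)
    folds = range(_n_folds(predictor))
    rows = []
    for i, bg in enumerate(sequences):
        edited = build_edited_sequence(bg, seq)
        for f in folds:
            try:
                y0 = _log_counts(predictor, bg, f)
                ya = _log_counts(predictor, edited, f)
            except Exception as exc:
                raise RuntimeError(f"predictor failed on background {i}: {exc}") from exc
            rows.append((i, f, y0, ya, ya - y0))
    table = pd.DataFrame(rows, columns=["seq_idx", "fold", "y0", "yA", "dA"])
    return SingleEffect(table, float(table["dA"].mean()))


def marginalize_pair(
    predictor,
    library,
    seq_a: str,
    seq_b: str,
    gaps: Iterable[int] = range(0, 201),
    orientations: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Effect table over all arrangements of a motif pair.

    One record per (background sequence, fold, arrangement), with the
    single-insertion effects dA/dB computed once per (sequence, fold) and
    shared across arrangements.  Iteration order is deterministic:
    orientation in canonical order, ascending gap, sequence, fold.
    """
    sequences = list(getattr(library, "sequences", library))
    if not sequences:
        raise ValueError("background library is empty")
    _check_dna(seq_a, "seq_a")
    _check_dna(seq_b, "seq_b")
    gaps = sorted(set(int(g) for g in gaps))
    if gaps and gaps[0] < 0:
        raise ValueError("gaps must be non-negative")
    if orientations is None:
        orientations = enumerate_orientations(seq_a, seq_b)
    n_folds = _n_folds(predictor)
    n_seq = len(sequences)
    la, lb = len(seq_a), len(seq_b)

    y0 = np.empty((n_seq, n_folds))
    ya = np.empty((n_seq, n_folds))
    yb = np.empty((n_seq, n_folds))
    for i, bg in enumerate(sequences):
        ea = build_edited_sequence(bg, seq_a)
        eb = build_edited_sequence(bg, seq_b)
        for f in range(n_folds):
            y0[i, f] = _log_counts(predictor, bg, f)
            ya[i, f] = _log_counts(predictor, ea, f)
            yb[i, f] = _log_counts(predictor, eb, f)

    seq_idx_block = np.repeat(np.arange(n_seq), n_folds)
    fold_block = np.tile(np.arange(n_folds), n_seq)
    frames = []
    for orient in orientations:
        for gap in gaps:
            arr = Arrangement(orient, gap, la, lb)
            yj = np.empty((n_seq, n_folds))
            for i, bg in enumerate(sequences):
                edited = build_edited_sequence(bg, seq_a, seq_b, arr)
                for f in range(n_folds):
                    yj[i, f] = _log_counts(predictor, edited, f)
            block = pd.DataFrame(
                {
                    "seq_idx": seq_idx_block,
                    "fold": fold_block,
                    "orientation": orient,
                    "gap": gap,
                    "center_distance": arr.center_distance,
                    "y0": y0.ravel(),
                    "yA": ya.ravel(),
                    "yB": yb.ravel(),
                    "yJ": yj.ravel(),
                }
            )
            frames.append(block)
    table = pd.concat(frames, ignore_index=True)
    table["dA"] = table["yA"] - table["y0"]
    table["dB"] = table["yB"] - table["y0"]
    table["dJ"] = table["yJ"] - table["y0"]
    table["dS"] = table["dA"] + table["dB"]
    return table[EFFECT_COLUMNS]


@dataclass(frozen=True)
class VariantEffect:
    """Predicted effect of a single-nucleotide variant on accessibility."""

    variant_id: str
    delta_counts_100bp: float
    log2fc_counts: float
    per_fold_delta: tuple
    per_fold_log2fc: tuple


def variant_effect(
    predictor,
    window_seq: str,
    variant_offset: int,
    non_effect_base: str,
    effect_base: str,
    variant_id: str = "variant",
    count_window: int = 100,
) -> VariantEffect:
    """Score a variant by count differences near it and total-count log2 FC.

    ``delta_counts_100bp`` sums per-base predicted count differences in the
    ``count_window`` bp window centred at the variant (truncated at the
    profile boundaries); ``log2fc_counts`` is the log2 fold change of total
    predicted counts, effect vs non-effect allele.  Both are computed per
    fold and averaged.
    """
    _check_dna(window_seq, "window_seq")
    if window_seq[variant_offset] != non_effect_base:
        raise ValueError(
            f"window sequence has {window_seq[variant_offset]!r} at offset "
            f"{variant_offset}, expected non-effect base {non_effect_base!r}"
        )
    profile_len = int(getattr(predictor, "profile_length", len(window_seq)))
    margin = (len(window_seq) - profile_len) // 2
    pidx = variant_offset - margin
    if not 0 <= pidx < profile_len:
        raise ValueError("variant offset falls outside the central profile window")
    alt_seq = (
        window_seq[:variant_offset] + effect_base + window_seq[variant_offset + 1:]
    )
    _check_dna(alt_seq, "effect-allele sequence")
    half = count_window // 2
    lo, hi = max(0, pidx - half), min(profile_len, pidx + half)
    deltas, log2fcs = [], []
    for f in range(_n_folds(predictor)):
        lc_ref, prof_ref = predictor.predict(window_seq, f)
        lc_alt, prof_alt = predictor.predict(alt_seq, f)
        deltas.append(float(np.sum(prof_alt[lo:hi] - prof_ref[lo:hi])))
        log2fcs.append((lc_alt - lc_ref) / math.log(2))
    return VariantEffect(
        variant_id=variant_id,
        delta_counts_100bp=float(np.mean(deltas)),
        log2fc_counts=float(np.mean(log2fcs)),
        per_fold_delta=tuple(deltas),
        per_fold_log2fc=tuple(log2fcs),
    )


def _neutral_base_ablation(predictor, seq: str, start: int, end: int) -> str:
    """Replace each base of [start, end) with the minimal-|contribution|
    alternative from the fold-averaged hypothetical contribution scores."""
    hyp = None
    for f in range(_n_folds(predictor)):
        h = np.asarray(predictor.hypothetical_contributions(seq, f), dtype=float)
        hyp = h if hyp is None else hyp + h
    hyp /= _n_folds(predictor)
    bases = list(seq)
    for pos in range(start, end):
        bases[pos] = "ACGT"[int(np.argmin(np.abs(hyp[:, pos])))]
    return "".join(bases)


def ablate_instances(
    predictor,
    sequences: Mapping[str, str],
    instances,
    per_quartile: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """Neutral-base ablation of motif instances sampled by quality quartile.

    Instances are split into quartiles of ``hit_correlation``; up to
    ``per_quartile`` are sampled from each (all, with a warning, if fewer).
    Each sampled instance span is replaced base-by-base with the most
    neutral base per the predictor's hypothetical contribution scores, and
    the change in predicted log counts (after - before, fold-averaged) is
    reported per instance.
    """
    instances = list(instances)
    if not instances:
        raise ValueError("no instances to ablate")
    rng = np.random.default_rng(seed)
    corr = np.array([inst.hit_correlation for inst in instances])
    qs = np.quantile(corr, [0.25, 0.5, 0.75])
    quartile = np.searchsorted(qs, corr, side="left")
    rows = []
    for q in range(4):
        idx = np.nonzero(quartile == q)[0]
        if len(idx) == 0:
            continue
        if len(idx) < per_quartile:
            warnings.warn(
                f"quartile {q + 1}: only {len(idx)} instances available "
                f"(requested {per_quartile}); using all"
            )
            chosen = idx
        else:
            chosen = rng.choice(idx, size=per_quartile, replace=False)
        for i in sorted(chosen):
            inst = instances[i]
            seq = sequences[inst.chrom]
            ablated = _neutral_base_ablation(predictor, seq, inst.start, inst.end)
            deltas = [
                _log_counts(predictor, ablated, f) - _log_counts(predictor, seq, f)
                for f in range(_n_folds(predictor))
            ]
            rows.append(
                (inst.chrom, inst.start, inst.end, inst.label, q + 1,
                 float(inst.hit_correlation), float(np.mean(deltas)))
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "label", "quartile",
                 "hit_correlation", "delta_log_counts"],
    )
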