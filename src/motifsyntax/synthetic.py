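"""Synthetic data stage: a planted-effect accessibility oracle and simulators.

Training deep accessibility models requires GPUs and large ATAC-seq atlases;
this module supplies a drop-in stand-in satisfying the predictor contract
used by :mod:`motifsyntax.marginalize`.  A :class:`PlantedModel` returns a
baseline natural-log count plus known, *planted* per-motif marginal effects
(exact consensus matches on either strand), pairwise interaction terms that
are either hard (one specific orientation + gap) or soft (a smooth kernel of
the gap, decaying to zero beyond ~100 bp), and a per-(sequence, fold)
Gaussian jitter emulating the variability of an ensemble of model folds.
Because effects are planted in closed form, every downstream statistic has a
known ground truth.

Also here: GC-controlled background sequence sampling with motif exclusion,
a paired-end fragment simulator under the 9-bp Tn5 duplication model, a
variant-gene (eQTL) table simulator with direction-faithful signed effects,
and a seeded battery builder of hard / soft / null motif pairs.
"""

from __future__ import annotations

import itertools
import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .instances import MotifInstance
from .marginalize import canonical_pair_code
from .motifs import reverse_complement

__all__ = [
    "InteractionRule",
    "PlantedModel",
    "BackgroundLibrary",
    "FragmentRecord",
    "make_background_library",
    "simulate_fragments",
    "simulate_eqtl_table",
    "PlantedPair",
    "make_syntax_battery",
]

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def _hash_gauss(*keys: int) -> float:
    """Deterministic standard normal from integer keys (Box-Muller)."""
    s = 0
    for k in keys:
        s = _splitmix64(s ^ (k & _MASK64))
    u1 = ((s >> 11) + 1) / (1 << 53)  # in (0, 1]
    s = _splitmix64(s)
    u2 = (s >> 11) / (1 << 53)
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)


def _seq_key(seq: str) -> int:
    return zlib.crc32(seq.encode("ascii"))


@dataclass(frozen=True)
class InteractionRule:
    """A planted pairwise interaction between two consensus sequences.

    ``kind='hard'`` adds ``magnitude`` log counts only when the realized
    arrangement matches ``orientation`` and ``gap`` exactly.  ``kind='soft'``
    adds ``magnitude * k(gap)`` for any orientation, with a logistic kernel
    ``k(g) = 1 / (1 + exp((g - midpoint) / scale))`` that is ~1 at contact
    and near zero beyond about 100 bp at the defaults.
    """

    motif_a: str
    motif_b: str
    kind: str
    magnitude: float
    orientation: Optional[str] = None
    gap: Optional[int] = None
    soft_midpoint: float = 60.0
    soft_scale: float = 15.0

    def __post_init__(self):
        if self.kind not in ("hard", "soft"):
            raise ValueError("kind must be 'hard' or 'soft'")
        if not math.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if self.kind == "hard":
            if self.orientation is None or self.gap is None:
                raise ValueError("hard rules require orientation and gap")
            if not 0 <= self.gap <= 200:
                raise ValueError("hard gap must lie in [0, 200]")

    def kernel(self, gap: int) -> float:
        if self.kind == "hard":
            return 1.0 if gap == self.gap else 0.0
        return 1.0 / (1.0 + math.exp((gap - self.soft_midpoint) / self.soft_scale))


class _Match(NamedTuple):
    consensus: str
    start: int
    end: int
    strand: str


class PlantedModel:
    """Accessibility oracle with planted marginal and interaction effects.

    Implements the predictor contract: ``predict(seq, fold)`` returns
    (natural-log total counts, per-base count profile over the central
    window) and ``contributions(seq, fold)`` returns per-base scores whose
    span sums equal the realized planted effects.  Deterministic given
    (sequence, fold, seed).
    """

    def __init__(
        self,
        baseline: float = 2.0,
        motif_effects: Optional[Mapping[str, float]] = None,
        interactions: Sequence[InteractionRule] = (),
        fold_jitter_sd: float = 0.0,
        seed: int = 0,
        window_length: int = 2114,
        profile_length: int = 1000,
        n_folds: int = 5,
        cwms: Optional[Mapping[str, np.ndarray]] = None,
    ):
        self.baseline = float(baseline)
        self.motif_effects = dict(motif_effects or {})
        for cons, eff in self.motif_effects.items():
            if set(cons) - set("ACGT"):
                raise ValueError(f"non-ACGT consensus {cons!r}")
            if not math.isfinite(eff):
                raise ValueError("motif effects must be finite")
        declared = set(self.motif_effects)
        for rule in interactions:
            if rule.motif_a not in declared or rule.motif_b not in declared:
                raise ValueError(
                    "interaction references a consensus without a declared effect"
                )
        self.interactions = list(interactions)
        self.fold_jitter_sd = float(fold_jitter_sd)
        self.seed = int(seed)
        self.window_length = int(window_length)
        self.profile_length = int(profile_length)
        self.n_folds = int(n_folds)
        self.cwms = {k: np.asarray(v, float) for k, v in (cwms or {}).items()}
        self._scan_cache: dict[str, tuple] = {}

    # -- sequence scanning -------------------------------------------------

    def _scan(self, seq: str) -> tuple:
        cached = self._scan_cache.get(seq)
        if cached is not None:
            return cached
        matches = []
        for cons in self.motif_effects:
            rc = reverse_complement(cons)
            patterns = [(cons, "+")] if rc == cons else [(cons, "+"), (rc, "-")]
            for pat, strand in patterns:
                i = seq.find(pat)
                while i != -1:
                    matches.append(_Match(cons, i, i + len(pat), strand))
                    i = seq.find(pat, i + 1)
        matches.sort(key=lambda m: (m.start, m.consensus))
        out = tuple(matches)
        if len(self._scan_cache) > 300_000:
            self._scan_cache.clear()
        self._scan_cache[seq] = out
        return out

    def _interaction_pairs(self, matches: tuple):
        """Yield (rule, left match, right match, realized gap) for firing rules."""
        by_cons: dict[str, list[_Match]] = {}
        for m in matches:
            by_cons.setdefault(m.consensus, []).append(m)
        for rule in self.interactions:
            if rule.motif_a == rule.motif_b:
                pairs = itertools.combinations(by_cons.get(rule.motif_a, ()), 2)
            else:
                pairs = itertools.product(
                    by_cons.get(rule.motif_a, ()), by_cons.get(rule.motif_b, ())
                )
            for ma, mb in pairs:
                left, right = (ma, mb) if ma.start <= mb.start else (mb, ma)
                gap = right.start - left.end
                if gap < 0:
                    continue  # overlapping matches carry no pair term
                code = canonical_pair_code(
                    left_is_a=(left is ma),
                    strand_left=left.strand,
                    strand_right=right.strand,
                    identical=(rule.motif_a == rule.motif_b),
                )
                if rule.kind == "hard":
                    if code == rule.orientation and gap == rule.gap:
                        yield rule, left, right, gap
                else:
                    k = rule.kernel(gap)
                    if k > 0:
                        yield rule, left, right, gap

    # -- predictor contract ------------------------------------------------

    def _check_length(self, seq: str):
        if len(seq) != self.window_length:
            raise ValueError(
                f"sequence length {len(seq)} != window length {self.window_length}"
            )

    def _jitter(self, seq: str, fold: int) -> float:
        if self.fold_jitter_sd == 0:
            return 0.0
        return self.fold_jitter_sd * _hash_gauss(_seq_key(seq), fold + 1, self.seed)

    def predict_log_counts(self, seq: str, fold: int) -> float:
        self._check_length(seq)
        matches = self._scan(seq)
        y = self.baseline
        for m in matches:
            y += self.motif_effects[m.consensus]
        for rule, _l, _r, gap in self._interaction_pairs(matches):
            y += rule.magnitude * rule.kernel(gap)
        return y + self._jitter(seq, fold)

    def predict(self, seq: str, fold: int) -> tuple[float, np.ndarray]:
        lc = self.predict_log_counts(seq, fold)
        margin = (self.window_length - self.profile_length) // 2
        weights = np.ones(self.profile_length)
        for m, effect in self._realized_effects(seq).items():
            lo = max(0, m.start - margin)
            hi = min(self.profile_length, m.end - margin)
            if hi > lo:
                weights[lo:hi] += 10.0 * abs(effect)
        profile = math.exp(lc) * weights / weights.sum()
        return lc, profile

    def _realized_effects(self, seq: str) -> dict:
        """Per-match realized effect: marginal + half of each firing pair term."""
        matches = self._scan(seq)
        effects = {m: self.motif_effects[m.consensus] for m in matches}
        for rule, left, right, gap in self._interaction_pairs(matches):
            share = 0.5 * rule.magnitude * rule.kernel(gap)
            effects[left] += share
            effects[right] += share
        return effects

    def contributions(self, seq: str, fold: int) -> np.ndarray:
        """Per-base contribution scores; each matched span sums to its
        realized effect, distributed proportionally to |CWM| when one is
        registered for the consensus, else uniformly.  Unmatched bases carry
        seeded noise of magnitude <= 1e-3."""
        self._check_length(seq)
        rng = np.random.default_rng(
            (_seq_key(seq) ^ _splitmix64(self.seed + fold)) % (1 << 63)
        )
        scores = rng.uniform(-1e-3, 1e-3, size=len(seq))
        for m, effect in self._realized_effects(seq).items():
            cwm = self.cwms.get(m.consensus)
            L = m.end - m.start
            if cwm is not None and cwm.shape[1] == L:
                w = np.abs(cwm).sum(axis=0)
                if m.strand == "-":
                    w = w[::-1]
                w = w / w.sum() if w.sum() > 0 else np.full(L, 1.0 / L)
            else:
                w = np.full(L, 1.0 / L)
            scores[m.start: m.end] = effect * w
        return scores

    def hypothetical_contributions(self, seq: str, fold: int) -> np.ndarray:
        """4 x L counterfactual scores: the observed base carries the actual
        contribution, alternate bases carry near-zero noise."""
        contrib = self.contributions(seq, fold)
        rng = np.random.default_rng(
            (_seq_key(seq) ^ _splitmix64(self.seed * 31 + fold + 7)) % (1 << 63)
        )
        hyp = rng.uniform(-1e-4, 1e-4, size=(4, len(seq)))
        idx = np.fromiter(("ACGT".index(b) for b in seq), dtype=int, count=len(seq))
        hyp[idx, np.arange(len(seq))] = contrib
        return hyp


# ---------------------------------------------------------------------------
# background libraries

@dataclass(frozen=True)
class BackgroundLibrary:
    """GC-controlled random sequences free of any planted consensus."""

    sequences: tuple
    gc_target: float
    tolerance: float
    seed: int

    def __len__(self):
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(_BASE_BYTES[rng.choice(4, size=length, p=p)]).decode("ascii")


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def make_background_library(
    n: int = 100,
    length: int = 2114,
    gc_target: float = 0.5,
    tolerance: float = 0.02,
    forbidden_motifs: Iterable[str] = (),
    seed: int = 0,
    max_attempts_per_seq: int = 200,
) -> BackgroundLibrary:
    """Seeded rejection sampling of background windows.

    Each sequence is drawn base-wise at the target GC, occurrences of any
    forbidden consensus (or its reverse complement) are locally resampled,
    and the sequence is accepted when it is match-free with GC within
    ``tolerance`` of ``gc_target``.  Raises when the constraints cannot be
    met within the attempt budget.
    """
    if not 0 < gc_target < 1:
        raise ValueError("gc_target must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    patterns = set()
    for m in forbidden_motifs:
        patterns.add(m)
        patterns.add(reverse_complement(m))
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        for _attempt in range(max_attempts_per_seq):
            seq = _random_seq(rng, length, gc_target)
            # local repair of forbidden matches
            for _round in range(100):
                hit = None
                for pat in patterns:
                    i = seq.find(pat)
                    if i != -1:
                        hit = (i, len(pat))
                        break
                if hit is None:
                    break
                i, L = hit
                seq = seq[:i] + _random_seq(rng, L, gc_target) + seq[i + L:]
            else:
                continue
            if abs(_gc_fraction(seq) - gc_target) <= tolerance:
                out.append(seq)
                break
        else:
            raise RuntimeError(
                f"could not satisfy GC within {tolerance} of {gc_target} and "
                f"exclusion of {len(patterns)} patterns after "
                f"{max_attempts_per_seq} attempts"
            )
    return BackgroundLibrary(tuple(out), gc_target, tolerance, seed)


# ---------------------------------------------------------------------------
# Tn5 fragment simulation

@dataclass(frozen=True)
class FragmentRecord:
    """A deduplicated ATAC fragment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("fragment start must be < end")
        if self.start < 0:
            raise ValueError("fragment coordinates must be non-negative")


#: Tn5 homodimer duplicates a 9-base span (inclusive); with the event centre
#: at c, the first duplicated base on the plus strand is c - 4 and on the
#: minus strand c + 4.
TN5_HALF_SPAN = 4


def simulate_fragments(
    events: Iterable[tuple], seed: int = 0
) -> tuple[list[FragmentRecord], dict]:
    """Fragments and an insertion-count track from transposition events.

    ``events`` are (chrom, centre, barcode) triples.  Each event's
    plus-strand insertion is at centre - 4 and minus-strand insertion at
    centre + 4; a fragment spans from one event's plus insertion to the next
    event's minus insertion (half-open end), so consecutive events within a
    (chrom, barcode) group share transposition events with their neighbours.
    Events closer than the 9-bp duplicated span collide and are skipped with
    a warning.  The insertion track increments at each reported insertion
    coordinate.
    """
    by_group: dict[tuple, list[int]] = {}
    for chrom, center, barcode in events:
        by_group.setdefault((chrom, barcode), []).append(int(center))
    fragments: list[FragmentRecord] = []
    insertions: dict[str, list] = {}
    skipped = 0
    for (chrom, barcode), centers in sorted(by_group.items()):
        centers.sort()
        for c1, c2 in zip(centers, centers[1:]):
            if c2 - c1 < 2 * TN5_HALF_SPAN + 1:
                skipped += 1
                continue
            start = c1 - TN5_HALF_SPAN
            end = c2 + TN5_HALF_SPAN + 1
            if start < 0:
                skipped += 1
                continue
            fragments.append(FragmentRecord(chrom, start, end, barcode))
            insertions.setdefault(chrom, []).extend((start, end - 1))
    if skipped:
        warnings.warn(f"{skipped} colliding or out-of-range event pair(s) skipped")
    tracks = {}
    for chrom, coords in insertions.items():
        arr = np.zeros(max(coords) + 1, dtype=np.int64)
        np.add.at(arr, np.asarray(coords), 1)
        tracks[chrom] = arr
    return fragments, tracks


# ---------------------------------------------------------------------------
# eQTL table simulation

def simulate_eqtl_table(
    instances: Sequence[MotifInstance],
    polarity: Mapping[str, str],
    n_variants: int,
    frac_in_instances: float = 0.5,
    direction_fidelity: float = 0.9,
    pip_distribution: Optional[Callable] = None,
    seed: int = 0,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Simulate fine-mapped variant-gene pairs concentrated in motif instances.

    A variant falls inside a (uniformly chosen) motif instance with
    probability ``frac_in_instances``.  Variants inside positive motifs are
    downregulating (negative allelic fold change) with probability
    ``direction_fidelity`` and conversely for negative motifs; off-instance
    variants have random signs.  PIPs are drawn from ``pip_distribution(rng)``
    (uniform on [0, 1] by default).
    """
    if not 0 <= frac_in_instances <= 1 or not 0 <= direction_fidelity <= 1:
        raise ValueError("frac_in_instances and direction_fidelity must lie in [0, 1]")
    instances = list(instances)
    if not instances and frac_in_instances > 0:
        raise ValueError("frac_in_instances > 0 requires at least one instance")
    rng = np.random.default_rng(seed)
    if chrom_sizes is None:
        chrom_sizes = {}
        for inst in instances:
            chrom_sizes[inst.chrom] = max(
                chrom_sizes.get(inst.chrom, 0), inst.end + 10_000
            )
        if not chrom_sizes:
            chrom_sizes = {"chr1": 1_000_000}
    chroms = sorted(chrom_sizes)
    spans = {
        c: [(i.start, i.end) for i in instances if i.chrom == c] for c in chroms
    }
    rows = []
    for i in range(n_variants):
        inside = rng.random() < frac_in_instances
        if inside:
            inst = instances[int(rng.integers(len(instances)))]
            pos = int(rng.integers(inst.start, inst.end))
            chrom = inst.chrom
            faithful = rng.random() < direction_fidelity
            down = (polarity[inst.label] == "positive") == faithful
        else:
            for _ in range(1000):
                chrom = chroms[int(rng.integers(len(chroms)))]
                pos = int(rng.integers(chrom_sizes[chrom]))
                if not any(s <= pos < e for s, e in spans[chrom]):
                    break
            down = bool(rng.random() < 0.5)
        afc = float(rng.uniform(0.1, 1.0)) * (-1.0 if down else 1.0)
        pip = float(pip_distribution(rng)) if pip_distribution else float(rng.random())
        rows.append((f"var{i}", chrom, pos, f"gene{i}", pip, afc))
    return pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "gene", "pip", "afc"]
    )


# ---------------------------------------------------------------------------
# planted syntax battery

class PlantedPair(NamedTuple):
    pair_id: str
    kind: str  # hard | soft | null
    model: PlantedModel
    library: BackgroundLibrary
    seq_a: str
    seq_b: str
    rule: Optional[InteractionRule]


def _random_consensus(rng: np.random.Generator, length: int = 8) -> str:
    while True:
        seq = bytes(_BASE_BYTES[rng.integers(0, 4, size=length)]).decode("ascii")
        if reverse_complement(seq) != seq:
            return seq


def make_syntax_battery(
    n_hard: int = 20,
    n_soft: int = 20,
    n_null: int = 20,
    seed: int = 0,
    n_backgrounds: int = 100,
    length: int = 2114,
    n_folds: int = 5,
    fold_jitter_sd: float = 0.05,
    magnitude_range: tuple = (0.3, 0.5),
    marginal_range: tuple = (0.3, 0.6),
    hard_gaps: Sequence[int] = (0, 5, 10, 15),
    motif_length: int = 8,
) -> list[PlantedPair]:
    """Seeded battery of motif pairs with planted hard / soft / no synergy.

    Each pair gets its own planted model (distinct random consensi with
    positive marginal effects and per-fold jitter) and its own background
    library excluding those consensi.  Hard rules pick one canonical
    orientation and a gap from ``hard_gaps``; soft rules use the logistic
    gap kernel at the module defaults.
    """
    from .marginalize import ORIENTATIONS_DISTINCT

    rng = np.random.default_rng(seed)
    pairs: list[PlantedPair] = []
    kinds = ["hard"] * n_hard + ["soft"] * n_soft + ["null"] * n_null
    for idx, kind in enumerate(kinds):
        while True:
            a = _random_consensus(rng, motif_length)
            b = _random_consensus(rng, motif_length)
            distinct = len({a, b, reverse_complement(a), reverse_complement(b)}) == 4
            if distinct and a not in b and b not in a:
                break
        effects = {
            a: float(rng.uniform(*marginal_range)),
            b: float(rng.uniform(*marginal_range)),
        }
        rule = None
        if kind == "hard":
            rule = InteractionRule(
                a, b, "hard",
                magnitude=float(rng.uniform(*magnitude_range)),
                orientation=ORIENTATIONS_DISTINCT[int(rng.integers(4))],
                gap=int(hard_gaps[int(rng.integers(len(hard_gaps)))]),
            )
        elif kind == "soft":
            rule = InteractionRule(
                a, b, "soft", magnitude=float(rng.uniform(*magnitude_range))
            )
        model = PlantedModel(
            baseline=2.0,
            motif_effects=effects,
            interactions=[rule] if rule else [],
            fold_jitter_sd=fold_jitter_sd,
            seed=int(rng.integers(1 << 31)),
            window_length=length,
            n_folds=n_folds,
        )
        library = make_background_library(
            n=n_backgrounds,
            length=length,
            gc_target=0.5,
            tolerance=0.05,
            forbidden_motifs=[a, b],
            seed=int(rng.integers(1 << 31)),
        )
        pairs.append(PlantedPair(f"pair{idx:03d}_{kind}", kind, model, library, a, b, rule))
    return pairs
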