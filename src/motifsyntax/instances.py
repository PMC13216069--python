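"""Calling, filtering and genomic annotation of predictive motif instances.

A motif *instance* is a short genomic span whose local contribution-score
pattern matches a motif CWM.  Hit calling here is a greedy matching-pursuit
over a per-base contribution track: the best-correlated (motif, offset,
strand) placement is recorded and its scaled CWM subtracted from the
residual until no placement reaches the similarity threshold.  Post-hoc
processing mirrors standard practice: motifs whose averaged instance-CWM
correlates < 0.9 with the input CWM are dropped wholesale; same-label
instances overlapping by more than 3 bp are deduplicated keeping the
highest ``hit_correlation``; instances are annotated by genomic context
(promoter > exonic > intronic > distal) and distance to TSS / nucleosome
dyad / peak summit; co-occurrence across peaks is tested with one-sided
Fisher exact tests; and Tn5-insertion footprints are aggregated in 500-bp
windows normalized to the outer-flank accessibility.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .motifs import cwm_similarity, reverse_complement

__all__ = [
    "MotifInstance",
    "Peak",
    "GenomeAnnotation",
    "greedy_hit_caller",
    "quality_filter",
    "dedup_overlaps",
    "annotate_context",
    "bin_distances",
    "cooccurrence_fisher",
    "footprint_metaplot",
    "UndefinedNormalizationError",
]


@dataclass(frozen=True)
class MotifInstance:
    """A called motif hit: half-open genomic span + quality scores."""

    chrom: str
    start: int
    end: int
    strand: str
    label: str
    hit_correlation: float
    contribution: float = 0.0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("instance start must be < end")
        if self.start < 0:
            raise ValueError("instance coordinates must be non-negative")
        if not -1.0 - 1e-9 <= self.hit_correlation <= 1.0 + 1e-9:
            raise ValueError("hit_correlation must lie in [-1, 1]")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int

    def __post_init__(self):
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie within the peak")


@dataclass
class GenomeAnnotation:
    """Per-chromosome TSS positions and exon / gene-body intervals.

    Intervals are 0-based half-open ``(start, end)`` tuples; positions are
    0-based.  Dyads and summits are optional anchor sets for distance
    computations.
    """

    tss: Mapping[str, Sequence[int]] = field(default_factory=dict)
    exons: Mapping[str, Sequence[tuple]] = field(default_factory=dict)
    gene_bodies: Mapping[str, Sequence[tuple]] = field(default_factory=dict)
    dyads: Mapping[str, Sequence[int]] = field(default_factory=dict)
    summits: Mapping[str, Sequence[int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# hit calling

def _scan_correlations(track: np.ndarray, cwm: np.ndarray) -> np.ndarray:
    """Pearson r between the track segment and the CWM at each offset."""
    L = cwm.shape[1]
    n = track.shape[1] - L + 1
    if n <= 0:
        return np.empty(0)
    v = cwm.ravel(order="F")
    v = v - v.mean()
    vnorm = np.sqrt(v @ v)
    out = np.full(n, -np.inf)
    if vnorm == 0:
        return out
    for off in range(n):
        u = track[:, off: off + L].ravel(order="F")
        u = u - u.mean()
        unorm = np.sqrt(u @ u)
        if unorm == 0:
            continue
        out[off] = (u @ v) / (unorm * vnorm)
    return out


def greedy_hit_caller(
    track: np.ndarray,
    cwms: Mapping[str, np.ndarray],
    min_similarity: float = 0.8,
    max_hits_per_peak: int = 50,
    chrom: str = "region",
    track_start: int = 0,
) -> list[MotifInstance]:
    """Greedy matching-pursuit motif hit caller on a 4 x N contribution track.

    Iteratively selects the (motif, offset, strand) with the highest Pearson
    correlation between the residual track segment and the motif CWM,
    records an instance when the correlation reaches ``min_similarity``,
    subtracts the least-squares-scaled CWM from the residual, and repeats.
    This is a verifiable greedy stand-in for sparse-regression hit callers.
    """
    if not cwms:
        raise ValueError("empty CWM set")
    residual = np.array(track, dtype=float)
    oriented = {}
    for label, cwm in cwms.items():
        cwm = np.asarray(cwm, dtype=float)
        oriented[(label, "+")] = cwm
        oriented[(label, "-")] = reverse_complement(cwm)
    hits: list[MotifInstance] = []
    for _ in range(max_hits_per_peak):
        best = None  # (r, label, strand, offset)
        for (label, strand), cwm in oriented.items():
            rs = _scan_correlations(residual, cwm)
            if rs.size == 0:
                continue
            off = int(np.argmax(rs))
            r = rs[off]
            if best is None or r > best[0]:
                best = (float(r), label, strand, off)
        if best is None or best[0] < min_similarity:
            break
        r, label, strand, off = best
        cwm = oriented[(label, strand)]
        L = cwm.shape[1]
        seg = residual[:, off: off + L]
        scale = float((seg * cwm).sum() / (cwm * cwm).sum())
        hits.append(
            MotifInstance(
                chrom=chrom,
                start=track_start + off,
                end=track_start + off + L,
                strand=strand,
                label=label,
                hit_correlation=min(1.0, r),
                contribution=float(np.abs(seg).sum()),
            )
        )
        residual[:, off: off + L] -= scale * cwm
    return hits


# ---------------------------------------------------------------------------
# post-processing

def quality_filter(
    instances: Iterable[MotifInstance],
    cwms: Mapping[str, np.ndarray],
    tracks: Mapping[str, np.ndarray],
    min_r: float = 0.9,
) -> tuple[list[MotifInstance], dict]:
    """Drop motifs whose averaged instance-CWM poorly matches the input CWM.

    For each motif, the instance-CWM is the strand-aligned mean of the
    contribution-track segments over all of its instances; the motif and
    every one of its instances are removed when the correlation with the
    input CWM is below ``min_r``.  Motifs with zero instances are dropped
    and flagged separately.  Returns (retained instances, dropped mapping
    label -> reason).
    """
    instances = list(instances)
    by_label: dict[str, list[MotifInstance]] = {label: [] for label in cwms}
    for inst in instances:
        by_label.setdefault(inst.label, []).append(inst)
    dropped: dict[str, str] = {}
    for label, insts in by_label.items():
        if label not in cwms:
            dropped[label] = "no input CWM"
            continue
        if not insts:
            dropped[label] = "zero instances"
            continue
        segs = []
        for inst in insts:
            seg = np.asarray(tracks[inst.chrom], dtype=float)[:, inst.start: inst.end]
            if inst.strand == "-":
                seg = reverse_complement(seg)
            segs.append(seg)
        instance_cwm = np.mean(segs, axis=0)
        r = cwm_similarity(instance_cwm, np.asarray(cwms[label]), allow_rc=False)
        if r.correlation < min_r:
            dropped[label] = f"instance-CWM correlation {r.correlation:.3f} < {min_r}"
    kept = [inst for inst in instances if inst.label not in dropped]
    return kept, dropped


def dedup_overlaps(
    instances: Iterable[MotifInstance], max_overlap: int = 3
) -> list[MotifInstance]:
    """Deduplicate same-label instances overlapping by more than ``max_overlap`` bp.

    Among conflicting instances the one with the highest ``hit_correlation``
    is kept (ties: leftmost start, then first in input).  Instances of
    different motifs never conflict.  Output is sorted by (chrom, start).
    """
    instances = list(instances)
    order = sorted(
        range(len(instances)),
        key=lambda i: (-instances[i].hit_correlation, instances[i].start, i),
    )
    kept_by_group: dict[tuple, list[MotifInstance]] = {}
    kept_idx = []
    for i in order:
        inst = instances[i]
        group = kept_by_group.setdefault((inst.chrom, inst.label), [])
        conflict = any(
            min(inst.end, k.end) - max(inst.start, k.start) > max_overlap
            for k in group
        )
        if not conflict:
            group.append(inst)
            kept_idx.append(i)
    return sorted(
        (instances[i] for i in kept_idx), key=lambda x: (x.chrom, x.start, x.end)
    )


# ---------------------------------------------------------------------------
# annotation

def _nearest_distance(pos: int, anchors) -> float:
    """|pos - nearest anchor|; ties resolve toward the smaller coordinate."""
    anchors = np.asarray(sorted(anchors))
    if anchors.size == 0:
        return float("nan")
    return float(np.min(np.abs(anchors - pos)))


def _interval_tree(intervals) -> IntervalTree:
    return IntervalTree.from_tuples((int(s), int(e)) for s, e in intervals if e > s)


def annotate_context(
    instances: Iterable[MotifInstance],
    annotation: GenomeAnnotation,
    promoter_window: int = 2000,
) -> pd.DataFrame:
    """Assign genomic context and anchor distances to each instance.

    Context is evaluated at the instance centre with precedence
    promoter (within ``promoter_window`` bp of a TSS) > exonic > intronic
    (gene body but not exon) > distal.  Instances on chromosomes absent
    from the annotation are labelled distal with a warning.
    """
    exon_trees = {c: _interval_tree(v) for c, v in annotation.exons.items()}
    body_trees = {c: _interval_tree(v) for c, v in annotation.gene_bodies.items()}
    missing = set()
    rows = []
    for inst in instances:
        c = inst.center
        known = (
            inst.chrom in annotation.tss
            or inst.chrom in exon_trees
            or inst.chrom in body_trees
        )
        if not known:
            missing.add(inst.chrom)
        d_tss = _nearest_distance(c, annotation.tss.get(inst.chrom, ()))
        if not np.isnan(d_tss) and d_tss <= promoter_window:
            context = "promoter"
        elif inst.chrom in exon_trees and exon_trees[inst.chrom].overlaps(c):
            context = "exonic"
        elif inst.chrom in body_trees and body_trees[inst.chrom].overlaps(c):
            context = "intronic"
        else:
            context = "distal"
        rows.append(
            {
                "chrom": inst.chrom,
                "start": inst.start,
                "end": inst.end,
                "strand": inst.strand,
                "label": inst.label,
                "hit_correlation": inst.hit_correlation,
                "context": context,
                "dist_tss": d_tss,
                "dist_dyad": _nearest_distance(c, annotation.dyads.get(inst.chrom, ())),
                "dist_summit": _nearest_distance(c, annotation.summits.get(inst.chrom, ())),
            }
        )
    if missing:
        warnings.warn(
            f"chromosomes absent from annotation treated as distal: {sorted(missing)}"
        )
    return pd.DataFrame(rows)


def bin_distances(
    instances: Iterable[MotifInstance],
    anchors: Mapping[str, Sequence[int]],
    bin_width: int = 10,
    max_dist: int = 250,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-motif counts of instance-centre distances to the nearest anchor.

    Distances fall into half-open bins [0, w), ..., [max_dist - w, max_dist);
    distances >= ``max_dist`` are excluded.  Returns (counts, z) where ``z``
    is the count row z-scored across bins within each motif (NaN when the
    counts are constant or empty).
    """
    if not anchors or all(len(v) == 0 for v in anchors.values()):
        raise ValueError("anchors must be non-empty")
    edges = np.arange(0, max_dist + bin_width, bin_width)
    labels = sorted({inst.label for inst in instances} | set())
    counts = pd.DataFrame(
        0, index=labels, columns=[f"[{e},{e + bin_width})" for e in edges[:-1]]
    )
    for inst in instances:
        d = _nearest_distance(inst.center, anchors.get(inst.chrom, ()))
        if np.isnan(d) or d >= max_dist:
            continue
        counts.iloc[labels.index(inst.label), int(d // bin_width)] += 1
    mat = counts.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (mat - mean) / sd, np.nan)
        # constant non-zero rows have zero numerator: z is 0, not undefined
        z = np.where((sd == 0) & (mean > 0), 0.0, z)
    zscores = pd.DataFrame(z, index=counts.index, columns=counts.columns)
    return counts, zscores


# ---------------------------------------------------------------------------
# co-occurrence

def cooccurrence_fisher(incidence: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher enrichment test of motif co-occurrence across peaks.

    ``incidence`` is a boolean peak x motif table.  For each unordered motif
    pair a 2 x 2 table of peaks with both / one / neither motif is tested
    one-sided for enrichment; P values are BH-adjusted across all pairs and
    significance called at adjusted P < ``alpha``.
    """
    from statsmodels.stats.multitest import multipletests

    if incidence.shape[0] < 1:
        raise ValueError("incidence table must contain at least one peak")
    inc = incidence.astype(bool)
    motifs = list(inc.columns)
    rows = []
    for a, b in itertools.combinations(motifs, 2):
        both = int((inc[a] & inc[b]).sum())
        a_only = int((inc[a] & ~inc[b]).sum())
        b_only = int((~inc[a] & inc[b]).sum())
        neither = int((~inc[a] & ~inc[b]).sum())
        odds, p = stats.fisher_exact(
            [[both, a_only], [b_only, neither]], alternative="greater"
        )
        rows.append((a, b, both, a_only, b_only, neither, odds, p))
    out = pd.DataFrame(
        rows,
        columns=["motif_a", "motif_b", "both", "a_only", "b_only", "neither",
                 "odds_ratio", "p"],
    )
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    return out


# ---------------------------------------------------------------------------
# footprinting

class UndefinedNormalizationError(ValueError):
    """Raised when the outer-flank mean insertion count is zero."""


def footprint_metaplot(
    insertions: Mapping[str, np.ndarray],
    instances: Iterable[MotifInstance],
    window: int = 500,
    flank_frac: float = 0.1,
) -> np.ndarray:
    """Aggregate Tn5 insertion counts around motif instances.

    Counts are summed per position over ``window``-bp windows centred at
    instance centres (windows truncated by chromosome ends are skipped with
    a warning), then divided by the mean count over the outer ``flank_frac``
    of positions on each side — the local background accessibility.
    """
    half = window // 2
    total = np.zeros(window)
    used = skipped = 0
    for inst in instances:
        track = insertions.get(inst.chrom)
        if track is None:
            skipped += 1
            continue
        c = inst.center
        lo, hi = c - half, c + half
        if lo < 0 or hi > len(track):
            skipped += 1
            continue
        total += np.asarray(track[lo:hi], dtype=float)
        used += 1
    if skipped:
        warnings.warn(f"{skipped} window(s) truncated or off-track were skipped")
    n_flank = max(1, int(round(window * flank_frac)))
    flank_mean = np.concatenate([total[:n_flank], total[-n_flank:]]).mean()
    if flank_mean == 0:
        raise UndefinedNormalizationError(
            f"zero flank insertions across {used} window(s); "
            "footprint normalization undefined"
        )
    return total / flank_mean
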