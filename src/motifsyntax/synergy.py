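"""Synergy calling and hard/soft syntax classification on effect tables.

For each motif pair the *optimal arrangement* is the orientation + gap with
the greatest mean joint effect dJ.  Synergy is a one-sided Wilcoxon
signed-rank test of the per-background-sequence differences dJ - dS at that
arrangement (BH-corrected across the batch of composites), combined with a
minimum mean effect.  Syntax is then classified: *hard* when any
arrangement's mean dJ exceeds four standard deviations across arrangements
(a spike at a specific spacing/orientation), *soft* when the mean excess
over additivity exceeds the effect threshold at any arrangement with the
motifs 20-150 bp apart.  Composites with both are reported hard-dominant.
An interpretation-consistency guard abstains from classification when the
predictor's contribution mass does not track the inserted nucleotides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .marginalize import ORIENTATIONS_DISTINCT, ORIENTATIONS_IDENTICAL

__all__ = [
    "SynergyThresholds",
    "SynergyCall",
    "optimal_arrangement",
    "wilcoxon_signed_rank_one_sided",
    "bh_adjust",
    "classify_batch",
    "classify_composite",
    "interpretation_guard",
    "cross_context_screen",
    "rank_sum_auroc",
    "rank_prevalence_importance",
]

_ORIENT_ORDER = {
    code: i
    for i, code in enumerate(ORIENTATIONS_IDENTICAL + ORIENTATIONS_DISTINCT)
}


@dataclass(frozen=True)
class SynergyThresholds:
    """Decision thresholds for synergy and syntax classification."""

    alpha_adj: float = 0.001
    min_diff: float = 0.15
    z_hard: float = 4.0
    soft_range: tuple = (20, 150)

    def __post_init__(self):
        if not 0 < self.alpha_adj < 1:
            raise ValueError("alpha_adj must lie in (0, 1)")
        if self.min_diff <= 0 or self.z_hard <= 0:
            raise ValueError("min_diff and z_hard must be positive")
        if self.soft_range[0] > self.soft_range[1]:
            raise ValueError("soft_range must be ordered")


@dataclass(frozen=True)
class SynergyCall:
    """Classification result for one composite motif in one context."""

    composite_id: str
    context: str
    orientation: str
    gap: int
    center_distance: float
    mean_diff: float
    p_raw: float
    p_adj: float
    z_max: float
    classes: frozenset
    status: str  # classified | abstained

    @property
    def class_label(self) -> str:
        if self.status == "abstained":
            return "abstained"
        if "hard" in self.classes:
            return "hard"  # hard-dominant when both hard and soft
        if "soft" in self.classes:
            return "soft"
        if "synergistic" in self.classes:
            return "synergistic"
        return "none"


def _arrangement_stats(table: pd.DataFrame) -> pd.DataFrame:
    g = table.groupby(["orientation", "gap"], sort=False)
    stats_df = g.agg(
        mean_dJ=("dJ", "mean"),
        mean_diff=("dJ", "mean"),
        center_distance=("center_distance", "first"),
    ).reset_index()
    stats_df["mean_diff"] = (
        g.apply(lambda d: (d["dJ"] - d["dS"]).mean(), include_groups=False)
        .reset_index(drop=True)
    )
    return stats_df


def optimal_arrangement(table: pd.DataFrame) -> tuple[str, int]:
    """Arrangement maximizing mean dJ; ties break to the smallest gap, then
    canonical orientation order."""
    if table.empty:
        raise ValueError("effect table is empty")
    arr = _arrangement_stats(table)
    best = arr.loc[
        arr.sort_values(
            ["mean_dJ", "gap", "orientation"],
            ascending=[False, True, True],
            key=lambda col: col.map(_ORIENT_ORDER) if col.name == "orientation" else col,
        ).index[0]
    ]
    return str(best["orientation"]), int(best["gap"])


def wilcoxon_signed_rank_one_sided(diffs) -> float:
    """One-sided (greater) Wilcoxon signed-rank P for paired differences.

    Zeros are dropped; all-zero input yields P = 1 (degenerate).  The exact
    null distribution is used for n <= 25 without ties; otherwise the normal
    approximation with tie correction and no continuity correction.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; P = 1")
        return 1.0
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d, alternative="greater", zero_method="wilcox",
        correction=False, method=method,
    )
    return float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _per_sequence_diffs(table: pd.DataFrame, orientation: str, gap: int) -> np.ndarray:
    sel = table[(table["orientation"] == orientation) & (table["gap"] == gap)]
    per_seq = sel.groupby("seq_idx")[["dJ", "dS"]].mean()
    return (per_seq["dJ"] - per_seq["dS"]).to_numpy()


def classify_batch(
    effect_tables: Mapping[str, pd.DataFrame],
    thresholds: SynergyThresholds = SynergyThresholds(),
    guard_pass: Optional[Mapping[str, bool]] = None,
    context: str = "default",
    require_synergy_for_syntax: bool = True,
) -> list[SynergyCall]:
    """Classify a batch of composites with BH correction across the batch.

    Per composite: Wilcoxon at the optimal arrangement on per-sequence
    (fold-averaged) dJ - dS; synergistic iff adjusted P < alpha and mean
    excess > min_diff; hard iff any per-arrangement mean-dJ z-score exceeds
    z_hard; soft iff the mean excess exceeds min_diff at any arrangement
    whose gap falls in the soft range.  Composites failing the
    interpretation guard are abstained and carry no classes.
    """
    ids = list(effect_tables)
    per_comp = {}
    for cid in ids:
        table = effect_tables[cid]
        arr = _arrangement_stats(table)
        if len(arr) < 2:
            warnings.warn(f"{cid}: fewer than 2 arrangements; z undefined")
        orient, gap = optimal_arrangement(table)
        opt_row = arr[(arr["orientation"] == orient) & (arr["gap"] == gap)].iloc[0]
        diffs = _per_sequence_diffs(table, orient, gap)
        p_raw = wilcoxon_signed_rank_one_sided(diffs)
        sd = arr["mean_dJ"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            z_max = float("nan")
        else:
            z_max = float((arr["mean_dJ"].max() - arr["mean_dJ"].mean()) / sd)
        lo, hi = thresholds.soft_range
        in_soft = arr["gap"].between(lo, hi)
        soft_hit = bool((arr.loc[in_soft, "mean_diff"] > thresholds.min_diff).any())
        per_comp[cid] = dict(
            orientation=orient,
            gap=gap,
            center_distance=float(opt_row["center_distance"]),
            mean_diff=float(opt_row["mean_diff"]),
            p_raw=p_raw,
            z_max=z_max,
            soft_hit=soft_hit,
        )
    p_adj = bh_adjust([per_comp[cid]["p_raw"] for cid in ids])
    calls = []
    for cid, padj in zip(ids, p_adj):
        c = per_comp[cid]
        abstained = guard_pass is not None and not guard_pass.get(cid, True)
        classes = set()
        if not abstained:
            synergistic = padj < thresholds.alpha_adj and c["mean_diff"] > thresholds.min_diff
            if synergistic:
                classes.add("synergistic")
            syntax_eligible = synergistic or not require_synergy_for_syntax
            if syntax_eligible:
                if np.isfinite(c["z_max"]) and c["z_max"] > thresholds.z_hard:
                    classes.add("hard")
                if c["soft_hit"]:
                    classes.add("soft")
        calls.append(
            SynergyCall(
                composite_id=cid,
                context=context,
                orientation=c["orientation"],
                gap=c["gap"],
                center_distance=c["center_distance"],
                mean_diff=c["mean_diff"],
                p_raw=c["p_raw"],
                p_adj=float(padj),
                z_max=c["z_max"],
                classes=frozenset(classes),
                status="abstained" if abstained else "classified",
            )
        )
    return calls


def classify_composite(
    table: pd.DataFrame,
    thresholds: SynergyThresholds = SynergyThresholds(),
    composite_id: str = "composite",
    **kwargs,
) -> SynergyCall:
    """Classify a single composite (its own BH family of size one)."""
    return classify_batch({composite_id: table}, thresholds, **kwargs)[0]


def interpretation_guard(
    predictor,
    edited_sequences: Sequence[str],
    insert_masks: Sequence[np.ndarray],
    min_inside_frac: float = 0.5,
) -> tuple[bool, float]:
    """Check that contribution mass tracks the inserted nucleotides.

    Returns (passed, mean inside-mask fraction of total |contribution|).
    Passes iff the mean fraction is >= ``min_inside_frac``; zero total mass
    abstains.
    """
    fracs = []
    n_folds = int(getattr(predictor, "n_folds", 1))
    for seq, mask in zip(edited_sequences, insert_masks):
        contrib = np.zeros(len(seq))
        for f in range(n_folds):
            contrib += np.abs(np.asarray(predictor.contributions(seq, f)))
        total = contrib.sum()
        if total == 0:
            warnings.warn("zero contribution mass; abstaining")
            return False, 0.0
        fracs.append(float(contrib[np.asarray(mask, bool)].sum() / total))
    mean_frac = float(np.mean(fracs))
    return mean_frac >= min_inside_frac, mean_frac


def cross_context_screen(
    predictors: Mapping[str, object],
    libraries,
    seq_a: str,
    seq_b: str,
    orientation: str,
    gap: int,
) -> pd.DataFrame:
    """Mean joint effect dJ (+/- across-fold spread) per context.

    ``libraries`` may be one background library shared by all contexts or a
    mapping context -> library.  Failures in one context are recorded and do
    not stop the screen.
    """
    from .marginalize import marginalize_pair

    if not predictors:
        raise ValueError("at least one predictor context is required")
    rows = []
    for ctx, predictor in predictors.items():
        library = libraries[ctx] if isinstance(libraries, Mapping) else libraries
        try:
            table = marginalize_pair(
                predictor, library, seq_a, seq_b,
                gaps=[gap], orientations=[orientation],
            )
            by_fold = table.groupby("fold")["dJ"].mean()
            rows.append((ctx, float(by_fold.mean()), float(by_fold.std(ddof=1)), ""))
        except Exception as exc:  # pragma: no cover - defensive per-context
            rows.append((ctx, float("nan"), float("nan"), str(exc)))
    return pd.DataFrame(rows, columns=["context", "mean_dJ", "sd_folds", "error"])


def rank_sum_auroc(x, y) -> float:
    """Rank-sum effect size W / (n1 * n2): the probability that a value from
    ``x`` exceeds one from ``y``, ties counted half."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    return float(u) / (x.size * y.size)


def rank_prevalence_importance(
    values: pd.DataFrame,
    groups: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized within-context motif ranks and per-group mean ranks.

    ``values`` has columns (context, motif, value) where value is a motif's
    instance count (prevalence) or summed trimmed-CWM contribution
    (importance).  Ranks ascend with value (ties averaged) and are divided
    by the maximum rank per context so they fall in [0, 1].  ``groups`` maps
    motif -> syntax class; group means are computed per class per context.
    """
    required = {"context", "motif", "value"}
    if not required <= set(values.columns):
        raise ValueError(f"values must have columns {sorted(required)}")
    out = []
    for ctx, sub in values.groupby("context"):
        if sub.empty:
            warnings.warn(f"context {ctx!r} is empty; skipped")
            continue
        ranks = sub["value"].rank(method="average", ascending=True)
        sub = sub.assign(normalized_rank=ranks / ranks.max())
        out.append(sub)
    ranked = pd.concat(out, ignore_index=True) if out else values.iloc[0:0].copy()
    ranked["group"] = ranked["motif"].map(lambda m: groups.get(m, "not_tested"))
    group_means = (
        ranked.groupby(["context", "group"])["normalized_rank"]
        .mean()
        .reset_index(name="mean_normalized_rank")
    )
    return ranked, group_means
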