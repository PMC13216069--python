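"""Permutation enrichment of directional eQTL variants in motif instances.

Fine-mapped variant-gene pairs carry a signed log2 allelic fold change
(aFC) whose sign defines the direction of effect on expression (positive =
upregulating).  Variants disrupting accessibility-promoting (positive)
motifs are expected to downregulate expression, and variants in
accessibility-reducing (negative) motifs to upregulate it.  The test
counts up/downregulating variants overlapping each motif's instances,
compares against counts recomputed after randomly shuffling the aFC values
across variants (direction margins preserved), and calls enrichment when
the BH FDR is below 0.05 and the observed count exceeds the empirical 95%
interval of shuffled counts.  A two-sided Fisher exact meta-test then
compares, separately for positive and negative motifs, how many motifs are
enriched for each direction.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instances import MotifInstance
from .synergy import bh_adjust

__all__ = [
    "dedup_variant_gene",
    "overlap_direction_counts",
    "permutation_enrichment",
    "fisher_meta",
]


def dedup_variant_gene(
    pairs: pd.DataFrame, key: Sequence[str] = ("variant_id", "gene")
) -> pd.DataFrame:
    """Keep one record per key, preferring the higher PIP (ties: first seen)."""
    if pairs.empty:
        return pairs.copy()
    order = np.lexsort((np.arange(len(pairs)), -pairs["pip"].to_numpy()))
    dedup = pairs.iloc[order].drop_duplicates(subset=list(key), keep="first")
    return dedup.sort_index().reset_index(drop=True)


def _overlap_matrix(
    pairs: pd.DataFrame, instances: Sequence[MotifInstance]
) -> tuple[np.ndarray, list]:
    """Boolean (n_variants x n_motifs) matrix: variant pos in [start, end)."""
    labels = sorted({inst.label for inst in instances})
    label_idx = {lab: i for i, lab in enumerate(labels)}
    by_chrom: dict[str, list[MotifInstance]] = {}
    for inst in instances:
        by_chrom.setdefault(inst.chrom, []).append(inst)
    M = np.zeros((len(pairs), len(labels)), dtype=bool)
    for row, (chrom, pos) in enumerate(zip(pairs["chrom"], pairs["pos"])):
        for inst in by_chrom.get(chrom, ()):
            if inst.start <= pos < inst.end:
                M[row, label_idx[inst.label]] = True
    return M, labels


def _dedup_instances(instances: Iterable[MotifInstance]) -> list[MotifInstance]:
    seen, out = set(), []
    for inst in instances:
        k = (inst.label, inst.chrom, inst.start, inst.end)
        if k not in seen:
            seen.add(k)
            out.append(inst)
    return out


def overlap_direction_counts(
    pairs: pd.DataFrame,
    instances: Sequence[MotifInstance],
    polarity: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed up/down variant counts per motif and per polarity cell.

    Returns (per-motif table with columns label, polarity, up, down;
    2 x 2 polarity x direction totals).  Instances are deduplicated on
    (label, position) first.
    """
    instances = _dedup_instances(instances)
    M, labels = _overlap_matrix(pairs, instances)
    up = (pairs["afc"].to_numpy() > 0)
    per_motif = pd.DataFrame(
        {
            "label": labels,
            "polarity": [polarity[lab] for lab in labels],
            "up": M[up.nonzero()[0], :].sum(axis=0) if len(pairs) else 0,
            "down": M[(~up).nonzero()[0], :].sum(axis=0) if len(pairs) else 0,
        }
    )
    cells = (
        per_motif.groupby("polarity")[["up", "down"]].sum()
        .reindex(["positive", "negative"], fill_value=0)
    )
    return per_motif, cells


def permutation_enrichment(
    pairs: pd.DataFrame,
    instances: Sequence[MotifInstance],
    polarity: Mapping[str, str],
    n_shuffles: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
    context: str = "default",
) -> pd.DataFrame:
    """Shuffle-based enrichment of directional variants in motif instances.

    The signed aFC values are permuted across variants (positions fixed,
    direction margin preserved) and per-(motif, direction) counts recounted.
    The enrichment score is observed / mean(shuffled); the empirical P is
    the pseudo-counted proportion of shuffles with a strictly larger count,
    (1 + #{shuffled > observed}) / (1 + n_shuffles), so sampled P values
    never reach zero.  A row is significant when the BH FDR across all
    (motif, direction) tests is < ``alpha`` AND the observed count exceeds
    the 97.5th percentile of shuffled counts.  Pass ``n_shuffles="exact"``
    to enumerate every distinct direction assignment instead of sampling
    (small n only); exact mode reports the plain enumeration proportion
    #{shuffled > observed} / #assignments, which can be zero.
    """
    if len(pairs) == 0 or len(instances) == 0:
        raise ValueError("need at least one variant and one instance")
    instances = _dedup_instances(instances)
    M, labels = _overlap_matrix(pairs, instances)
    up = pairs["afc"].to_numpy() > 0
    n = len(pairs)
    obs_up = M[up].sum(axis=0)
    obs_down = M[~up].sum(axis=0)

    if n_shuffles == "exact":
        k = int(up.sum())
        combos = list(itertools.combinations(range(n), k))
        shuf_up = np.zeros((len(combos), len(labels)), dtype=np.int64)
        for i, pos in enumerate(combos):
            mask = np.zeros(n, dtype=bool)
            mask[list(pos)] = True
            shuf_up[i] = M[mask].sum(axis=0)
        n_draws = len(combos)
    else:
        rng = np.random.default_rng(seed)
        n_draws = int(n_shuffles)
        shuf_up = np.empty((n_draws, len(labels)), dtype=np.int64)
        chunk = 2048
        tiled = np.tile(up.astype(np.int64), (chunk, 1))
        M_int = M.astype(np.int64)
        for lo in range(0, n_draws, chunk):
            hi = min(lo + chunk, n_draws)
            perm = rng.permuted(tiled[: hi - lo], axis=1)
            shuf_up[lo:hi] = perm @ M_int
    totals = M.sum(axis=0)
    shuf_down = totals[None, :] - shuf_up

    rows = []
    for direction, obs, shuf in (
        ("up", obs_up, shuf_up),
        ("down", obs_down, shuf_down),
    ):
        mean_shuf = shuf.mean(axis=0)
        ci_upper = np.quantile(shuf, 0.975, axis=0)
        exceed = (shuf > obs[None, :]).sum(axis=0)
        if n_shuffles == "exact":
            p = exceed / n_draws
        else:
            p = (1 + exceed) / (1 + n_draws)
        for j, lab in enumerate(labels):
            if obs[j] == 0:
                score, infinite = 0.0, False
            elif mean_shuf[j] == 0:
                score, infinite = float("inf"), True
                warnings.warn(
                    f"{lab}/{direction}: zero mean shuffled count with "
                    f"observed {obs[j]}; infinite enrichment score"
                )
            else:
                score, infinite = float(obs[j] / mean_shuf[j]), False
            rows.append(
                dict(
                    context=context,
                    label=lab,
                    polarity=polarity[lab],
                    direction=direction,
                    observed=int(obs[j]),
                    mean_shuffled=float(mean_shuf[j]),
                    enrichment_score=score,
                    score_infinite=infinite,
                    p=float(p[j]),
                    ci_upper=float(ci_upper[j]),
                )
            )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"])
    out["significant"] = (out["fdr"] < alpha) & (out["observed"] > out["ci_upper"])
    return out


def fisher_meta(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2 x 2 motif-count table.

    Returns (P, odds ratio); a zero cell forcing an infinite sample odds
    ratio is reported as ``inf``.  Degenerate margins yield P = 1 and an
    undefined (NaN) odds ratio.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2 x 2 count matrix")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0, float("nan")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p), float(odds)
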