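"""Instance calling, filtering, dedup, annotation, co-occurrence, footprints."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, pearsonr

from motifsyntax import (
    GenomeAnnotation,
    MotifInstance,
    annotate_context,
    bin_distances,
    cooccurrence_fisher,
    dedup_overlaps,
    footprint_metaplot,
    greedy_hit_caller,
    quality_filter,
    reverse_complement,
    simulate_fragments,
)
from motifsyntax.instances import UndefinedNormalizationError


def random_cwm(rng, length=6):
    return rng.normal(size=(4, length))


def brute_force_best_placement(track, cwms):
    """Oracle: exhaustively scan every (motif, offset, strand) placement."""
    best = None
    for label, cwm in cwms.items():
        for strand in "+-":
            mat = cwm if strand == "+" else reverse_complement(cwm)
            L = mat.shape[1]
            for off in range(track.shape[1] - L + 1):
                seg = track[:, off: off + L].ravel()
                if seg.std() == 0 or mat.std() == 0:
                    continue
                r = pearsonr(seg, mat.ravel())[0]
                if best is None or r > best[0]:
                    best = (r, label, strand, off)
    return best


def dedup_oracle(instances, max_overlap=3):
    """Oracle: recursively keep the best instance and drop its conflicts."""
    remaining = sorted(
        range(len(instances)),
        key=lambda i: (-instances[i].hit_correlation, instances[i].start, i),
    )
    kept = []
    for i in remaining:
        inst = instances[i]
        if all(
            k.label != inst.label
            or k.chrom != inst.chrom
            or min(inst.end, k.end) - max(inst.start, k.start) <= max_overlap
            for k in kept
        ):
            kept.append(inst)
    return sorted(kept, key=lambda x: (x.chrom, x.start, x.end))


def fisher_oracle(both, a_only, b_only, neither):
    """One-sided enrichment P by hypergeometric tail enumeration."""
    N = both + a_only + b_only + neither
    K, n = both + a_only, both + b_only
    return sum(
        hypergeom.pmf(x, N, K, n) for x in range(both, min(K, n) + 1)
    )


class TestHitCaller:
    def test_single_exact_bump(self, rng):
        cwm = random_cwm(rng, 6)
        track = np.zeros((4, 80))
        track[:, 37:43] = 2.0 * cwm
        hits = greedy_hit_caller(track, {"m": cwm}, min_similarity=0.8)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (37, 43, "+")
        assert h.hit_correlation == pytest.approx(1.0)
        oracle = brute_force_best_placement(np.zeros((4, 80)) + track, {"m": cwm})
        assert (oracle[3], oracle[1]) == (37, "m")

    def test_all_zero_track_no_hits(self, rng):
        hits = greedy_hit_caller(np.zeros((4, 50)), {"m": random_cwm(rng)})
        assert hits == []

    def test_two_disjoint_bumps_two_motifs(self, rng):
        c1, c2 = random_cwm(rng, 6), random_cwm(rng, 7)
        track = np.zeros((4, 100))
        track[:, 10:16] = c1
        track[:, 60:67] = reverse_complement(c2)  # minus-strand placement
        hits = greedy_hit_caller(track, {"m1": c1, "m2": c2}, min_similarity=0.9)
        got = {(h.label, h.start, h.strand) for h in hits}
        assert got == {("m1", 10, "+"), ("m2", 60, "-")}

    def test_empty_cwm_set_raises(self):
        with pytest.raises(ValueError):
            greedy_hit_caller(np.zeros((4, 50)), {})


class TestQualityFilter:
    def test_mixed_fixture_drops_only_permuted(self, rng):
        good, bad = random_cwm(rng, 6), random_cwm(rng, 6)
        permuted = rng.permutation(bad.ravel()).reshape(4, 6)
        track = np.zeros((4, 200))
        instances = []
        for k, start in enumerate((10, 50, 90)):
            track[:, start: start + 6] += good * (1 + 0.1 * k)
            instances.append(MotifInstance("t", start, start + 6, "+", "good", 0.95))
        for start in (130, 170):
            track[:, start: start + 6] += permuted
            instances.append(MotifInstance("t", start, start + 6, "+", "bad", 0.95))
        kept, dropped = quality_filter(
            instances, {"good": good, "bad": bad}, {"t": track}
        )
        assert set(dropped) == {"bad"}
        assert {i.label for i in kept} == {"good"}

    def test_zero_instance_motif_flagged(self, rng):
        kept, dropped = quality_filter(
            [], {"lonely": random_cwm(rng)}, {}
        )
        assert dropped == {"lonely": "zero instances"}


class TestDedup:
    def make(self, spans_corr, label="m"):
        return [
            MotifInstance("c", s, e, "+", label, r)
            for (s, e, r) in spans_corr
        ]

    def test_keeps_higher_correlation(self):
        out = dedup_overlaps(self.make([(0, 10, 0.9), (6, 16, 0.8)]))
        assert [(i.start, i.hit_correlation) for i in out] == [(0, 0.9)]

    def test_overlap_exactly_three_retained(self):
        out = dedup_overlaps(self.make([(0, 10, 0.9), (7, 17, 0.8)]))
        assert len(out) == 2

    def test_different_labels_never_conflict(self):
        a = self.make([(0, 10, 0.9)], "m1")
        b = self.make([(0, 10, 0.8)], "m2")
        assert len(dedup_overlaps(a + b)) == 2

    def test_matches_oracle_on_small_chains(self, rng):
        for trial in range(200):
            n = int(rng.integers(1, 6))
            insts = []
            for _ in range(n):
                s = int(rng.integers(0, 30))
                e = s + int(rng.integers(4, 12))
                insts.append(
                    MotifInstance(
                        "c", s, e, "+", rng.choice(["m1", "m2"]),
                        float(rng.choice([0.5, 0.7, 0.9])),
                    )
                )
            assert dedup_overlaps(insts) == dedup_oracle(insts)

    def test_input_order_invariance(self, rng):
        insts = self.make([(0, 10, 0.9), (6, 16, 0.7), (12, 22, 0.8), (30, 40, 0.6)])
        expected = dedup_overlaps(insts)
        for perm in itertools.permutations(insts):
            assert dedup_overlaps(list(perm)) == expected


class TestAnnotate:
    @pytest.fixture()
    def annotation(self):
        return GenomeAnnotation(
            tss={"chr1": [10_000]},
            exons={"chr1": [(20_000, 20_500)]},
            gene_bodies={"chr1": [(15_000, 30_000)]},
            dyads={"chr1": [11_000]},
            summits={"chr1": [10_500]},
        )

    def inst(self, center, chrom="chr1"):
        return MotifInstance(chrom, center - 5, center + 5, "+", "m", 0.9)

    def test_promoter_within_2kb(self, annotation):
        out = annotate_context([self.inst(11_500)], annotation)
        assert out["context"].iloc[0] == "promoter"
        assert out["dist_tss"].iloc[0] == 1_500

    def test_exonic_precedence_over_intronic(self, annotation):
        assert annotate_context([self.inst(20_100)], annotation)["context"].iloc[0] == "exonic"

    def test_intronic_in_gene_body_not_exon(self, annotation):
        assert annotate_context([self.inst(16_000)], annotation)["context"].iloc[0] == "intronic"

    def test_distal_otherwise(self, annotation):
        assert annotate_context([self.inst(50_000)], annotation)["context"].iloc[0] == "distal"

    def test_missing_chrom_warns_distal(self, annotation):
        with pytest.warns(UserWarning, match="absent"):
            out = annotate_context([self.inst(100, "chrX")], annotation)
        assert out["context"].iloc[0] == "distal"


class TestBins:
    def anchors(self):
        return {"chr1": [1_000]}

    def inst(self, dist, label="m"):
        c = 1_000 + dist
        return MotifInstance("chr1", c - 5, c + 5, "+", label, 0.9)

    def test_zero_distance_first_bin(self):
        counts, _ = bin_distances([self.inst(0)], self.anchors())
        assert counts.iloc[0, 0] == 1

    def test_exactly_max_dist_excluded(self):
        counts, _ = bin_distances([self.inst(250)], self.anchors())
        assert counts.to_numpy().sum() == 0

    def test_uniform_counts_zero_z(self):
        insts = [self.inst(d) for d in range(5, 250, 10)]
        counts, z = bin_distances(insts, self.anchors())
        assert (counts.to_numpy() == 1).all()
        np.testing.assert_allclose(z.to_numpy(), 0.0)

    def test_empty_anchors_raise(self):
        with pytest.raises(ValueError):
            bin_distances([self.inst(0)], {})


class TestCooccurrence:
    def test_balanced_table(self):
        inc = pd.DataFrame(
            {"A": [1, 1, 0, 0], "B": [1, 0, 1, 0]}, dtype=bool
        )
        out = cooccurrence_fisher(inc)
        assert out["p"].iloc[0] == pytest.approx(5 / 6)

    def test_perfect_cooccurrence(self):
        inc = pd.DataFrame({"A": [1] * 5 + [0] * 5, "B": [1] * 5 + [0] * 5}, dtype=bool)
        out = cooccurrence_fisher(inc)
        assert out["p"].iloc[0] == pytest.approx(1 / 252)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cooccurrence_fisher(pd.DataFrame(columns=["A", "B"]))

    def test_matches_hypergeometric_oracle(self, rng):
        for trial in range(50):
            n_peaks = int(rng.integers(2, 31))
            inc = pd.DataFrame(
                rng.integers(0, 2, size=(n_peaks, 2)), columns=["A", "B"], dtype=bool
            )
            out = cooccurrence_fisher(inc)
            both = int((inc["A"] & inc["B"]).sum())
            a_only = int((inc["A"] & ~inc["B"]).sum())
            b_only = int((~inc["A"] & inc["B"]).sum())
            neither = n_peaks - both - a_only - b_only
            assert out["p"].iloc[0] == pytest.approx(
                fisher_oracle(both, a_only, b_only, neither), abs=1e-12
            )


class TestFootprint:
    def test_uniform_rate_normalizes_to_one(self, rng):
        chrom_len = 100_000
        centers = rng.integers(500, chrom_len - 500, size=150_000)
        events = [("chr1", int(c), f"bc{i % 97}") for i, c in enumerate(centers)]
        _, tracks = simulate_fragments(events)
        anchors = [
            MotifInstance("chr1", int(p) - 5, int(p) + 5, "+", "m", 0.9)
            for p in rng.integers(1_000, chrom_len - 1_000, size=5_000)
        ]
        profile = footprint_metaplot(tracks, anchors)
        assert profile.shape == (500,)
        assert np.max(np.abs(profile - 1.0)) < 0.05

    def test_constructed_dip(self):
        track = np.full(2_000, 10.0)
        track[990:1010] = 0.0
        inst = [MotifInstance("c", 995, 1005, "+", "m", 0.9)]
        profile = footprint_metaplot({"c": track}, inst)
        assert np.allclose(profile[240:260], 0.0)
        assert np.allclose(profile[:50], 1.0)

    def test_zero_insertions_error(self):
        inst = [MotifInstance("c", 995, 1005, "+", "m", 0.9)]
        with pytest.raises(UndefinedNormalizationError):
            footprint_metaplot({"c": np.zeros(2_000)}, inst)

    def test_truncated_windows_skipped_with_warning(self):
        track = np.full(600, 5.0)
        inst = [
            MotifInstance("c", 5, 15, "+", "m", 0.9),  # window exceeds chrom start
            MotifInstance("c", 295, 305, "+", "m", 0.9),
        ]
        with pytest.warns(UserWarning, match="skipped"):
            profile = footprint_metaplot({"c": track}, inst)
        assert np.allclose(profile, 1.0)
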