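"""Synergy statistics: Wilcoxon, BH, classification, guard, AUROC, ranks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from motifsyntax import (
    SynergyThresholds,
    bh_adjust,
    classify_batch,
    classify_composite,
    cross_context_screen,
    interpretation_guard,
    optimal_arrangement,
    rank_prevalence_importance,
    rank_sum_auroc,
    wilcoxon_signed_rank_one_sided,
)
from motifsyntax import InteractionRule, PlantedModel, make_background_library
from motifsyntax.marginalize import build_edited_sequence, pair_insert_mask, Arrangement


# ---------------------------------------------------------------------------
# independent oracles

def wilcoxon_enumeration_oracle(diffs):
    """P(W+ >= observed) by brute-force enumeration of all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2 ** n


def auroc_oracle(x, y):
    wins = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
    return wins / (len(x) * len(y))


def effect_table(arr_diffs, n_seq=10, ds=1.0, noise=0.0, seed=0):
    """Synthetic effect table with specified mean dJ - dS per arrangement."""
    rng = np.random.default_rng(seed)
    rows = []
    for (orient, gap), diff in arr_diffs.items():
        for s in range(n_seq):
            dj = ds + diff + (rng.normal(0, noise) if noise else 0.0)
            rows.append((s, 0, orient, gap, gap + 8.0, 0.0, 0.5, 0.5, dj,
                         0.5, 0.5, dj, ds))
    return pd.DataFrame(
        rows,
        columns=["seq_idx", "fold", "orientation", "gap", "center_distance",
                 "y0", "yA", "yB", "yJ", "dA", "dB", "dJ", "dS"],
    )


class TestWilcoxon:
    def test_five_positive_diffs_exact(self):
        assert wilcoxon_signed_rank_one_sided([0.1, 0.2, 0.3, 0.4, 0.5]) == 1 / 32

    def test_all_zero_degenerate(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank_one_sided([0.0, 0.0]) == 1.0

    def test_tied_opposite_pair(self):
        # symmetric two-point sample: normal approximation gives exactly 1/2
        assert wilcoxon_signed_rank_one_sided([1.0, -1.0]) == pytest.approx(0.5)

    @given(
        st.lists(
            st.integers(min_value=1, max_value=1000), min_size=2, max_size=10,
            unique=True,
        ),
        st.integers(min_value=0, max_value=2 ** 10 - 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, magnitudes, signbits):
        diffs = [
            m * (1 if (signbits >> i) & 1 else -1)
            for i, m in enumerate(magnitudes)
        ]
        if all(d < 0 for d in diffs):
            diffs[0] = -diffs[0]
        p = wilcoxon_signed_rank_one_sided(diffs)
        assert p == pytest.approx(wilcoxon_enumeration_oracle(diffs), abs=1e-12)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.01])[0] == pytest.approx(0.01)

    def test_hand_step_up_triple(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw_and_order_preserving(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestOptimalArrangement:
    def test_single_arrangement(self):
        t = effect_table({("A+B+", 5): 0.3})
        assert optimal_arrangement(t) == ("A+B+", 5)

    def test_planted_spike_found(self):
        t = effect_table({("tandem", g): (0.5 if g == 5 else 0.0) for g in range(0, 30, 5)})
        assert optimal_arrangement(t) == ("tandem", 5)

    def test_tie_breaks_to_smaller_gap(self):
        t = effect_table({("tandem", 7): 0.5, ("tandem", 5): 0.5})
        assert optimal_arrangement(t) == ("tandem", 5)

    def test_tie_breaks_to_canonical_orientation(self):
        t = effect_table({("head_to_head", 5): 0.5, ("tandem", 5): 0.5})
        assert optimal_arrangement(t) == ("tandem", 5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            optimal_arrangement(effect_table({}).iloc[0:0])


class TestClassify:
    def make_tables(self):
        # two orientations x 21 gaps, comparable to a real arrangement scan
        arrangements = [
            (o, g) for o in ("A+B+", "A+B-") for g in range(0, 210, 10)
        ]
        spike = {a: 0.0 for a in arrangements}
        spike[("A+B+", 10)] = 0.5
        plateau = {
            (o, g): (0.3 if 20 <= g <= 80 else 0.0) for o, g in arrangements
        }
        null = {a: 0.0 for a in arrangements}
        return {
            "spike": effect_table(spike, n_seq=30, noise=0.01, seed=1),
            "plateau": effect_table(plateau, n_seq=30, noise=0.01, seed=2),
            "null": effect_table(null, n_seq=30, noise=0.01, seed=3),
        }

    def test_hard_soft_and_none(self):
        calls = {c.composite_id: c for c in classify_batch(self.make_tables())}
        assert calls["spike"].class_label == "hard"
        assert "soft" not in calls["spike"].classes
        assert calls["plateau"].class_label == "soft"
        assert calls["null"].class_label == "none"

    def test_strong_effect_without_significance_not_synergistic(self):
        # two sequences cannot reach p_adj < 0.001 however large the effect
        t = effect_table({("A+B+", 5): 0.8, ("A+B+", 50): 0.0}, n_seq=2)
        call = classify_composite(t)
        assert "synergistic" not in call.classes

    def test_guard_abstains(self):
        tables = self.make_tables()
        calls = classify_batch(tables, guard_pass={"spike": False})
        spike = [c for c in calls if c.composite_id == "spike"][0]
        assert spike.status == "abstained"
        assert spike.classes == frozenset()
        assert spike.class_label == "abstained"

    def test_constant_dj_flags_hard_false(self):
        t = effect_table({("A+B+", g): 0.5 for g in (5, 15, 25)}, n_seq=30)
        call = classify_composite(t)
        assert np.isnan(call.z_max)
        assert "hard" not in call.classes
        assert "soft" in call.classes  # plateau covers the soft range


class TestInterpretationGuard:
    def setup_case(self, rig_outside=False):
        a, b = "GATAACCG", "CCGGTAAT"
        flank = "TTGACGTCAT"
        effects = {a: 0.5, b: 0.7}
        if rig_outside:
            effects[flank] = 5.0
        model = PlantedModel(
            baseline=2.0, motif_effects=effects, window_length=200, n_folds=1
        )
        lib = make_background_library(
            n=4, length=200, gc_target=0.5, tolerance=0.1,
            forbidden_motifs=[a, b, flank], seed=12,
        )
        arr = Arrangement("A+B+", 5, len(a), len(b))
        seqs, masks = [], []
        for bg in lib:
            seq = build_edited_sequence(bg, a, b, arr)
            if rig_outside:
                seq = flank + seq[len(flank):]
            seqs.append(seq)
            masks.append(pair_insert_mask(200, a, b, arr))
        return model, seqs, masks

    def test_planted_mass_passes(self):
        model, seqs, masks = self.setup_case()
        passed, frac = interpretation_guard(model, seqs, masks)
        assert passed and frac > 0.9

    def test_rigged_flank_mass_abstains(self):
        model, seqs, masks = self.setup_case(rig_outside=True)
        passed, frac = interpretation_guard(model, seqs, masks)
        assert not passed and frac < 0.5

    def test_threshold_is_inclusive(self):
        model, seqs, masks = self.setup_case()
        _, frac = interpretation_guard(model, seqs, masks)
        passed, _ = interpretation_guard(model, seqs, masks, min_inside_frac=frac)
        assert passed


class TestCrossContext:
    def test_contexts_with_and_without_interaction(self):
        a, b = "GATAACCG", "CCGGTAAT"
        lib = make_background_library(
            n=5, length=300, gc_target=0.5, tolerance=0.1,
            forbidden_motifs=[a, b], seed=10,
        )
        rule = InteractionRule(a, b, "hard", 0.4, orientation="A+B+", gap=5)
        on = PlantedModel(baseline=2.0, motif_effects={a: 0.5, b: 0.7},
                          interactions=[rule], window_length=300, n_folds=2)
        off = PlantedModel(baseline=2.0, motif_effects={}, window_length=300, n_folds=2)
        out = cross_context_screen(
            {"on": on, "off": off}, lib, a, b, orientation="A+B+", gap=5
        )
        assert len(out) == 2
        vals = dict(zip(out["context"], out["mean_dJ"]))
        assert vals["on"] == pytest.approx(0.5 + 0.7 + 0.4)
        assert vals["off"] == pytest.approx(0.0)


class TestAuroc:
    def test_complete_separation(self):
        assert rank_sum_auroc([3, 4, 5], [0, 1, 2]) == 1.0

    def test_half_win(self):
        assert rank_sum_auroc([1, 3], [2]) == 0.5

    def test_single_tie(self):
        assert rank_sum_auroc([2.0], [2.0]) == 0.5

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum_auroc([], [1.0])

    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=25),
        st.lists(st.integers(0, 20), min_size=1, max_size=25),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_pair_counting_oracle(self, x, y):
        assert rank_sum_auroc(x, y) == pytest.approx(auroc_oracle(x, y))


class TestRanks:
    def test_single_motif_rank_one(self):
        values = pd.DataFrame({"context": ["c"], "motif": ["m"], "value": [5]})
        ranked, _ = rank_prevalence_importance(values, {"m": "hard"})
        assert ranked["normalized_rank"].iloc[0] == 1.0

    def test_three_counts(self):
        values = pd.DataFrame(
            {"context": "c", "motif": ["a", "b", "d"], "value": [10, 20, 30]}
        )
        ranked, means = rank_prevalence_importance(
            values, {"a": "hard", "b": "soft", "d": "hard"}
        )
        got = dict(zip(ranked["motif"], ranked["normalized_rank"]))
        assert got == {"a": pytest.approx(1 / 3), "b": pytest.approx(2 / 3),
                       "d": pytest.approx(1.0)}
        hard = means[means["group"] == "hard"]["mean_normalized_rank"].iloc[0]
        assert hard == pytest.approx((1 / 3 + 1.0) / 2)

    def test_ranks_bounded(self, rng):
        values = pd.DataFrame(
            {
                "context": np.repeat(["c1", "c2"], 10),
                "motif": [f"m{i}" for i in range(10)] * 2,
                "value": rng.integers(0, 100, size=20),
            }
        )
        ranked, _ = rank_prevalence_importance(values, {})
        assert ranked["normalized_rank"].between(0, 1).all()
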