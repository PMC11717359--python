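"""Binomial spacing statistics, clustering, and the interaction matrix."""
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spice.motif_io import consensus_to_pwm
from spice.spacing_scan import QUADRANTS, SpacingObservation
from spice.spacing_stats import (
    SpacingTestResult,
    binom_bin_pvalue,
    build_histogram,
    build_matrix,
    evalue_across_db,
    filter_and_rank,
    group_redundant,
    pwm_similarity,
    significant_bins,
    test_secondary as spacing_test,
)
from spice.synthetic_data import FixtureSpec, simulate_windows


def exact_tail(k, n, n_bins):
    """Independent oracle: exact rational tail sum of the binomial pmf."""
    p = Fraction(1, n_bins)
    return float(sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)))


def obs(quadrant, gap, i=0, sec="S"):
    return SpacingObservation(
        window_id=f"w{i}", secondary_id=sec, quadrant=quadrant, gap=gap, score=1.0
    )


def result(sec, p_adj, e_value=float("nan"), primary="lib"):
    return SpacingTestResult(
        primary_id=primary, secondary_id=sec, best_quadrant="same-down", best_gap=4,
        k=10, n=100, n_bins=604, p_raw=p_adj / 604, p_adj=p_adj, e_value=e_value,
    )


class TestHistogram:
    def test_direct_count(self):
        h = build_histogram([obs("same-down", 4, i) for i in range(10)], max_gap=20)
        assert h.count("same-down", 4) == 10 and h.n == 10

    def test_empty(self):
        h = build_histogram([], max_gap=20)
        assert h.n == 0 and h.counts == {}

    @given(st.lists(st.tuples(st.sampled_from(QUADRANTS), st.integers(0, 30)), max_size=60))
    def test_counts_conserve_n(self, pairs):
        h = build_histogram([obs(q, g, i) for i, (q, g) in enumerate(pairs)], max_gap=30)
        assert sum(h.counts.values()) == h.n == len(pairs)

    def test_mixed_secondary_ids_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            build_histogram([obs("same-up", 1, sec="A"), obs("same-up", 1, sec="B")], 5)


class TestBinomPvalue:
    def test_k_zero_is_exactly_one(self):
        assert binom_bin_pvalue(0, 50, 10) == 1.0

    def test_forced_arithmetic(self):
        assert binom_bin_pvalue(10, 10, 2) == pytest.approx(9.765625e-4, rel=1e-12)

    def test_enumeration_example(self):
        assert binom_bin_pvalue(3, 12, 10) == pytest.approx(
            exact_tail(3, 12, 10), abs=1e-12
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binom_bin_pvalue(5, 3, 10)
        with pytest.raises(ValueError):
            binom_bin_pvalue(1, 3, 0)


class TestTestSecondary:
    def test_single_bin_forced_arithmetic(self):
        h = build_histogram([obs("same-down", 1, i) for i in range(10)], max_gap=1)
        r = spacing_test(h)
        assert r.n_bins == 8
        assert r.p_raw == pytest.approx((1 / 8) ** 10, rel=1e-9)
        assert r.p_adj == pytest.approx(8 * (1 / 8) ** 10, rel=1e-9)
        assert (r.best_quadrant, r.best_gap, r.k) == ("same-down", 1, 10)

    def test_tie_breaks_smaller_gap_then_quadrant_order(self):
        h = build_histogram(
            [obs("opp-up", 3, 0), obs("same-up", 7, 1), obs("same-down", 3, 2)], 10
        )
        r = spacing_test(h)
        assert (r.best_quadrant, r.best_gap) == ("same-down", 3)

    def test_exactly_uniform_counts_are_null(self):
        o = []
        i = 0
        for q in QUADRANTS:
            for g in range(5):
                for _ in range(3):
                    o.append(obs(q, g, i))
                    i += 1
        r = spacing_test(build_histogram(o, max_gap=4))
        assert r.p_adj == 1.0

    def test_empty_flagged_no_data(self):
        r = spacing_test(build_histogram([], max_gap=10))
        assert r.no_data and r.p_adj == 1.0

    @given(
        st.lists(st.tuples(st.sampled_from(QUADRANTS), st.integers(0, 10)),
                 min_size=1, max_size=50)
    )
    def test_bonferroni_inequality(self, pairs):
        h = build_histogram([obs(q, g, i) for i, (q, g) in enumerate(pairs)], 10)
        r = spacing_test(h)
        assert r.p_raw <= r.p_adj <= 1.0


class TestEvalueAndRanking:
    def test_database_scaling(self):
        (r,) = evalue_across_db([result("A", 1e-13)], 401)
        assert r.e_value == pytest.approx(4.01e-11)
        (r,) = evalue_across_db([result("A", 1.0)], 401)
        assert r.e_value == 401.0

    def test_ordering_preserved(self, rng):
        rs = [result(f"m{i}", p) for i, p in enumerate(rng.uniform(0, 1, 20))]
        ev = evalue_across_db(rs, 50)
        order_p = sorted(ev, key=lambda r: r.p_adj)
        order_e = sorted(ev, key=lambda r: r.e_value)
        assert [r.secondary_id for r in order_p] == [r.secondary_id for r in order_e]
        for r in ev:
            assert r.e_value >= r.p_adj

    def test_db_smaller_than_tested_rejected(self):
        with pytest.raises(ValueError):
            evalue_across_db([result("A", 0.5), result("B", 0.5)], 1)

    def test_filter_and_rank(self):
        rs = [result("A", 0.5), result("B", 1e-5)]
        kept = filter_and_rank(rs, alpha=0.01)
        assert [r.secondary_id for r in kept] == ["B"]
        assert filter_and_rank([], 0.01) == []

    def test_rank_is_sorted(self, rng):
        rs = [result(f"m{i}", p) for i, p in enumerate(rng.uniform(0, 0.02, 30))]
        kept = filter_and_rank(rs, alpha=0.015)
        assert all(a.p_adj <= b.p_adj for a, b in zip(kept, kept[1:]))


class TestGrouping:
    def test_identical_pwms_merge_with_similarity_one(self):
        a = consensus_to_pwm("CAGGAAGT", id="ETS1")
        b = consensus_to_pwm("CAGGAAGT", id="ETS1b")
        assert pwm_similarity(a, b) == pytest.approx(1.0)
        preds = group_redundant(
            [result("ETS1", 1e-5), result("ETS1b", 1e-4)], {"ETS1": a, "ETS1b": b}
        )
        assert len(preds) == 1
        assert preds[0].representative.secondary_id == "ETS1"

    def test_disjoint_consensus_stay_separate(self):
        a = consensus_to_pwm("AAAAAAAA", id="polyA")
        b = consensus_to_pwm("CCCCCCCC", id="polyC")
        assert pwm_similarity(a, b) < 0.8
        preds = group_redundant(
            [result("polyA", 1e-5), result("polyC", 1e-4)], {"polyA": a, "polyC": b}
        )
        assert len(preds) == 2

    def test_shared_core_family_merges_ap1_separate(self):
        """ETS1-like and ELF1-like motifs share the GGAA core (shifted) and
        merge; the AP1-like motif stays its own cluster."""
        ets1 = consensus_to_pwm("ACAGGAAGTG", id="ETS1")
        elf1 = consensus_to_pwm("AACAGGAAGT", id="ELF1")
        ap1 = consensus_to_pwm("TGACTCA", id="JUN")
        pwms = {"ETS1": ets1, "ELF1": elf1, "JUN": ap1}
        assert pwm_similarity(ets1, elf1) >= 0.8
        assert pwm_similarity(ets1, ap1) < 0.8
        preds = group_redundant(
            [result("ETS1", 1e-6), result("ELF1", 1e-5), result("JUN", 1e-4)], pwms
        )
        assert len(preds) == 2
        assert set(preds[0].member_ids) == {"ETS1", "ELF1"}
        assert preds[0].rank == 1 and preds[1].rank == 2

    def test_cluster_tags_override_similarity(self):
        a = consensus_to_pwm("AAAAAAAA", id="a", cluster="FAM")
        b = consensus_to_pwm("CCCCCCCC", id="b", cluster="FAM")
        c = consensus_to_pwm("AAAAAAAA", id="c", cluster="OTHER")
        preds = group_redundant(
            [result("a", 1e-5), result("b", 1e-4), result("c", 1e-3)],
            {"a": a, "b": b, "c": c},
        )
        clusters = {frozenset(p.member_ids) for p in preds}
        assert frozenset({"a", "b"}) in clusters  # same tag links dissimilar
        assert frozenset({"c"}) in clusters  # different tag blocks identical


class TestMatrix:
    def test_threshold_filter(self):
        m = build_matrix(
            {"lib": [result("A", 1e-12, 4e-10), result("B", 1e-5, 4e-3)]},
            e_threshold=None,
        )
        sig = m.filtered(1e-10)
        assert sig.cells == {}  # 4e-10 and 4e-3 both fail E < 1e-10
        m2 = build_matrix(
            {"lib": evalue_across_db([result("A", 1e-14), result("B", 1e-5)], 401)},
            e_threshold=1e-10,
        )
        assert set(m2.cells) == {("lib", "A")}

    def test_empty(self):
        m = build_matrix({}, e_threshold=1e-10)
        assert m.cells == {} and m.primary_ids == []

    def test_brute_force_cell_count(self, rng):
        evals = 10.0 ** rng.uniform(-20, 2, size=200)
        results = [
            SpacingTestResult("lib", f"m{i}", "same-down", 0, 1, 1, 604,
                              0.5, 0.5, e_value=e)
            for i, e in enumerate(evals)
        ]
        m = build_matrix({"lib": results}, e_threshold=1e-10)
        assert len(m.cells) == int(np.sum(evals < 1e-10))

    def test_neglog10_grid(self):
        results = evalue_across_db([result("A", 1e-14), result("B", 1e-5)], 401)
        m = build_matrix({"lib": results}, e_threshold=None)
        grid = m.to_neglog10_frame()
        assert grid.loc["A", "lib"] == pytest.approx(-np.log10(1e-14 * 401), abs=1e-9)


class TestPlantedFractionMonotonicity:
    def test_p_raw_never_increases_with_planted_fraction(
        self, ap1_pwm, irf_pwm, uniform_bg
    ):
        from spice.spacing_scan import filter_primary, scan_secondary

        p_raws = []
        for frac in (0.2, 0.5, 0.8):
            spec = FixtureSpec(n_peaks=300, planted_fraction=frac, rng_seed=99)
            wins, _ = simulate_windows(spec)
            kept, _ = filter_primary(wins, ap1_pwm, uniform_bg, out_width=440)
            o = scan_secondary(kept, irf_pwm, uniform_bg, primary_width=7, max_gap=150)
            p_raws.append(spacing_test(build_histogram(o, 150)).p_raw)
        assert p_raws[0] >= p_raws[1] >= p_raws[2]


class TestSignificantBins:
    def test_dual_optimum_reported(self):
        o = [obs("same-down", 0, i) for i in range(12)] + [
            obs("same-down", 4, 100 + i) for i in range(10)
        ]
        bins = significant_bins(build_histogram(o, max_gap=20), alpha=0.01)
        assert {(b.best_quadrant, b.best_gap) for b in bins} == {
            ("same-down", 0),
            ("same-down", 4),
        }
        assert bins[0].p_adj <= bins[1].p_adj
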