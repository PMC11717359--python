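"""Primary anchoring, window recentering, and secondary spacing scans."""
import pytest

from conftest import random_window
from spice._seq import BASES, revcomp
from spice.motif_io import consensus_to_pwm, log_odds
from spice.peaks_windows import SequenceWindow
from spice.spacing_scan import (
    QUADRANTS,
    best_match,
    filter_primary,
    primary_footprint,
    recenter_on_primary,
    scan_secondary,
)
from spice.synthetic_data import FixtureSpec, simulate_windows


def plant(window, site, pos):
    seq = list(window.seq)
    seq[pos : pos + len(site)] = site
    window.seq = "".join(seq)
    return window


def ac_window(width, window_id="w0"):
    """A deterministic AC-repeat window: cannot contain any of the planted
    motifs (or their reverse complements) by chance, so geometry assertions
    are exact and tie-free."""
    return SequenceWindow(
        window_id=window_id, chrom="c", win_start=0, seq=("AC" * width)[:width]
    )


class TestBestMatch:
    def test_planted_consensus_found(self, rng, ap1_pwm, uniform_bg):
        win = plant(random_window(rng, 200), "TGACTCA", 63)
        m = best_match(win, ap1_pwm, uniform_bg)
        assert (m.offset, m.strand) == (63, "+")

    def test_all_n_window_has_no_match(self, ap1_pwm, uniform_bg):
        win = SequenceWindow(window_id="n", chrom="c", win_start=0, seq="N" * 100)
        assert best_match(win, ap1_pwm, uniform_bg) is None

    def test_exhaustive_oracle(self, rng, uniform_bg):
        """Vectorized best placement equals brute-force search over every
        offset and strand, exactly, on 50 random windows."""
        pwm = consensus_to_pwm("GGATGTCAT", id="x", match_prob=0.8)
        lom = log_odds(pwm, uniform_bg)
        lom_rc = lom[::-1, ::-1]
        w = len(pwm)
        for i in range(50):
            win = random_window(rng, 150, window_id=f"w{i}")
            best = None
            for o in range(150 - w + 1):
                for strand, mat in (("+", lom), ("-", lom_rc)):
                    s = 0.0
                    for j in range(w):
                        b = win.seq[o + j]
                        if b in BASES:
                            s += mat[j, BASES.index(b)]
                    if best is None or s > best[0]:
                        best = (s, o, strand)
            m = best_match(win, pwm, uniform_bg, min_score=-1e9)
            assert (m.score, m.offset, m.strand) == best


class TestRecenter:
    def test_footprint_lands_centered(self, ap1_pwm, uniform_bg):
        win = plant(ac_window(700), "TGACTCA", 300)
        m = best_match(win, ap1_pwm, uniform_bg)
        assert (m.offset, m.strand) == (300, "+")
        rec = recenter_on_primary(win, m, 500)
        assert rec.width == 500
        assert rec.seq[246:253] == "TGACTCA"  # footprint at (500-7)//2
        assert rec.win_start == win.win_start + (300 - 246)

    def test_minus_strand_is_revcomped(self, ap1_pwm, uniform_bg):
        win = plant(ac_window(700), revcomp("TGACTCA"), 350)
        m = best_match(win, ap1_pwm, uniform_bg)
        assert m.strand == "-"
        rec = recenter_on_primary(win, m, 500)
        assert rec.oriented_minus
        # recentered sequence is the revcomp of the corresponding plus slice
        plus_off = rec.win_start - win.win_start
        assert rec.seq == revcomp(win.seq[plus_off : plus_off + 500])
        assert rec.seq[246:253] == "TGACTCA"

    def test_recentering_is_idempotent(self, ap1_pwm, uniform_bg):
        win = plant(ac_window(700), "TGACTCA", 350)
        m = best_match(win, ap1_pwm, uniform_bg)
        rec = recenter_on_primary(win, m, 500)
        m2 = best_match(rec, ap1_pwm, uniform_bg)
        assert (m2.offset, m2.strand) == (246, "+")

    def test_out_of_sequence_returns_none(self, ap1_pwm, uniform_bg):
        win = plant(ac_window(300), "TGACTCA", 5)
        m = best_match(win, ap1_pwm, uniform_bg)
        assert recenter_on_primary(win, m, 298) is None


class TestFilterPrimary:
    def test_fully_planted_nothing_dropped(self, ap1_pwm, uniform_bg):
        """Every window carries an unambiguous exact site within the
        recentering slack: none may be dropped at the default threshold."""
        wins = [
            plant(ac_window(300, f"w{i}"), "TGACTCA", 146 + (i % 31) - 15)
            for i in range(80)
        ]
        kept, dropped = filter_primary(wins, ap1_pwm, uniform_bg, out_width=240)
        assert dropped == 0
        assert len(kept) == 80
        # realistic generator conditions keep essentially all windows too
        spec = FixtureSpec(
            n_peaks=80, window_width=300, mutation_rate=0.0, secondary=None,
            summit_jitter_sd=5.0, rng_seed=3,
        )
        gwins, _ = simulate_windows(spec)
        gkept, gdropped = filter_primary(gwins, ap1_pwm, uniform_bg, out_width=240)
        assert gdropped <= 2  # rare chance duplicate near a window edge

    def test_background_with_high_threshold_drops_all(self, rng, ap1_pwm, uniform_bg):
        wins = [random_window(rng, 200, window_id=f"w{i}") for i in range(30)]
        kept, dropped = filter_primary(
            wins, ap1_pwm, uniform_bg, min_score=1e6, out_width=200
        )
        assert kept == [] and dropped == 30

    def test_conservation(self, rng, ap1_pwm, uniform_bg):
        spec = FixtureSpec(n_peaks=60, window_width=300, rng_seed=5, secondary=None)
        wins, _ = simulate_windows(spec)
        kept, dropped = filter_primary(wins, ap1_pwm, uniform_bg, out_width=240)
        assert len(kept) + dropped == 60


class TestScanSecondary:
    def _centered(self, rng, n=40, width=400, plant_fn=None):
        wins = []
        for i in range(n):
            win = random_window(rng, width, window_id=f"w{i}")
            win = plant(win, "TGACTCA", (width - 7) // 2)
            if plant_fn:
                win = plant_fn(win)
            wins.append(win)
        return wins

    def test_planted_gap_recovered_exactly(self, rng, irf_pwm, uniform_bg):
        p1 = primary_footprint(400, 7)[1]
        wins = self._centered(rng, plant_fn=lambda w: plant(w, "TGAAAC", p1 + 4))
        obs = scan_secondary(wins, irf_pwm, uniform_bg, primary_width=7, max_gap=100)
        assert len(obs) == len(wins)
        # chance exact matches in the flanks can steal a few windows via the
        # smallest-offset tie-break; the planted bin must dominate heavily
        hits = sum(o.quadrant == "same-down" and o.gap == 4 for o in obs)
        assert hits >= 0.8 * len(wins)

    @pytest.mark.parametrize("quadrant", QUADRANTS)
    @pytest.mark.parametrize("gap", [0, 4, 17])
    def test_all_quadrants_by_construction(
        self, quadrant, gap, ap1_pwm, irf_pwm, uniform_bg
    ):
        """Recentering reorients randomly flipped windows, so the observed
        quadrant equals the planted one regardless of genomic strand."""
        spec = FixtureSpec(
            n_peaks=25, window_width=300, gap=gap, quadrant=quadrant,
            planted_fraction=1.0, mutation_rate=0.0, summit_jitter_sd=0.0,
            primary_strand="both", rng_seed=17,
        )
        wins, _ = simulate_windows(spec)
        kept, _ = filter_primary(wins, ap1_pwm, uniform_bg, out_width=280)
        obs = scan_secondary(kept, irf_pwm, uniform_bg, primary_width=7, max_gap=60)
        assert len(obs) == len(kept) >= 24
        hits = sum((o.quadrant, o.gap) == (quadrant, gap) for o in obs)
        assert hits >= 0.8 * len(obs)  # chance ties may steal isolated windows
        from spice.spacing_stats import build_histogram
        from spice.spacing_stats import test_secondary as spacing_test

        r = spacing_test(build_histogram(obs, 60))
        assert (r.best_quadrant, r.best_gap) == (quadrant, gap)

    def test_overlapping_placements_never_emitted(self, ap1_pwm, uniform_bg):
        """Scanning the primary PWM as its own secondary over windows whose
        only good placement IS the footprint: the exclusion rule leaves no
        qualifying placement, so nothing is emitted despite the perfect
        match sitting at the center."""
        seq = "A" * 196 + "TGACTCA" + "A" * 197
        wins = [
            SequenceWindow(window_id=f"w{i}", chrom="c", win_start=0, seq=seq)
            for i in range(5)
        ]
        obs = scan_secondary(wins, ap1_pwm, uniform_bg, primary_width=7, max_gap=100)
        assert obs == []

    def test_known_flank_word(self, rng, uniform_bg):
        """A planted IKZF1-variant-like word (GTTGCAGTTTC) in the downstream
        flank yields exactly one observation at the constructed gap."""
        word = "GTTGCAGTTTC"
        sec = consensus_to_pwm(word, id="IKZF1var", match_prob=0.9)
        p1 = primary_footprint(400, 7)[1]
        wins = self._centered(rng, n=20, plant_fn=lambda w: plant(w, word, p1 + 9))
        obs = scan_secondary(wins, sec, uniform_bg, primary_width=7, max_gap=80)
        assert all(o.quadrant == "same-down" and o.gap == 9 for o in obs)
        assert len(obs) == 20

    def test_at_most_one_observation_per_window(self, rng, irf_pwm, uniform_bg):
        wins = self._centered(rng, n=50)
        obs = scan_secondary(wins, irf_pwm, uniform_bg, primary_width=7, max_gap=100)
        assert len(obs) <= 50
        assert len({o.window_id for o in obs}) == len(obs)

    def test_secondary_too_wide_for_flank_raises(self, rng, uniform_bg):
        wide = consensus_to_pwm("A" * 60, id="wide", match_prob=0.7)
        wins = self._centered(rng, n=3, width=120)
        with pytest.raises(ValueError, match="fit"):
            scan_secondary(wins, wide, uniform_bg, primary_width=7, max_gap=40)


class TestQuadrantGeometry:
    def _window_with_pair(self, primary_site, secondary_site, gap=6, width=300):
        p0 = (width - len(primary_site)) // 2
        win = ac_window(width)
        plant(win, primary_site, p0)
        plant(win, secondary_site, p0 + len(primary_site) + gap)
        return win

    def test_whole_element_flip_leaves_quadrant_invariant(
        self, ap1_pwm, irf_pwm, uniform_bg
    ):
        """An element on the reference minus strand reads identically after
        recentering reorients the window."""
        win = self._window_with_pair("TGACTCA", "TGAAAC")
        flipped = SequenceWindow(
            window_id="f", chrom="c", win_start=0, seq=revcomp(win.seq)
        )
        for w in (win, flipped):
            m = best_match(w, ap1_pwm, uniform_bg)
            rec = recenter_on_primary(w, m, 240)
            (o,) = scan_secondary([rec], irf_pwm, uniform_bg, primary_width=7, max_gap=60)
            assert (o.quadrant, o.gap) == ("same-down", 6)

    def test_primary_only_flip_mirrors_quadrant(self, ap1_pwm, irf_pwm, uniform_bg):
        """Flipping only the planted primary strand turns same-down into
        opp-up: recentering reverses the frame while the secondary stays put."""
        win = self._window_with_pair(revcomp("TGACTCA"), "TGAAAC")
        m = best_match(win, ap1_pwm, uniform_bg)
        assert m.strand == "-"
        rec = recenter_on_primary(win, m, 240)
        (o,) = scan_secondary([rec], irf_pwm, uniform_bg, primary_width=7, max_gap=60)
        assert (o.quadrant, o.gap) == ("opp-up", 6)
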