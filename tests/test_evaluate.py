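import numpy as np
import pytest
from statsmodels.stats.proportion import proportions_ztest

from conftest import random_intervals
from lmrsvm import evaluate
from lmrsvm.evaluate import (MARKER_STATES, MarkerTracks, build_tpm,
                             categorize, conserved_midpoint_rate,
                             fantom_overlap_rate, marker_state,
                             two_proportion_ztest)
from lmrsvm.genome_io import GenomicInterval
from lmrsvm.predict import Enhancer, ScoredWindow

from _oracles import brute_nearest_edge, brute_overlap_select


def _iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def _w(start, end, chrom="chr1", score=1.0):
    return ScoredWindow(GenomicInterval(chrom, start, end), score)


class TestBuildTpm:
    def test_distance_boundary(self):
        tss = [_iv(10_000, 10_001)]
        near = _iv(9000, 9002)       # edge gap 9998 < 1000? no: 10_000-9002=998
        far = _iv(8000, 8999)        # gap 1001
        at = _iv(8000, 9000)         # gap exactly 1000: "1 kb away" not satisfied
        tracks = MarkerTracks(dhs=[near, far, at], p300=[], tf=[], tss=tss)
        tpm, report = build_tpm(tracks, tss_exclusion_bp=1000)
        assert tpm.dhs == [far]
        assert report["dhs"] == (1, 3)

    def test_no_tss_chromosome_retained(self):
        tracks = MarkerTracks(dhs=[_iv(0, 100, "chr9")], p300=[], tf=[],
                              tss=[_iv(5, 6, "chr1")])
        tpm, _ = build_tpm(tracks)
        assert len(tpm.dhs) == 1

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            build_tpm(MarkerTracks(dhs=[], p300=[], tf=[], tss=[]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        tss = [GenomicInterval(iv.chrom, iv.start, iv.start + 1)
               for iv in random_intervals(rng, 50)]
        markers = random_intervals(rng, 300)
        tracks = MarkerTracks(dhs=markers, p300=[], tf=[], tss=tss)
        tpm, _ = build_tpm(tracks, tss_exclusion_bp=1000)
        expected = [m for m in markers
                    if brute_nearest_edge(m, tss) > 1000]
        assert tpm.dhs == expected


class TestCategorize:
    def _tracks(self, dhs, tss):
        return MarkerTracks(dhs=dhs, p300=[], tf=[], tss=tss)

    def test_three_rules(self):
        tss = [_iv(50_000, 50_001)]
        # validated: TPM 800 bp away
        t1 = self._tracks([_iv(12_800, 13_000)], tss)
        # misclassified: TPM 1500 away, TSS 2000 away
        t2 = self._tracks([_iv(13_500, 13_700)], [_iv(14_000, 14_001)])
        # unknown: TPM 1500 away, TSS 3000 away
        t3 = self._tracks([_iv(13_500, 13_700)], [_iv(15_000, 15_001)])
        w = [_w(10_000, 12_000)]
        assert categorize(w, t1).categories == ["validated"]
        assert categorize(w, t2).categories == ["misclassified"]
        assert categorize(w, t3).categories == ["unknown"]

    def test_inclusive_thresholds(self):
        w = [_w(10_000, 12_000)]
        tpm_at_1000 = self._tracks([_iv(13_000, 13_200)],
                                   [_iv(50_000, 50_001)])
        assert categorize(w, tpm_at_1000).categories == ["validated"]
        tss_at_2500 = self._tracks([], [_iv(14_500, 14_501)])
        assert categorize(w, tss_at_2500).categories == ["misclassified"]

    def test_categories_partition_input(self, validation):
        assert sum(validation.counts.values()) == validation.n
        pct = validation.percentages()
        assert sum(pct.values()) == pytest.approx(100.0)


class TestMarkerState:
    @pytest.mark.parametrize("p300,dhs,tf,expected", [
        (True, False, False, "p300+/-DHS"),
        (True, True, False, "p300+/-DHS"),
        (False, True, False, "DHS only"),
        (False, True, True, "TF+DHS"),
        (False, False, True, "TF only"),
        (True, False, True, "TF+p300"),
        (True, True, True, "p300+DHS+TF"),
    ])
    def test_state_mapping(self, p300, dhs, tf, expected):
        w = _iv(10_000, 12_000)
        near = [_iv(12_500, 12_700)]
        far = [_iv(90_000, 90_200)]
        state = marker_state(w, dhs=near if dhs else far,
                             p300=near if p300 else far,
                             tf=near if tf else far)
        assert state == expected

    def test_no_marker_is_inconsistent(self):
        with pytest.raises(ValueError):
            marker_state(_iv(0, 100), dhs=[_iv(90_000, 90_100)],
                         p300=[_iv(90_000, 90_100)], tf=[_iv(90_000, 90_100)])

    def test_states_partition_validated(self, validation):
        n_state = sum(validation.state_counts.values())
        assert n_state == validation.counts["validated"]
        for cat, st in zip(validation.categories, validation.states):
            assert (st is not None) == (cat == "validated")
            if st is not None:
                assert st in MARKER_STATES


class TestFantomOverlap:
    def test_degenerate_rates(self):
        assert fantom_overlap_rate([_w(0, 100)], []) == 0.0
        giant = [_iv(0, 1_000_000)]
        assert fantom_overlap_rate([_w(10, 20), _w(500, 600)], giant) == 1.0
        assert fantom_overlap_rate([], giant) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        wins = [ScoredWindow(iv, 1.0) for iv in random_intervals(rng, 200)]
        fantom = random_intervals(rng, 100)
        rate = fantom_overlap_rate(wins, fantom)
        expected = len(brute_overlap_select(
            [w.interval for w in wins], fantom)) / 200
        assert rate == pytest.approx(expected)

    def test_order_invariant(self):
        rng = np.random.default_rng(2)
        wins = [ScoredWindow(iv, 1.0) for iv in random_intervals(rng, 100)]
        fantom = random_intervals(rng, 50)
        shuffled = list(wins)
        rng.shuffle(shuffled)
        assert fantom_overlap_rate(wins, fantom) == \
            fantom_overlap_rate(shuffled, fantom)


class TestConservedMidpoint:
    def test_midpoint_rule(self):
        enh = [_iv(1000, 3000)]       # midpoint 2000
        assert conserved_midpoint_rate(enh, [_iv(1990, 2010)], []) == 1.0
        assert conserved_midpoint_rate(enh, [_iv(2001, 2010)], []) == 0.0

    def test_exon_overlap_excluded(self):
        enh = [_iv(1000, 3000), _iv(10_000, 12_000)]
        conserved = [_iv(1990, 2010), _iv(10_990, 11_010)]
        exons = [_iv(2900, 3100)]
        assert conserved_midpoint_rate(enh, conserved, exons) == 1.0

    def test_all_exonic_undefined(self):
        enh = [_iv(0, 100)]
        assert np.isnan(conserved_midpoint_rate(enh, [_iv(0, 100)],
                                                [_iv(50, 60)]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        enh = random_intervals(rng, 150)
        conserved = random_intervals(rng, 80)
        exons = random_intervals(rng, 40)
        rate = conserved_midpoint_rate(enh, conserved, exons)
        kept = [e for e in enh
                if not any(e.chrom == x.chrom and e.start < x.end
                           and x.start < e.end for x in exons)]
        hits = sum(
            1 for e in kept
            if any(c.chrom == e.chrom and c.start <= e.midpoint < c.end
                   for c in conserved))
        assert rate == pytest.approx(hits / len(kept))


class TestTwoProportionZtest:
    def test_equal_proportions(self):
        z, p = two_proportion_ztest(30, 100, 60, 200)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_formula(self):
        x1, n1, x2, n2 = 90, 100, 50, 100
        z, p = two_proportion_ztest(x1, n1, x2, n2)
        pool = (x1 + x2) / (n1 + n2)
        se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        z_hand = (x1 / n1 - x2 / n2) / se
        assert z == pytest.approx(z_hand, rel=1e-12)
        from scipy.stats import norm
        assert p == pytest.approx(2 * norm.sf(abs(z_hand)), rel=1e-12)

    def test_antisymmetry(self):
        z1, p1 = two_proportion_ztest(40, 90, 20, 80)
        z2, p2 = two_proportion_ztest(20, 80, 40, 90)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_zero_pooled_variance(self):
        z, p = two_proportion_ztest(0, 10, 0, 10)
        assert np.isnan(z) and np.isnan(p)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            two_proportion_ztest(5, 4, 1, 10)


class TestRecoveryFscore:
    def test_perfect_and_empty(self):
        truth = [_iv(1000, 2000), _iv(5000, 6000)]
        wins = [_w(900, 2900), _w(4900, 6900)]
        m = evaluate.recovery_fscore(wins, truth)
        assert (m.precision, m.recall, m.f) == (1.0, 1.0, 1.0)
        m0 = evaluate.recovery_fscore([], truth)
        assert m0.f == 0.0

    def test_counts(self):
        truth = [_iv(1000, 2000)]
        wins = [_w(900, 2900), _w(50_000, 52_000)]
        m = evaluate.recovery_fscore(wins, truth)
        assert m.precision == 0.5 and m.recall == 1.0
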