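"""Feature scanners vs direct counting and naive re-scans."""

import numpy as np
import pytest

from breakscan import (
    at_content_windows,
    find_inverted_repeats,
    find_tandem_repeats,
    mar_propensity,
)
from breakscan.errors import DataError
from breakscan.features import merge_candidate_regions
from breakscan._seq import revcomp


class TestAtContentWindows:
    def test_all_a_sequence_fully_flagged(self):
        stats = at_content_windows("A" * 100)
        assert len(stats) == 51
        assert all(w.at_fraction == 1.0 and w.flagged for w in stats)

    def test_step_boundary_counts(self):
        seq = "A" * 50 + "G" * 50
        stats = {w.start: w for w in at_content_windows(seq)}
        assert stats[1].at_fraction == 1.0
        assert stats[26].at_fraction == 0.5
        assert stats[51].at_fraction == 0.0
        # 38/50 = 0.76 at start 13, 37/50 = 0.74 at start 14
        flagged = [w.start for w in stats.values() if w.flagged]
        assert flagged == list(range(1, 14))

    def test_alternating_at(self):
        assert all(w.at_fraction == 1.0 for w in at_content_windows("AT" * 50))

    def test_n_counts_as_neither(self):
        stats = at_content_windows("A" * 25 + "N" * 25, window=50)
        assert stats[0].at_fraction == 0.5

    def test_bad_window_rejected(self):
        with pytest.raises(DataError):
            at_content_windows("ACGT" * 20, window=0)

    def test_mean_window_fraction_matches_whole_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500, p=[0.4, 0.1, 0.1, 0.4]))
        stats = at_content_windows(seq, window=50)
        mean = sum(w.at_fraction for w in stats) / len(stats)
        whole = (seq.count("A") + seq.count("T")) / len(seq)
        assert abs(mean - whole) < 0.05  # window-edge correction only


class TestTandemRepeats:
    def test_dinucleotide_array(self):
        (rep,) = find_tandem_repeats("ACACACAC")
        assert (rep.unit, rep.copies, rep.start, rep.end) == ("AC", 4, 1, 8)

    def test_below_min_copies_empty(self):
        assert find_tandem_repeats("ACGT", min_copies=4) == []

    def test_rotated_unit_canonicalized(self):
        (rep,) = find_tandem_repeats("GCACACACA"[1:])  # "CACACACA"
        assert rep.unit == "AC"

    def test_span_is_copies_times_unit(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            for rep in find_tandem_repeats(seq):
                assert rep.end - rep.start + 1 == rep.copies * len(rep.unit)
                unit_at = seq[rep.start - 1 : rep.start - 1 + len(rep.unit)]
                assert seq[rep.start - 1 : rep.end] == unit_at * rep.copies

    def test_fixture_flank_contains_planted_ag_array(self, scaled_fixture):
        fx = scaled_fixture
        allele = fx.allele("bp-1")
        flank = fx.reference.sub(allele.north_bp - 200, allele.north_bp)
        reps = find_tandem_repeats(flank)
        assert any(r.unit == "AG" and r.copies >= 50 for r in reps)

    def test_n_breaks_arrays(self):
        reps = find_tandem_repeats("ACACNACAC", min_copies=2)
        assert all(r.end <= 4 or r.start >= 6 for r in reps)


class TestInvertedRepeats:
    def test_constructed_hairpin(self, rng):
        stem = "".join(rng.choice(list("ACGT"), size=12))
        seq = "GG" + stem + "TTTT" + revcomp(stem) + "CC"
        cands = find_inverted_repeats(seq, min_stem=10, max_loop=20)
        best = cands[0]
        assert best.stem_len >= 12 and best.loop_len == 4

    def test_random_sequence_has_no_long_stems(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        assert find_inverted_repeats(seq, min_stem=10) == []

    def test_perfect_palindrome_loop_zero(self):
        stem = "ACGTACGTACGT"
        cands = find_inverted_repeats(stem + revcomp(stem), min_stem=12, max_loop=0)
        assert cands and cands[0].loop_len == 0

    def test_strand_symmetry(self, rng):
        for _ in range(10):
            stem = "".join(rng.choice(list("ACGT"), size=11))
            pad1 = "".join(rng.choice(list("ACGT"), size=30))
            pad2 = "".join(rng.choice(list("ACGT"), size=30))
            seq = pad1 + stem + "TATA" + revcomp(stem) + pad2
            fwd = find_inverted_repeats(seq, min_stem=10)
            rev = find_inverted_repeats(revcomp(seq), min_stem=10)
            n = len(seq)
            mirrored = {
                (h.stem_len, h.loop_len, n - h.right_arm[1] + 1, n - h.left_arm[0] + 1)
                for h in rev
            }
            direct = {
                (h.stem_len, h.loop_len, h.left_arm[0], h.right_arm[1])
                for h in fwd
            }
            assert direct == mirrored


class TestMarPropensity:
    def test_all_g_window_not_candidate(self):
        (score,) = mar_propensity("G" * 300, window=300)
        assert score.at_fraction == 0 and score.motif_count == 0
        assert not score.candidate

    def test_at_window_with_motifs_is_candidate(self):
        seq = ("AT" * 50 + "ATTA" + "TA" * 50 + "ATTA" + "AT" * 46 + "ATTA")[:300]
        (score,) = mar_propensity(seq, window=300)
        assert score.candidate and score.motif_count >= 2

    def test_motifs_counted_on_both_strands(self):
        core = "TAAT" + "G" * 20 + "TAAAT"  # revcomp motifs only
        seq = ("A" * 140 + core + "T" * 140)[:300]
        (score,) = mar_propensity(seq, window=300)
        assert score.motif_count >= 2

    def test_fixture_at_tract_yields_candidate_region(self, scaled_fixture):
        fx = scaled_fixture
        tract = next(a for a in fx.annotations if a.kind == "AT_tract")
        lo = max(1, tract.start - 300)
        hi = min(len(fx.reference), tract.end + 300)
        scores = mar_propensity(fx.reference.sub(lo, hi))
        regions = merge_candidate_regions(scores)
        # some merged candidate region overlaps the planted tract
        assert any(
            lo + s - 1 <= tract.end and lo + e - 1 >= tract.start
            for s, e in regions
        )


class TestNaiveRescans:
    """Scanners agree with direct brute-force re-scans on random 1 kbp draws.

    A quick sweep here; the full 200-draw sweep runs with the acceptance
    checks.
    """

    def _draws(self, rng, n):
        for _ in range(n):
            yield "".join(
                rng.choice(list("ACGTN"), size=1_000, p=[0.3, 0.2, 0.2, 0.29, 0.01])
            )

    def test_at_windows_match_naive(self, rng):
        from oracles import naive_at_fraction

        for seq in self._draws(rng, 40):
            for w in at_content_windows(seq, window=50):
                assert w.at_fraction == naive_at_fraction(seq[w.start - 1 : w.start + 49])

    def test_mar_match_naive(self, rng):
        from oracles import naive_mar_window

        for seq in self._draws(rng, 15):
            for s in mar_propensity(seq, window=300, step=100):
                at, count = naive_mar_window(seq[s.start - 1 : s.start + 299])
                assert s.at_fraction == at and s.motif_count == count

    def test_tandem_match_naive(self, rng):
        from oracles import naive_tandem_spans

        for seq in self._draws(rng, 15):
            got = {(r.start, r.end) for r in find_tandem_repeats(seq)}
            assert got == naive_tandem_spans(seq)

    def test_inverted_match_naive(self, rng):
        from oracles import naive_inverted

        for seq in self._draws(rng, 15):
            got = {
                (h.start, h.loop_len, h.stem_len)
                for h in find_inverted_repeats(seq, min_stem=8, max_loop=6)
            }
            assert got == naive_inverted(seq, min_stem=8, max_loop=6)
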