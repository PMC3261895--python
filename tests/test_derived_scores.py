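import numpy as np
import pytest

import mappability as mp
from mappability.mappability_core import MappabilityTrack, TrackParams


def _mtrack(values, k=1, contig_lengths=None):
    values = np.asarray(values, dtype=float)
    lengths = contig_lengths or [len(values)]
    return MappabilityTrack(values, TrackParams(k, 0, None), [f"c{i}" for i in range(len(lengths))], lengths)


class TestPileup:
    def test_all_unique_interior(self):
        M = _mtrack(np.ones(50), k=5)
        assert mp.pileup_mappability(M, 25, 5) == 1.0

    def test_mean_of_covering_starts(self):
        # l=2: position 1 is covered by reads starting at 0 and 1
        M = _mtrack([1.0, 0.5, 0.0], k=2)
        assert mp.pileup_mappability(M, 1, 2) == pytest.approx(0.75)

    def test_contig_start_clips_window(self):
        M = _mtrack([0.5, 1.0, 1.0, 1.0], k=2)
        # position 0: only the read starting at 0 covers it
        assert mp.pileup_mappability(M, 0, 2) == pytest.approx(0.5)

    def test_undefined_starts_excluded_from_mean(self):
        M = _mtrack([0.0, 0.5, 0.0], k=2)
        assert mp.pileup_mappability(M, 1, 2) == pytest.approx(0.5)

    def test_no_valid_start_returns_zero(self):
        M = _mtrack([0.0, 0.0, 0.0], k=2)
        assert mp.pileup_mappability(M, 1, 2) == 0.0

    def test_read_length_must_match_track_k(self):
        M = _mtrack(np.ones(10), k=3)
        with pytest.raises(ValueError):
            mp.pileup_mappability(M, 5, 4)

    def test_window_does_not_cross_contig_boundary(self):
        M = _mtrack([0.25, 1.0, 1.0, 1.0], k=2, contig_lengths=[2, 2])
        # global position 2 = start of c1: covering start 1 is in c0
        assert mp.pileup_mappability(M, 2, 2) == pytest.approx(1.0)


class TestPairedEnd:
    """Three-case mate-rescue rule on constructed tracks (l = 1 makes the
    pileup at a position equal its own value, so cases are explicit)."""

    def _track(self, u, vminus, vplus, d=5):
        vals = np.full(2 * d + 1, 1.0)
        vals[0], vals[d], vals[2 * d] = vminus, u, vplus
        return _mtrack(vals, k=1), d

    def test_case1_target_already_maximal(self):
        M, d = self._track(1.0, 0.5, 0.5)
        lib = mp.LibrarySpec(1, d)
        assert mp.paired_end_mappability(M, d, lib) == pytest.approx(1.0)

    def test_case2_average_with_the_single_better_mate(self):
        M, d = self._track(0.2, 0.8, 0.1)
        lib = mp.LibrarySpec(1, d)
        assert mp.paired_end_mappability(M, d, lib) == pytest.approx(0.5)

    def test_case3_average_of_both_mates(self):
        M, d = self._track(0.2, 0.6, 0.8)
        lib = mp.LibrarySpec(1, d)
        assert mp.paired_end_mappability(M, d, lib) == pytest.approx(0.7)

    def test_tie_resolves_to_case2_with_strictly_better_mate(self):
        # u equal to one mate, smaller than the other -> case 2 with the
        # strictly better mate only
        M, d = self._track(0.5, 0.5, 0.9)
        lib = mp.LibrarySpec(1, d)
        assert mp.paired_end_mappability(M, d, lib) == pytest.approx(0.7)

    def test_unavailable_mates_fall_back_to_single_end(self):
        vals = np.array([0.25, 1.0, 0.25])
        M = _mtrack(vals, k=1)
        lib = mp.LibrarySpec(1, 5)  # mates off-contig
        assert mp.paired_end_mappability(M, 0, lib) == pytest.approx(0.25)

    def test_undefined_mate_is_unavailable(self):
        M, d = self._track(0.2, 0.0, 0.8)  # v- undefined
        lib = mp.LibrarySpec(1, d)
        assert mp.paired_end_mappability(M, d, lib) == pytest.approx(0.5)

    def test_rescue_never_hurts(self, small_repeat_genome):
        ref, _ = small_repeat_genome
        track = mp.compute_frequency_track(ref, 30, 1, 4)
        M = mp.frequency_to_mappability(track)
        lib = mp.LibrarySpec(30, 200)
        rng = np.random.default_rng(3)
        for p in rng.integers(0, ref.n, 50):
            p = int(p)
            u = mp.pileup_mappability(M, p, 30)
            pe = mp.paired_end_mappability(M, p, lib)
            assert pe >= u - 1e-12
            assert 0.0 <= pe <= 1.0


def _planted_two_copy_genome(unit=100, k=36, d=300):
    """Two identical copies far apart, unique flanks, single contig."""
    rng = np.random.default_rng(17)
    bg = "".join(rng.choice(list("ACGT"), 9000))
    unit_seq = "".join(rng.choice(list("ACGT"), unit))
    seq = bg[:2000] + unit_seq + bg[2000:6000] + unit_seq + bg[6000:]
    return mp.ReferenceSequence([("c1", seq)])


class TestRescueFraction:
    def test_fully_unique_genome_is_nan(self, random_dna):
        ref = mp.ReferenceSequence([("c1", random_dna(500, seed=4))])
        track = mp.exact_frequency_track(ref, 20, 0)
        frac = mp.rescue_fraction(track, mp.LibrarySpec(20, 100))
        assert np.isnan(frac)

    def test_sub_insert_repeat_fully_rescued(self):
        ref = _planted_two_copy_genome(unit=100, k=36, d=300)
        track = mp.exact_frequency_track(ref, 36, 0)
        frac = mp.rescue_fraction(track, mp.LibrarySpec(36, 300))
        assert frac == 1.0

    def test_sweep_monotone_in_d(self):
        # mixed repeat scales, far apart, away from contig ends
        rng = np.random.default_rng(21)
        bg = "".join(rng.choice(list("ACGT"), 20000))
        r1 = "".join(rng.choice(list("ACGT"), 100))
        r2 = "".join(rng.choice(list("ACGT"), 400))
        r3 = "".join(rng.choice(list("ACGT"), 1500))
        seq = (
            bg[:3000] + r1 + bg[3000:6000] + r1
            + bg[6000:9000] + r2 + bg[9000:12000] + r2
            + bg[12000:15000] + r3 + bg[15000:18000] + r3 + bg[18000:]
        )
        ref = mp.ReferenceSequence([("c1", seq)])
        track = mp.exact_frequency_track(ref, 36, 0)
        ds = [150, 600, 2000]
        sweep = mp.rescue_sweep(track, 36, ds)
        assert list(sweep.columns) == ["contig", "d", "eligible_positions", "rescued", "fraction"]
        fracs = [float(sweep[sweep.d == d].fraction.iloc[0]) for d in ds]
        assert fracs == sorted(fracs)
        assert fracs[-1] == 1.0  # all repeats shorter than the largest d

    def test_invariant_under_contig_permutation(self):
        rng = np.random.default_rng(30)
        c1 = "".join(rng.choice(list("ACGT"), 1000))
        unit = "".join(rng.choice(list("ACGT"), 60))
        c1 = c1[:300] + unit + c1[300:700] + unit + c1[700:]
        c2 = "".join(rng.choice(list("ACGT"), 800))
        for order in ([("a", c1), ("b", c2)], [("b", c2), ("a", c1)]):
            ref = mp.ReferenceSequence(list(order))
            track = mp.exact_frequency_track(ref, 30, 0)
            frac = mp.rescue_fraction(track, mp.LibrarySpec(30, 200))
            if order[0][0] == "a":
                first = frac
        assert frac == first


class TestProperLength:
    @pytest.mark.parametrize(
        "n,s,expected",
        [
            (4, 4, 1),
            (3_107_677_273, 4, 16),  # human-genome scale
            (100_281_426, 4, 14),  # nematode-genome scale
            (168_736_537, 4, 14),  # fly-genome scale
            (5, 4, 2),
        ],
    )
    def test_known_values(self, n, s, expected):
        assert mp.proper_length(n, s) == expected

    def test_boundary_is_smallest_sufficient_length(self):
        for n in (2, 16, 17, 1024):
            l = mp.proper_length(n, 4)
            assert 4**l >= n
            assert l == 0 or 4 ** (l - 1) < n


class TestLibrarySpec:
    def test_insert_must_exceed_read_length(self):
        with pytest.raises(ValueError):
            mp.LibrarySpec(100, 100)
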