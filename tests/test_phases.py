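"""Split-and-merge phase identification."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from phasevel import (
    PhaseSegParams,
    PhaseSet,
    VelocitySeries,
    drop_short_phases,
    identify_phases,
    merge_fractions,
    split_at_local_maxima,
)
from phasevel.filters import InsufficientDataError
from phasevel.phases import Phase

from conftest import make_piecewise_series


class TestSplit:
    def test_monotone_series_has_no_interior_maxima(self):
        s = VelocitySeries(np.linspace(0, 10, 50))
        assert split_at_local_maxima(s) == []

    def test_triangle_peak_gives_single_boundary(self):
        v = np.concatenate([np.arange(20.0), np.arange(20.0)[::-1]])
        b = split_at_local_maxima(VelocitySeries(v),
                                  PhaseSegParams(smooth_sigma=0.5))
        assert len(b) == 1
        assert abs(b[0] - 19) <= 1

    def test_plateau_contributes_first_index_only(self):
        # symmetric signal: the smoothed array has two equal central
        # maxima; only the first may become a boundary
        v = np.array([0.0, 1.0, 2.0, 2.0, 1.0, 0.0])
        b = split_at_local_maxima(VelocitySeries(v),
                                  PhaseSegParams(smooth_sigma=0.5))
        assert b == [2]

    def test_matches_brute_force_neighbor_scan(self, rng):
        v = rng.uniform(0, 10, 100)
        params = PhaseSegParams(smooth_sigma=3.0)
        got = split_at_local_maxima(VelocitySeries(v), params)
        s = gaussian_filter1d(v, sigma=3.0, mode="reflect", truncate=4.0)
        expected = [i for i in range(1, len(s) - 1)
                    if s[i - 1] < s[i] >= s[i + 1]]
        assert got == expected

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            split_at_local_maxima(VelocitySeries(np.array([1.0, 2.0])))


class TestMerge:
    def test_identical_fractions_merge(self):
        rng = np.random.default_rng(1)
        v = 5.0 + rng.normal(0, 0.01, 40)
        ps = merge_fractions(VelocitySeries(v), [20])
        assert len(ps) == 1

    def test_distinct_fractions_stay_separate(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([2.0 + rng.normal(0, 0.5, 20),
                            8.0 + rng.normal(0, 0.5, 20)])
        ps = merge_fractions(VelocitySeries(v), [20])
        assert len(ps) == 2
        assert [p.start for p in ps.phases] == [0, 20]

    def test_alpha_near_one_keeps_every_fraction(self, rng):
        v = rng.uniform(0, 10, 60)
        bounds = [10, 25, 40, 50]
        ps = merge_fractions(VelocitySeries(v), bounds,
                             PhaseSegParams(alpha=1 - 1e-12))
        assert len(ps) == len(bounds) + 1  # p <= 1 always

    def test_single_value_fraction_absorbed_unconditionally(self):
        v = np.concatenate([np.full(20, 2.0), [50.0], np.full(20, 2.0)])
        ps = merge_fractions(VelocitySeries(v), [20, 21])
        assert len(ps) == 1

    def test_invalid_boundaries(self):
        with pytest.raises(ValueError):
            merge_fractions(VelocitySeries(np.ones(10)), [5, 5])


class TestDropShort:
    def _mk(self, lengths):
        phases, s = [], 0
        for l in lengths:
            phases.append(Phase(s, s + l, 1.0, 0.0))
            s += l
        return PhaseSet(phases)

    def test_short_phases_removed(self):
        kept = drop_short_phases(self._mk([12, 4, 30]),
                                 PhaseSegParams(min_phase_frames=10))
        assert [p.duration_frames for p in kept.phases] == [12, 30]

    def test_all_short_gives_empty_set(self):
        kept = drop_short_phases(self._mk([3, 5]),
                                 PhaseSegParams(min_phase_frames=10))
        assert len(kept) == 0

    def test_min_one_is_identity(self):
        ps = self._mk([1, 2, 3])
        kept = drop_short_phases(ps, PhaseSegParams(min_phase_frames=1))
        assert len(kept) == len(ps)


class TestIdentifyPhases:
    def test_constant_noisy_series_is_one_phase(self, rng):
        s, _ = make_piecewise_series([5.0], [100], noise_sd=0.3, rng=rng)
        ps = identify_phases(s)
        assert len(ps) == 1
        assert (ps.phases[0].start, ps.phases[0].end) == (0, 100)
        assert ps.phases[0].mean_velocity == pytest.approx(5.0, abs=0.15)

    def test_three_epoch_series_recovers_outer_phases(self):
        # 5/2/8 px/frame epochs of 40 intervals, noise SD 0.3.  The outer
        # phases are recovered with accurate means; the middle (valley)
        # phase absorbs the sigma-smeared transitions, because splits only
        # occur at local maxima of the smoothed signal, which are sparse
        # on a low plateau flanked by two slopes.
        rng = np.random.default_rng(11)
        s, _ = make_piecewise_series([5.0, 2.0, 8.0], [40, 40, 40],
                                     noise_sd=0.3, rng=rng)
        ps = identify_phases(s)
        assert len(ps) == 3
        first, mid, last = ps.phases
        assert first.mean_velocity == pytest.approx(5.0, abs=0.2)
        assert last.mean_velocity == pytest.approx(8.0, abs=0.2)
        assert abs(first.end - 40) <= 10
        assert abs(last.start - 80) <= 15
        assert 2.0 < mid.mean_velocity < 5.0  # transition-contaminated

    def test_series_shorter_than_min_phase_is_empty(self):
        s = VelocitySeries(np.array([1.0, 2.0, 1.5, 1.8, 1.2]))
        ps = identify_phases(s, PhaseSegParams(min_phase_frames=10))
        assert len(ps) == 0

    def test_phases_partition_series_before_length_filter(self, rng):
        v = VelocitySeries(rng.uniform(0, 10, 200))
        params = PhaseSegParams()
        bounds = split_at_local_maxima(v, params)
        merged = merge_fractions(v, bounds, params)
        spans = [(p.start, p.end) for p in merged.phases]
        assert spans[0][0] == 0 and spans[-1][1] == 200
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 == s2  # contiguous, non-overlapping

    def test_phase_count_nonincreasing_as_alpha_decreases(self, rng):
        v = VelocitySeries(rng.uniform(0, 10, 300))
        counts = []
        for alpha in (1 - 1e-12, 0.5, 0.2, 0.05, 0.01, 0.001):
            params = PhaseSegParams(alpha=alpha, min_phase_frames=1)
            bounds = split_at_local_maxima(v, params)
            counts.append(len(merge_fractions(v, bounds, params)))
        assert counts == sorted(counts, reverse=True)

    def test_stored_stats_match_recomputation(self, rng):
        v = VelocitySeries(rng.uniform(0, 10, 200))
        for p in identify_phases(v, PhaseSegParams(min_phase_frames=1)).phases:
            seg = v.values[p.start:p.end]
            assert p.mean_velocity == pytest.approx(seg.mean(), abs=1e-10)
            if len(seg) > 1:
                assert p.sd_velocity == pytest.approx(seg.std(ddof=1), abs=1e-10)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            PhaseSegParams(smooth_sigma=0)
        with pytest.raises(ValueError):
            PhaseSegParams(alpha=1.0)
        with pytest.raises(ValueError):
            PhaseSegParams(min_phase_frames=0)
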