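"""Glycemic endpoint metrics: interpolation, crossings, episode logic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tgcsim.metrics import (
    endpoint_report,
    hypo_episodes,
    post_target_endpoints,
    time_in_ranges,
    time_to_target,
)


def _trace(*points):
    t = np.array([p[0] for p in points], dtype=float)
    g = np.array([p[1] for p in points], dtype=float)
    return (t, g)


class TestTimeInRanges:
    def test_constant_in_range(self):
        tr = _trace((0, 5.0), (1440, 5.0))
        assert time_in_ranges(tr) == pytest.approx((100.0, 0.0, 0.0))

    def test_step_profile_splits_evenly(self):
        """12 h above range then 12 h in range: 50/50 by sample counting."""
        t = np.arange(0, 1440, 1.0)
        g = np.where(t < 720, 7.0, 5.0)
        pct = time_in_ranges((t, g), mode="samples")
        assert pct == pytest.approx((50.0, 50.0, 0.0))
        # interpolation differs only by the single 1-min crossing segment
        pct_i = time_in_ranges((t, g), total_h=1439 / 60.0)
        assert pct_i[0] == pytest.approx(50.0, abs=0.1)

    def test_linear_ramp_closed_form(self):
        """8 -> 4 mmol/L over 24 h: in-range fraction is (6.1-4.4)/4."""
        tr = _trace((0, 8.0), (1440, 4.0))
        pct_in, pct_above, pct_below = time_in_ranges(tr)
        assert pct_in == pytest.approx((6.1 - 4.4) / 4.0 * 100.0)
        assert pct_above == pytest.approx((8.0 - 6.1) / 4.0 * 100.0)
        assert pct_below == pytest.approx((4.4 - 4.0) / 4.0 * 100.0)

    def test_boundary_value_counts_in_range(self):
        tr = _trace((0, 4.4), (100, 4.4))
        assert time_in_ranges(tr, total_h=100 / 60.0)[0] == pytest.approx(100.0)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            time_in_ranges((np.array([]), np.array([])))

    def test_partition_sums_to_hundred(self, rng):
        for _ in range(50):
            n = rng.integers(2, 40)
            t = np.sort(rng.uniform(0, 1440, size=n))
            t = np.unique(t)
            if len(t) < 2:
                continue
            g = rng.uniform(1.0, 15.0, size=len(t))
            span_h = (t[-1] - t[0]) / 60.0
            assert sum(time_in_ranges((t, g), total_h=span_h)) == pytest.approx(100.0)

    @given(st.integers(0, 2**31 - 1))
    def test_density_refinement_invariance(self, seed):
        """Inserting midpoints on the piecewise-linear path changes nothing."""
        r = np.random.default_rng(seed)
        t = np.sort(r.uniform(0, 1440, size=8))
        t = np.unique(t)
        if len(t) < 2:
            return
        g = r.uniform(2.0, 12.0, size=len(t))
        tm = (t[:-1] + t[1:]) / 2
        gm = (g[:-1] + g[1:]) / 2
        t2 = np.sort(np.concatenate([t, tm]))
        g2 = np.interp(t2, t, g)
        a = time_in_ranges((t, g), total_h=24.0)
        b = time_in_ranges((t2, g2), total_h=24.0)
        assert a == pytest.approx(b)


class TestTimeToTarget:
    def test_starting_in_range_is_zero(self):
        assert time_to_target(_trace((0, 5.0), (100, 5.5))) == 0.0

    def test_descending_crossing_closed_form(self):
        """Linear 9 -> 5 over 8 h crosses the 6.1 bound at 5.8 h."""
        tr = _trace((0, 9.0), (480, 5.0))
        assert time_to_target(tr) == pytest.approx((9.0 - 6.1) / 4.0 * 8.0)

    def test_never_reached_is_none(self):
        assert time_to_target(_trace((0, 9.0), (480, 8.0))) is None

    def test_crossing_from_below(self):
        tr = _trace((0, 3.0), (120, 5.0))
        assert time_to_target(tr) == pytest.approx((4.4 - 3.0) / 2.0 * 2.0)


class TestHypoEpisodes:
    def test_no_excursion(self):
        assert hypo_episodes(_trace((0, 5.0), (500, 3.6), (1000, 5.0))) == 0

    def test_single_dip_with_recovery(self):
        tr = _trace((0, 5.0), (100, 2.5), (200, 5.0), (1000, 5.0))
        assert hypo_episodes(tr) == 1

    def test_shallow_recovery_merges_excursions(self):
        """Dip, brief rise to 3.2 (below the 3.9 exit), dip again: one episode."""
        tr = _trace((0, 5.0), (60, 2.8), (90, 3.2), (100, 3.2), (130, 2.7), (300, 5.0))
        assert hypo_episodes(tr) == 1

    def test_sustained_recovery_separates_episodes(self):
        tr = _trace((0, 5.0), (60, 2.8), (120, 5.0), (240, 5.0), (300, 2.8), (360, 5.0))
        assert hypo_episodes(tr) == 2

    def test_short_recovery_above_exit_still_merges(self):
        """Recovery above exit but shorter than 30 min does not end the episode."""
        tr = _trace((0, 5.0), (60, 2.8), (70, 4.2), (80, 2.8), (300, 5.0))
        assert hypo_episodes(tr) == 1

    def test_refinement_invariance(self):
        tr = _trace((0, 5.0), (60, 2.8), (90, 3.2), (130, 2.7), (300, 5.0))
        t, g = tr
        tm = (t[:-1] + t[1:]) / 2
        t2 = np.sort(np.concatenate([t, tm]))
        g2 = np.interp(t2, t, g)
        assert hypo_episodes((t2, g2)) == hypo_episodes(tr)


class TestPostTarget:
    def test_whole_trace_in_range_equals_whole_study(self):
        tr = _trace((0, 5.0), (1440, 5.5))
        frag = post_target_endpoints(tr)
        assert frag.pct_in == pytest.approx(100.0)
        assert frag.mean_bg_mmol_l == pytest.approx(5.25)

    def test_ramp_restricts_to_post_crossing_segment(self):
        """8 -> 4 ramp: post-target metrics cover [crossing of 6.1, end]."""
        tr = _trace((0, 8.0), (1440, 4.0))
        frag = post_target_endpoints(tr)
        assert frag.mean_bg_mmol_l == pytest.approx((6.1 + 4.0) / 2.0)
        assert frag.pct_in == pytest.approx((6.1 - 4.4) / (6.1 - 4.0) * 100.0)
        assert frag.pct_above == pytest.approx(0.0)
        assert frag.duration_h == pytest.approx(24.0 - (8.0 - 6.1) / 4.0 * 24.0, rel=1e-9)

    def test_never_reached_flagged(self):
        assert post_target_endpoints(_trace((0, 9.0), (100, 8.0))) is None


def test_endpoint_report_references_insulin_start():
    tr = _trace((0, 9.0), (480, 5.0))
    rep = endpoint_report(tr, insulin_start_min=60.0)
    assert rep.target_reached
    assert rep.time_to_target_h == pytest.approx((9.0 - 6.1) / 4.0 * 8.0 - 1.0)
    assert rep.mean_bg_mmol_l == pytest.approx(7.0)
    assert rep.hypo_count == 0


def test_endpoint_report_never_reached():
    rep = endpoint_report(_trace((0, 9.0), (480, 7.0)))
    assert not rep.target_reached
    assert rep.time_to_target_h is None
    assert rep.post_target is None
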