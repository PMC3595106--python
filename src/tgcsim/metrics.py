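"""Glycemic-control endpoints of a trial trace.

Endpoints: whole-study average glycemia; time to the 4.4-6.1 mmol/L
target range; percentage of study time within / above / below the range
(hours in range / 24 * 100); the same metrics after reaching the target;
and the number of hypoglycemic episodes (<= 2.9 mmol/L).

The glucose path between samples is treated as piecewise linear and
boundary-crossing times are found analytically, so all metrics are
independent of the sampling resolution. A per-sample counting mode is
available for sensitivity checks (``mode="samples"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EndpointReport",
    "PostTargetMetrics",
    "time_in_ranges",
    "time_to_target",
    "hypo_episodes",
    "post_target_endpoints",
    "endpoint_report",
]


def _as_arrays(trace) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a trace (DataFrame, Nx2 array, or (t, g) pair) to arrays."""
    if isinstance(trace, pd.DataFrame):
        t = trace["t_min"].to_numpy(dtype=float)
        g = trace["g_mmol_l"].to_numpy(dtype=float)
    elif isinstance(trace, tuple) and len(trace) == 2:
        t = np.asarray(trace[0], dtype=float)
        g = np.asarray(trace[1], dtype=float)
    else:
        arr = np.asarray(trace, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("trace must be a DataFrame, (t, g) pair, or Nx2 array")
        t, g = arr[:, 0], arr[:, 1]
    if len(t) == 0:
        raise ValueError("trace is empty")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("trace times must be strictly increasing")
    return t, g


def _band_times(
    t: np.ndarray, g: np.ndarray, lo: float, hi: float
) -> tuple[float, float, float]:
    """Minutes spent in / above / below [lo, hi] along the linear path."""
    t_in = t_above = t_below = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        g0, g1 = g[i], g[i + 1]
        if g0 == g1:
            if lo <= g0 <= hi:
                t_in += dt
            elif g0 > hi:
                t_above += dt
            else:
                t_below += dt
            continue
        gmin, gmax = min(g0, g1), max(g0, g1)
        span = gmax - gmin
        in_len = max(0.0, min(gmax, hi) - max(gmin, lo))
        above_len = max(0.0, gmax - max(gmin, hi))
        below_len = max(0.0, min(gmax, lo) - gmin)
        t_in += dt * in_len / span
        t_above += dt * above_len / span
        t_below += dt * below_len / span
    return t_in, t_above, t_below


def time_in_ranges(
    trace,
    lo: float = 4.4,
    hi: float = 6.1,
    total_h: float = 24.0,
    mode: str = "interpolate",
) -> tuple[float, float, float]:
    """Percent of time in / above / below [lo, hi].

    Percentages are hours in each stratum divided by ``total_h`` times
    100. With ``mode="samples"`` the fraction of samples is used instead
    of the interpolated path. Boundary values count as in range.
    """
    t, g = _as_arrays(trace)
    if mode == "samples":
        n = len(g)
        n_in = int(np.sum((g >= lo) & (g <= hi)))
        n_above = int(np.sum(g > hi))
        scale = 100.0 / n
        return n_in * scale, n_above * scale, (n - n_in - n_above) * scale
    if mode != "interpolate":
        raise ValueError(f"unknown mode {mode!r}")
    t_in, t_above, t_below = _band_times(t, g, lo, hi)
    scale = 100.0 / (total_h * 60.0)
    return t_in * scale, t_above * scale, t_below * scale


def time_to_target(trace, lo: float = 4.4, hi: float = 6.1) -> float | None:
    """Hours from trace start to the first interpolated entry into [lo, hi].

    Returns ``None`` when the range is never reached.
    """
    t, g = _as_arrays(trace)
    if lo <= g[0] <= hi:
        return 0.0
    for i in range(len(t) - 1):
        g0, g1 = g[i], g[i + 1]
        dt = t[i + 1] - t[i]
        if lo <= g1 <= hi or (g0 > hi and g1 < lo) or (g0 < lo and g1 > hi):
            # entering from above crosses hi first; from below crosses lo
            if g0 > hi:
                s = (hi - g0) / (g1 - g0)
            elif g0 < lo:
                s = (lo - g0) / (g1 - g0)
            else:  # pragma: no cover - g0 in range handled earlier
                s = 0.0
            return (t[i] + s * dt - t[0]) / 60.0
    return None


def hypo_episodes(
    trace,
    threshold: float = 2.9,
    exit: float = 3.9,
    min_separation_min: float = 30.0,
) -> int:
    """Count hypoglycemic episodes (glucose <= ``threshold``).

    An episode begins when the interpolated path reaches ``threshold``
    and ends only after glucose has stayed at or above ``exit`` for at
    least ``min_separation_min`` minutes; shallower recoveries merge
    adjacent excursions into one episode.
    """
    t, g = _as_arrays(trace)
    count = 0
    in_episode = False
    recovery_min = 0.0
    for i in range(len(t) - 1):
        # split the segment at crossings of both thresholds
        g0, g1 = g[i], g[i + 1]
        dt = t[i + 1] - t[i]
        cuts = {0.0, 1.0}
        for level in (threshold, exit):
            if g0 != g1:
                s = (level - g0) / (g1 - g0)
                if 0.0 < s < 1.0:
                    cuts.add(s)
        cuts = sorted(cuts)
        for s0, s1 in zip(cuts[:-1], cuts[1:]):
            g_start = g0 + s0 * (g1 - g0)
            if g_start <= threshold and not in_episode:
                count += 1
                in_episode = True
                recovery_min = 0.0
            mid = g0 + 0.5 * (s0 + s1) * (g1 - g0)
            dur = (s1 - s0) * dt
            if dur <= 0:
                continue
            if mid <= threshold:
                if not in_episode:
                    count += 1
                    in_episode = True
                recovery_min = 0.0
            elif mid >= exit:
                recovery_min += dur
                if in_episode and recovery_min >= min_separation_min:
                    in_episode = False
            else:
                recovery_min = 0.0
    # terminal point
    if g[-1] <= threshold and not in_episode:
        count += 1
    return count


@dataclass(frozen=True)
class PostTargetMetrics:
    """Endpoint fragment restricted to the time after reaching target."""

    mean_bg_mmol_l: float
    pct_in: float
    pct_above: float
    pct_below: float
    duration_h: float

    def to_dict(self) -> dict:
        return {
            "mean_bg_mmol_l": self.mean_bg_mmol_l,
            "pct_in": self.pct_in,
            "pct_above": self.pct_above,
            "pct_below": self.pct_below,
            "duration_h": self.duration_h,
        }


def _restrict_from(t: np.ndarray, g: np.ndarray, t_from: float):
    """Sub-trace on [t_from, end] with an interpolated first point."""
    idx = np.searchsorted(t, t_from, side="left")
    if idx < len(t) and t[idx] == t_from:
        return t[idx:], g[idx:]
    g_at = float(np.interp(t_from, t, g))
    return np.concatenate(([t_from], t[idx:])), np.concatenate(([g_at], g[idx:]))


def post_target_endpoints(
    trace, lo: float = 4.4, hi: float = 6.1
) -> PostTargetMetrics | None:
    """Endpoints over [first entry into range, end of trace].

    Returns ``None`` when the target range is never reached.
    """
    t, g = _as_arrays(trace)
    ttt = time_to_target((t, g), lo, hi)
    if ttt is None:
        return None
    t_from = t[0] + ttt * 60.0
    ts, gs = _restrict_from(t, g, t_from)
    duration_min = ts[-1] - ts[0]
    if duration_min <= 0:
        return PostTargetMetrics(float(gs[-1]), 100.0, 0.0, 0.0, 0.0)
    mean_bg = float(np.trapezoid(gs, ts) / duration_min)
    pct = time_in_ranges((ts, gs), lo, hi, total_h=duration_min / 60.0)
    return PostTargetMetrics(mean_bg, *pct, duration_h=duration_min / 60.0)


@dataclass(frozen=True)
class EndpointReport:
    """All protocol endpoints computed from one glucose trace."""

    mean_bg_mmol_l: float
    time_to_target_h: float | None
    target_reached: bool
    pct_in: float
    pct_above: float
    pct_below: float
    hypo_count: int
    n_samples: int
    post_target: PostTargetMetrics | None

    def to_dict(self) -> dict:
        return {
            "mean_bg_mmol_l": self.mean_bg_mmol_l,
            "time_to_target_h": self.time_to_target_h,
            "target_reached": self.target_reached,
            "pct_in": self.pct_in,
            "pct_above": self.pct_above,
            "pct_below": self.pct_below,
            "hypo_count": self.hypo_count,
            "n_samples": self.n_samples,
            "post_target": self.post_target.to_dict() if self.post_target else None,
        }


def endpoint_report(
    trace,
    lo: float = 4.4,
    hi: float = 6.1,
    insulin_start_min: float = 0.0,
    total_h: float | None = None,
    hypo_threshold: float = 2.9,
    mode: str = "interpolate",
) -> EndpointReport:
    """Compute the full endpoint report for one trial trace.

    ``time_to_target_h`` is referenced to ``insulin_start_min``;
    ``total_h`` defaults to the trace span.
    """
    t, g = _as_arrays(trace)
    span_min = t[-1] - t[0]
    if total_h is None:
        total_h = span_min / 60.0 if span_min > 0 else 1.0
    mean_bg = (
        float(np.trapezoid(g, t) / span_min) if span_min > 0 else float(g[0])
    )
    pct = time_in_ranges((t, g), lo, hi, total_h=total_h, mode=mode)
    ttt_abs = time_to_target((t, g), lo, hi)
    if ttt_abs is None:
        ttt = None
        reached = False
    else:
        ttt = max(0.0, ttt_abs - (insulin_start_min - t[0]) / 60.0)
        reached = True
    return EndpointReport(
        mean_bg_mmol_l=mean_bg,
        time_to_target_h=ttt,
        target_reached=reached,
        pct_in=pct[0],
        pct_above=pct[1],
        pct_below=pct[2],
        hypo_count=hypo_episodes((t, g), threshold=hypo_threshold),
        n_samples=len(g),
        post_target=post_target_endpoints((t, g), lo, hi),
    )
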