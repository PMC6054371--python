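"""Telemetry cleaning: speed filter, deployment trimming, even-hour binning,
and removal of non-independent individuals by coordinate correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import Track

__all__ = [
    "QCReport",
    "speed_filter",
    "trim_window",
    "bin_to_even_hours",
    "screen_independence",
    "clean_tracks",
]


@dataclass
class QCReport:
    """Per-stage accounting of removed fixes and individuals."""

    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    pairwise_r: list[dict] = field(default_factory=list)
    removed_individuals: list[dict] = field(default_factory=list)

    def record(self, stage: str, individual: str, n_in: int, n_out: int) -> None:
        d = self.stage_counts.setdefault(stage, {})
        d[individual] = d.get(individual, 0) + (n_in - n_out)

    def removed(self, stage: str) -> int:
        return sum(self.stage_counts.get(stage, {}).values())


def speed_filter(track: Track, v_max_kmh: float = 20.0) -> tuple[Track, int]:
    """Drop fixes implying travel faster than ``v_max_kmh`` from the last
    retained fix.

    Sequential scan with a sliding anchor: the first fix is always kept;
    each later fix is compared with the most recent *retained* fix, and
    discarded if straight-line distance / elapsed time exceeds the limit
    (the anchor then stays put, so a run of aberrant fixes is removed
    against the same good anchor).
    """
    if v_max_kmh <= 0:
        raise ValueError("v_max must be positive")
    n = len(track)
    if n == 0:
        return track, 0
    keep = np.zeros(n, dtype=bool)
    keep[0] = True
    anchor = 0
    t_h = track.t.astype("datetime64[s]").astype(np.int64) / 3600.0
    for i in range(1, n):
        dt_h = t_h[i] - t_h[anchor]
        if dt_h <= 0:
            raise ValueError(
                f"non-positive elapsed time at fix {i} of {track.individual_id} "
                "(duplicate timestamp?)"
            )
        d_km = np.hypot(track.x[i] - track.x[anchor], track.y[i] - track.y[anchor]) / 1000.0
        if d_km / dt_h > v_max_kmh:
            continue
        keep[i] = True
        anchor = i
    out = track.replace(t=track.t[keep], x=track.x[keep], y=track.y[keep])
    return out, int(n - keep.sum())


def trim_window(track: Track, buffer_hours: float = 24.0) -> Track:
    """Drop fixes within ``buffer_hours`` of deployment and of track end.

    A missing deploy/end bound leaves that side untrimmed.  A window that
    swallows the whole track yields an empty track with a warning.
    """
    buf = np.timedelta64(int(round(buffer_hours * 3600)), "s")
    keep = np.ones(len(track), dtype=bool)
    if track.deploy_time is not None:
        keep &= track.t >= np.datetime64(track.deploy_time) + buf
    if track.end_time is not None:
        keep &= track.t <= np.datetime64(track.end_time) - buf
    if len(track) and not keep.any():
        warnings.warn(f"trim window removed every fix of {track.individual_id}")
    return track.replace(t=track.t[keep], x=track.x[keep], y=track.y[keep])


def bin_to_even_hours(track: Track, window_minutes: float = 5.0) -> Track:
    """Keep fixes within ``window_minutes`` of a whole hour, relabelled to it.

    When several fixes fall in the same hour bin the one closest to the
    hour wins (the earlier fix on ties).
    """
    if not 0 < window_minutes < 30:
        raise ValueError("window_minutes must be in (0, 30)")
    if len(track) == 0:
        return track
    t_s = track.t.astype("datetime64[s]").astype(np.int64)
    nearest = np.round(t_s / 3600.0).astype(np.int64) * 3600
    off = np.abs(t_s - nearest)
    ok = off <= window_minutes * 60
    order = np.arange(len(track))[ok]
    best: dict[int, int] = {}
    for i in order:  # earlier wins ties because strict inequality
        h = nearest[i]
        if h not in best or off[i] < off[best[h]]:
            best[h] = i
    idx = np.array(sorted(best.values(), key=lambda i: nearest[i]), dtype=int)
    if len(idx) == 0:
        return track.replace(t=track.t[:0], x=track.x[:0], y=track.y[:0])
    new_t = nearest[idx].astype("datetime64[s]").astype("datetime64[ns]")
    return track.replace(t=new_t, x=track.x[idx], y=track.y[idx])


def _pair_correlation(a: Track, b: Track, min_overlap: int):
    ta = a.t.astype(np.int64)
    tb = b.t.astype(np.int64)
    common, ia, ib = np.intersect1d(ta, tb, return_indices=True)
    if len(common) < min_overlap:
        return None
    out = {}
    for axis, va, vb in (("x", a.x[ia], b.x[ib]), ("y", a.y[ia], b.y[ib])):
        sa, sb = va.std(), vb.std()
        if sa == 0 or sb == 0:
            # degenerate axis: identical flat coordinates count as dependent
            out[axis] = 1.0 if (sa == 0 and sb == 0 and np.allclose(va, vb)) else np.nan
        else:
            out[axis] = float(np.corrcoef(va, vb)[0, 1])
    out["n_matched"] = int(len(common))
    return out


def screen_independence(
    tracks: list[Track],
    r_threshold: float = 0.5,
    min_overlap: int = 30,
    seed: int = 0,
) -> tuple[list[Track], QCReport]:
    """Remove one member of every dependent pair of individuals.

    For every pair of tracks (already binned to even hours), fixes are
    matched on identical bin times; with at least ``min_overlap`` matches,
    Pearson r is computed separately on x and y.  A pair is dependent iff
    |r| exceeds the threshold on *both* axes.  Dependent pairs form a
    graph from which a random flagged edge is drawn and a random endpoint
    removed (seeded), repeating until no flagged edge remains.
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    report = QCReport()
    edges = set()
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            rr = _pair_correlation(tracks[i], tracks[j], min_overlap)
            if rr is None:
                continue
            rx, ry = rr["x"], rr["y"]
            if np.isnan(rx) or np.isnan(ry):
                warnings.warn(
                    f"undefined correlation for pair "
                    f"({tracks[i].individual_id}, {tracks[j].individual_id}); skipped"
                )
                continue
            flagged = abs(rx) > r_threshold and abs(ry) > r_threshold
            report.pairwise_r.append(
                {
                    "a": tracks[i].individual_id,
                    "b": tracks[j].individual_id,
                    "r_x": rx,
                    "r_y": ry,
                    "n_matched": rr["n_matched"],
                    "dependent": flagged,
                }
            )
            if flagged:
                edges.add((i, j))
    rng = np.random.default_rng(seed)
    removed: set[int] = set()
    live = set(edges)
    while live:
        edge = sorted(live)[rng.integers(len(live))]
        victim = edge[rng.integers(2)]
        removed.add(victim)
        rec = next(r for r in report.pairwise_r
                   if {r["a"], r["b"]}
                   == {tracks[edge[0]].individual_id, tracks[edge[1]].individual_id})
        report.removed_individuals.append(
            {"individual_id": tracks[victim].individual_id,
             "pair": (rec["a"], rec["b"]), "r_x": rec["r_x"], "r_y": rec["r_y"]}
        )
        live = {e for e in live if victim not in e}
    retained = [tr for k, tr in enumerate(tracks) if k not in removed]
    report.stage_counts["independence"] = {
        tracks[k].individual_id: len(tracks[k]) for k in sorted(removed)
    }
    return retained, report


def clean_tracks(
    tracks: list[Track],
    v_max_kmh: float = 20.0,
    trim_hours: float = 24.0,
    bin_window_minutes: float = 5.0,
    r_threshold: float = 0.5,
    min_overlap: int = 30,
    seed: int = 0,
) -> tuple[list[Track], QCReport]:
    """Full QC pipeline: speed filter, trimming, binning, dependence screen."""
    staged = []
    report = QCReport()
    for tr in tracks:
        n0 = len(tr)
        filt, n_removed = speed_filter(tr, v_max_kmh)
        report.record("speed_filter", tr.individual_id, n0, n0 - n_removed)
        trimmed = trim_window(filt, trim_hours)
        report.record("trim_window", tr.individual_id, len(filt), len(trimmed))
        binned = bin_to_even_hours(trimmed, bin_window_minutes)
        report.record("bin_to_even_hours", tr.individual_id, len(trimmed), len(binned))
        if len(binned):
            staged.append(binned)
    retained, indep_report = screen_independence(staged, r_threshold, min_overlap, seed)
    report.pairwise_r = indep_report.pairwise_r
    report.removed_individuals = indep_report.removed_individuals
    report.stage_counts["independence"] = indep_report.stage_counts["independence"]
    return retained, report
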