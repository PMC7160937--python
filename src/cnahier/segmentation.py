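"""Savitzky-Golay smoothing and amplitude-shift change-point detection.

The RD signal is smoothed with a Savitzky-Golay (local least-squares
polynomial) filter, which flattens short-term noise and low-frequency wave
artifacts while preserving sharp copy-number edges without phase shift.
Change points are then found with an amplitude-restricted variant of the
Varri segmentation statistic: at every interior bin ``t`` we compare the mean
of the ``w`` bins to the left against the ``w`` bins to the right,

    G(t) = | mean(s[t-w : t]) - mean(s[t : t+w]) |,

and keep local maxima of G exceeding ``k`` times the robust per-bin noise
scale (estimated from first differences of the *unsmoothed* signal, so the
threshold is in honest per-bin sigma units).  Accepted points are at least
``w`` bins apart; on conflict the higher-G point wins, ties to the left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

#: masked runs at least this many bins long act as hard segment boundaries
#: (assembly gaps / centromeres must not be bridged)
HARD_GAP_BINS = 100


@dataclass
class ChangePointSet:
    chromosome: str
    positions: np.ndarray  # sorted bin indices
    scores: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class Segment:
    """A primary segment: half-open bin range with summary statistics."""

    chromosome: str
    start_bin: int
    end_bin: int
    mean_rd: float
    mean_cn: float
    n_unmasked_bins: int
    excluded: bool = False  # fully-masked territory (gap/centromere)
    segment_id: int = field(default=-1)

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


def _interpolate_missing(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bridge NaN runs by linear interpolation; returns (filled, was_missing)."""
    x = np.asarray(signal, dtype=float)
    missing = ~np.isfinite(x)
    if missing.all():
        raise ValueError("signal is entirely missing")
    if missing.any():
        idx = np.arange(x.size)
        x = x.copy()
        x[missing] = np.interp(idx[missing], idx[~missing], x[~missing])
    return x, missing


def sg_smooth(signal: np.ndarray, window: int = 51, order: int = 3) -> np.ndarray:
    """Savitzky-Golay smooth a signal that may contain missing (NaN) bins.

    Missing bins are bridged by linear interpolation before filtering (so the
    kernel never sees sentinels) and re-masked to NaN afterwards.  Polynomials
    of degree <= ``order`` pass through unchanged on the interior, and the
    symmetric kernel introduces no phase shift.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be < window")
    x, missing = _interpolate_missing(signal)
    if window >= x.size:
        raise ValueError(
            f"window ({window}) must be smaller than the signal "
            f"({x.size} bins); use a smaller window"
        )
    sm = savgol_filter(x, window_length=window, polyorder=order, mode="interp")
    sm[missing] = np.nan
    return sm


def _robust_noise_sd(signal: np.ndarray) -> float:
    """Per-bin noise scale: 1.4826 * MAD of first differences / sqrt(2).

    First differences cancel any piecewise-constant structure (steps affect
    only one diff each, which the median ignores), so this tracks the noise
    floor, not the copy-number signal.
    """
    x = np.asarray(signal, dtype=float)
    d = np.diff(x[np.isfinite(x)])
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def varri_change_points(smoothed: np.ndarray, window_w: int = 30,
                        threshold_k: float = 4.0,
                        raw: np.ndarray | None = None,
                        chromosome: str = "",
                        mask: np.ndarray | None = None) -> ChangePointSet:
    """Detect amplitude-shift points of a (smoothed) RD signal.

    Parameters
    ----------
    smoothed
        Signal the statistic is computed on (NaNs bridged internally).
    window_w
        Half-window ``w`` (bins) of the mean-difference statistic; also the
        minimum spacing between accepted change points.
    threshold_k
        Acceptance threshold in units of the robust per-bin noise SD.
    raw
        Pre-smoothing signal used for the noise-scale estimate; defaults to
        ``smoothed`` (on noiseless input either choice gives scale 0, making
        every true step detectable).
    mask
        Optional boolean per-bin exclusion; change points falling on masked
        bins are dropped.
    """
    if window_w < 5:
        raise ValueError("window_w must be >= 5 bins")
    x, missing = _interpolate_missing(smoothed)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values remain after interpolation")
    n = x.size
    w = int(window_w)
    if n < 2 * w + 1:
        return ChangePointSet(chromosome, np.empty(0, int), np.empty(0))

    sigma = _robust_noise_sd(raw if raw is not None else x)
    thr = max(threshold_k * sigma, 1e-12 * max(np.abs(x).max(), 1.0))

    csum = np.concatenate([[0.0], np.cumsum(x)])
    t = np.arange(w, n - w + 1)
    left = (csum[t] - csum[t - w]) / w
    right = (csum[t + w] - csum[t]) / w
    G = np.abs(right - left)

    # local maxima (plateau -> leftmost point) above threshold
    cand = []
    for j in range(G.size):
        if G[j] <= thr:
            continue
        if j > 0 and G[j - 1] >= G[j]:
            continue
        if j < G.size - 1 and G[j + 1] > G[j]:
            continue
        cand.append(j)

    # enforce min spacing w: greedy by descending score, ties to the left;
    # also suppress smoothing sidelobes - secondary maxima within 2w of a
    # kept point at under 10% of its score (true neighbouring steps need a
    # plateau of >= 2x the smoothing window anyway)
    order = sorted(cand, key=lambda j: (-G[j], j))
    kept: list[int] = []
    for j in order:
        if any(abs(j - k) < w for k in kept):
            continue
        if any(abs(j - k) < 2 * w and G[j] < 0.1 * G[k] for k in kept):
            continue
        kept.append(j)
    kept.sort()
    positions = t[kept]
    scores = G[kept]

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        keep = ~mask[positions]
        positions, scores = positions[keep], scores[keep]

    return ChangePointSet(chromosome, positions, scores)


def _masked_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True at least ``min_len`` long."""
    runs = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def build_primary_segments(profile, cps: ChangePointSet, ref=None,
                           hard_gap_bins: int = HARD_GAP_BINS) -> list[Segment]:
    """Cut the chromosome at change points into primary segments.

    Long masked runs (>= ``hard_gap_bins``) additionally split segments and
    are emitted as ``excluded`` segments so no block ever spans an assembly
    gap.  Per-segment mean RD is taken over unmasked bins only; mean CN is
    filled in when a :class:`CNReference` is supplied.
    """
    v = profile.values
    n = profile.bins.n_bins
    boundaries = {0, n}
    boundaries.update(int(p) for p in cps.positions)
    gap_runs = _masked_runs(profile.mask, hard_gap_bins)
    for s, e in gap_runs:
        boundaries.add(s)
        boundaries.add(e)
    cuts = sorted(b for b in boundaries if 0 <= b <= n)

    gap_set = gap_runs
    segments: list[Segment] = []
    for i, (s, e) in enumerate(zip(cuts[:-1], cuts[1:])):
        if e <= s:
            continue
        seg_vals = v[s:e]
        obs = np.isfinite(seg_vals)
        n_obs = int(obs.sum())
        excluded = n_obs == 0 or any(gs <= s and e <= ge for gs, ge in gap_set)
        mean_rd = float(np.nanmean(seg_vals)) if n_obs else np.nan
        mean_cn = (float(2.0 * mean_rd / ref.rd_2n)
                   if (ref is not None and n_obs) else np.nan)
        segments.append(Segment(profile.chromosome, s, e, mean_rd, mean_cn,
                                n_obs, excluded=excluded, segment_id=i))
    return segments
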