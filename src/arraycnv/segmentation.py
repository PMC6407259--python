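"""Least-squares changepoint segmentation of per-sample log2-ratio profiles.

The segmenter finds, for a given per-segment penalty λ ≥ 0, the partition of
a probe profile minimizing

    Σ_segments Σ_probes (x − segment mean)²  +  λ · (number of segments)

by exact dynamic programming (Bellman recursion over candidate last
changepoints, O(n²) per profile, O(n·band) when a maximum segment length is
set).  This is the classical penalized least-squares formulation of the
"minimize squared error around segment means" objective used by aCGH
segment callers.  Penalty selection, when not fixed by the caller, uses
the changepoint BIC n·ln(SSE/n) + 2k·ln(n) over the candidate grid.

Baseline handling: profiles are recentred so the diploid state sits at 0 —
per-sample autosomal median subtraction, plus a chrX median shift for male
samples hybridized against a female reference (whose chrX baseline is −1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SignalMatrix

__all__ = [
    "Segment",
    "SegmentationConfig",
    "normalize_profile",
    "shift_chrx_baseline",
    "segment_profile",
    "segmentation_cost",
    "select_penalty",
    "segment_matrix",
    "DEFAULT_PENALTY_GRID",
]

#: candidate per-segment penalties for BIC selection (squared-log2 units)
DEFAULT_PENALTY_GRID = (0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2)

_SSE_FLOOR = 1e-12  # keeps ln(SSE/n) finite on noiseless profiles


@dataclass(frozen=True)
class Segment:
    """A maximal constant-mean run of probes (indices 0-based inclusive
    within the chromosome's probe order; bp coordinates are the member
    probes' positions)."""

    chrom: str
    first_probe_index: int
    last_probe_index: int
    start_bp: int
    end_bp: int
    mean_log2: float
    n_probes: int

    def __post_init__(self):
        if self.first_probe_index > self.last_probe_index:
            raise ValueError("first_probe_index must be <= last_probe_index")
        if self.n_probes != self.last_probe_index - self.first_probe_index + 1:
            raise ValueError("n_probes inconsistent with probe index range")


@dataclass(frozen=True)
class SegmentationConfig:
    """Penalty and structural constraints for the DP.

    penalty=None means "select from ``penalty_grid`` by BIC per profile".
    ``max_segment_probes`` bands the DP (an approximation for very long
    profiles); ``max_segments`` caps the segment count exactly.
    """

    penalty: float | None = None
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID
    max_segments: int | None = None
    min_probes_per_segment: int = 1
    max_segment_probes: int | None = None

    def __post_init__(self):
        if self.penalty is not None and self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if self.min_probes_per_segment < 1:
            raise ValueError("min_probes_per_segment must be >= 1")


# ---------------------------------------------------------------------------
# baseline normalization
# ---------------------------------------------------------------------------

def normalize_profile(values: np.ndarray,
                      baseline_mask: np.ndarray | None = None) -> np.ndarray:
    """Subtract the (autosomal) median so the diploid baseline sits at 0.

    ``baseline_mask`` restricts the median to a subset of probes (typically
    the autosomes); the subtraction applies to the whole profile.
    """
    values = np.asarray(values, dtype=float)
    ref = values if baseline_mask is None else values[np.asarray(baseline_mask)]
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise ValueError("profile has no finite values to normalize against")
    return values - np.median(ref)


def shift_chrx_baseline(values: np.ndarray, sample_sex: str) -> np.ndarray:
    """Recentre a male sample's chrX values at its chrX median.

    Against a female (two-X) reference a male's hemizygous chrX baseline is
    −1; subtracting the chrX median moves that single-copy state to 0 so
    true chrX CNVs deviate from 0 like autosomal ones.  Female profiles are
    returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    if sample_sex == "female":
        return values.copy()
    if sample_sex != "male":
        raise ValueError(f"unknown sample sex {sample_sex!r}")
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("chrX profile has no finite values")
    return values - np.median(finite)


# ---------------------------------------------------------------------------
# dynamic programming core
# ---------------------------------------------------------------------------

def _dp_unbounded(x: np.ndarray, penalty: float, min_len: int,
                  max_len: int | None) -> list[int]:
    """Optimal changepoints for penalized least squares; returns the sorted
    list of segment end indices (inclusive)."""
    n = len(x)
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))
    best = np.full(n + 1, np.inf)
    best[0] = 0.0
    prev = np.zeros(n + 1, dtype=np.int64)
    for i in range(1, n + 1):
        lo = 0 if max_len is None else max(0, i - max_len)
        hi = i - min_len + 1
        if hi <= lo:
            # shorter than min_len: fall back to one short segment from lo
            hi = lo + 1
        j = np.arange(lo, hi)
        ln = i - j
        sse = (s2[i] - s2[j]) - (s1[i] - s1[j]) ** 2 / ln
        cand = best[j] + np.maximum(sse, 0.0) + penalty
        k = int(np.argmin(cand))  # first minimum -> deterministic
        best[i] = cand[k]
        prev[i] = j[k]
    ends = []
    i = n
    while i > 0:
        ends.append(i - 1)
        i = int(prev[i])
    return ends[::-1]


def _dp_capped(x: np.ndarray, penalty: float, min_len: int,
               max_segments: int) -> list[int]:
    """DP with an exact cap on the number of segments."""
    n = len(x)
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(j, i):  # probes j..i-1
        ln = i - j
        return max((s2[i] - s2[j]) - (s1[i] - s1[j]) ** 2 / ln, 0.0)

    kmax = min(max_segments, n)
    best = np.full((kmax + 1, n + 1), np.inf)
    best[0, 0] = 0.0
    prev = np.zeros((kmax + 1, n + 1), dtype=np.int64)
    for k in range(1, kmax + 1):
        for i in range(k, n + 1):
            lo, hi = k - 1, i - min_len + 1
            if hi <= lo:
                hi = lo + 1
            js = np.arange(lo, hi)
            ln = i - js
            ss = (s2[i] - s2[js]) - (s1[i] - s1[js]) ** 2 / ln
            cand = best[k - 1, js] + np.maximum(ss, 0.0) + penalty
            m = int(np.argmin(cand))
            best[k, i] = cand[m]
            prev[k, i] = js[m]
    k = int(np.argmin(best[1:, n])) + 1
    ends = []
    i = n
    while k > 0:
        ends.append(i - 1)
        i = int(prev[k, i])
        k -= 1
    return ends[::-1]


def segment_profile(values: np.ndarray, positions: np.ndarray,
                    config: SegmentationConfig | None = None,
                    chrom: str = ".") -> list[Segment]:
    """Optimal penalized least-squares segmentation of one profile.

    Missing (NaN) probes are dropped from the fit but retained in the index
    bookkeeping: the returned segments tile the full probe index range, a
    missing probe being absorbed into the span of the following segment
    (trailing missing probes into the last segment).

    Returns the exact optimum for the configured penalty; deterministic
    (ties broken toward the longer last segment).
    """
    config = config or SegmentationConfig()
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions)
    if values.size == 0:
        raise ValueError("empty profile")
    if values.shape != positions.shape:
        raise ValueError("values and positions must have the same length")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")

    finite_idx = np.flatnonzero(np.isfinite(values))
    if finite_idx.size == 0:
        raise ValueError("profile has no finite values")
    x = values[finite_idx]

    penalty = config.penalty
    if penalty is None:
        penalty = select_penalty(x, config.penalty_grid, config=config)

    if config.max_segments is not None:
        ends_f = _dp_capped(x, penalty, config.min_probes_per_segment,
                            config.max_segments)
    else:
        ends_f = _dp_unbounded(x, penalty, config.min_probes_per_segment,
                               config.max_segment_probes)

    n = len(values)
    segments = []
    start_f = 0
    prev_end = -1
    for si, end_f in enumerate(ends_f):
        first = prev_end + 1
        last = int(finite_idx[end_f]) if si < len(ends_f) - 1 else n - 1
        mean = float(np.mean(x[start_f:end_f + 1]))
        segments.append(Segment(
            chrom=chrom,
            first_probe_index=first,
            last_probe_index=last,
            start_bp=int(positions[first]),
            end_bp=int(positions[last]),
            mean_log2=mean,
            n_probes=last - first + 1,
        ))
        prev_end = last
        start_f = end_f + 1
    return segments


def segmentation_cost(values: np.ndarray, segments: Sequence[Segment],
                      penalty: float) -> float:
    """Penalized cost of a segmentation: Σ SSE + penalty·k (finite probes only)."""
    values = np.asarray(values, dtype=float)
    total = 0.0
    for seg in segments:
        xs = values[seg.first_probe_index:seg.last_probe_index + 1]
        xs = xs[np.isfinite(xs)]
        if xs.size:
            total += float(np.sum((xs - np.mean(xs)) ** 2))
    return total + penalty * len(segments)


def select_penalty(values: np.ndarray,
                   candidates: Sequence[float] = DEFAULT_PENALTY_GRID,
                   config: SegmentationConfig | None = None) -> float:
    """Choose the candidate penalty minimizing n·ln(SSE/n) + 2k·ln(n).

    This is the classical changepoint BIC with two parameters per segment
    (its mean and its boundary); a single-parameter count systematically
    oversegments pure-noise profiles at this noise scale.  Ties (to 9
    decimals) break toward fewer segments, then toward the larger penalty;
    deterministic.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate penalty")
    values = np.asarray(values, dtype=float)
    x = values[np.isfinite(values)]
    n = len(x)
    if n == 0:
        raise ValueError("profile has no finite values")
    base = config or SegmentationConfig()
    best_key, best_pen = None, None
    for pen in candidates:
        cfg = SegmentationConfig(
            penalty=float(pen),
            max_segments=base.max_segments,
            min_probes_per_segment=base.min_probes_per_segment,
            max_segment_probes=base.max_segment_probes,
        )
        segs = segment_profile(x, np.arange(1, n + 1), cfg)
        k = len(segs)
        sse = segmentation_cost(x, segs, 0.0)
        bic = n * np.log(max(sse, _SSE_FLOOR * n) / n) + 2 * k * np.log(max(n, 2))
        key = (round(bic, 9), k, -pen)
        if best_key is None or key < best_key:
            best_key, best_pen = key, float(pen)
    return best_pen


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def segment_matrix(
    sm: SignalMatrix,
    config: SegmentationConfig | None = None,
    *,
    sex_chromosome: str | None = None,
    sample_sex: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Normalize and segment every sample × chromosome profile.

    Per sample: subtract the autosomal median genome-wide, then (for male
    samples) recentre chrX at its own median; segment each chromosome
    independently.  Returns a tidy table (sample, chrom, start_bp, end_bp,
    first_probe_index, last_probe_index, n_probes, mean_log2).
    """
    config = config or SegmentationConfig()
    chrom_arr = sm.probes["chrom"].to_numpy(dtype=object)
    autosomal = np.ones(len(chrom_arr), dtype=bool)
    if sex_chromosome is not None:
        autosomal = chrom_arr != sex_chromosome
    rows = []
    for j, sample in enumerate(sm.samples):
        col = normalize_profile(sm.values[:, j], baseline_mask=autosomal)
        if sex_chromosome is not None:
            sex = (sample_sex or {}).get(sample, "female")
            on_x = ~autosomal
            if on_x.any():
                col = col.copy()
                col[on_x] = shift_chrx_baseline(col[on_x], sex)
        for chrom in sm.chromosomes:
            idx = sm.chrom_index(chrom)
            segs = segment_profile(
                col[idx], sm.probes["pos"].to_numpy()[idx], config, chrom=chrom
            )
            for s in segs:
                rows.append((sample, chrom, s.start_bp, s.end_bp,
                             s.first_probe_index, s.last_probe_index,
                             s.n_probes, s.mean_log2))
    return pd.DataFrame(rows, columns=[
        "sample", "chrom", "start_bp", "end_bp", "first_probe_index",
        "last_probe_index", "n_probes", "mean_log2",
    ])
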