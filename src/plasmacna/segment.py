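"""Circular binary segmentation (CBS) of per-chromosome log-ratio profiles.

The core statistic follows Olshen & Venkatraman: for an arc (i, j] of the
(circularly closed) profile, compare the bins inside the arc against all
bins outside with a pooled-variance two-sample t-like statistic

    T(i, j) = |mean_in - mean_out| / (s * sqrt(1/n_in + 1/n_out)).

Internally the scan maximizes the monotone surrogate

    u(i, j) = (n_in * n_out / n) * (mean_in - mean_out)^2,

the between-group sum of squares, because T^2 = (n-2) u / (C - u) with C
the (permutation-invariant) total centered sum of squares — so the arc
maximizing u maximizes T, and permutation exceedance can be decided in
u-space with a three-flop inner loop.

The maximizing arc is tested by permutation (values shuffled within the
current stretch, with sequential early stopping once significance at level
alpha is ruled out); a significant arc splits the stretch at its boundaries
and the pieces are segmented recursively.  Adjacent segments whose means
differ by less than ``merge_tol`` are merged afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .genome import BinGrid

__all__ = [
    "CbsParams",
    "Segment",
    "cbs_max_statistic",
    "cbs_segment",
    "segments_to_bp",
    "segment_profile",
]


@dataclass(frozen=True)
class CbsParams:
    """CBS tuning knobs (alpha/permutations/width follow common practice)."""

    alpha: float = 0.01
    n_permutations: int = 1000
    min_width: int = 3
    merge_tol: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


@dataclass
class Segment:
    """A constant-level stretch of bins on one chromosome.

    ``start_bin``/``end_bin`` are half-open grid bin indices; bp coordinates
    and Mb size are filled by :func:`segments_to_bp`.  ``n_bins`` counts the
    unmasked bins only, while the bp span includes interior masked gaps.
    """

    chrom: str
    start_bin: int
    end_bin: int
    n_bins: int
    mean_value: float
    start_bp: int = -1
    end_bp: int = -1
    size_mb: float = float("nan")


@njit(cache=True)
def _max_arc_u(x, min_width):
    """Best arc by between-group sum of squares u; returns (i, j, u, C).

    Scans all arcs (i, j] with width in [min_width, n - min_width]; ties in
    u are broken by smallest i, then smallest j.  C is the total centered
    sum of squares of x.
    """
    n = x.shape[0]
    S = np.empty(n + 1)
    S[0] = 0.0
    q = 0.0
    for t in range(n):
        S[t + 1] = S[t] + x[t]
        q += x[t] * x[t]
    tot = S[n]
    C = q - tot * tot / n
    best_u = -1.0
    best_i = 0
    best_j = min_width if min_width < n else n
    for m in range(min_width, n - min_width + 1):
        out = n - m
        denom = float(n) * m * out
        for i in range(0, n - m + 1):
            a = n * (S[i + m] - S[i]) - m * tot
            u = a * a / denom
            if u > best_u * (1.0 + 1e-12) + 1e-15:
                best_u = u
                best_i = i
                best_j = i + m
            elif u > best_u * (1.0 - 1e-12) - 1e-15 and (
                i < best_i or (i == best_i and i + m < best_j)
            ):
                # tie: prefer smallest i, then smallest j
                best_i = i
                best_j = i + m
    if best_u < 0.0:
        best_u = 0.0
    return best_i, best_j, best_u, C


@njit(cache=True)
def _perm_exceed_count(x, u_obs, n_perm, max_exceed, min_width, seed):
    """Permutations whose max arc u reaches u_obs; early-stops two ways.

    Stops across permutations once the exceedance count passes
    ``max_exceed`` (split can no longer be significant) and within a
    permutation as soon as any arc reaches u_obs.  Returns (count, n_done).
    """
    np.random.seed(seed)
    n = x.shape[0]
    y = x.copy()
    S = np.empty(n + 1)
    S[0] = 0.0
    thresh = u_obs * (1.0 - 1e-9)
    count = 0
    done = 0
    for _p in range(n_perm):
        np.random.shuffle(y)
        for t in range(n):
            S[t + 1] = S[t] + y[t]
        tot = S[n]
        exceeded = False
        for m in range(min_width, n - min_width + 1):
            out = n - m
            lim = np.sqrt(thresh * n * m * out)
            for i in range(0, n - m + 1):
                a = n * (S[i + m] - S[i]) - m * tot
                if a < 0.0:
                    a = -a
                if a >= lim:
                    exceeded = True
                    break
            if exceeded:
                break
        done += 1
        if exceeded:
            count += 1
            if count > max_exceed:
                break
    return count, done


def _u_to_t(u: float, C: float, n: int) -> float:
    if u <= 0.0:
        return 0.0
    resid = C - u
    if resid <= max(C, 1.0) * 1e-12:
        return float("inf")
    if n <= 2:
        return float("inf")
    return float(np.sqrt((n - 2) * u / resid))


def cbs_max_statistic(values: np.ndarray, min_width: int = 3) -> tuple[int, int, float]:
    """Maximizing arc (i, j] and its t-like statistic for one stretch.

    A constant vector returns (0, min_width, 0.0); a zero-variance split
    (noiseless step) returns T = inf.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.shape[0] < 2 * min_width:
        raise ValueError(f"need at least {2 * min_width} values")
    if np.any(~np.isfinite(x)):
        raise ValueError("remove missing values before segmentation")
    i, j, u, C = _max_arc_u(x, min_width)
    if C <= 1e-300:
        return 0, min(min_width, x.shape[0]), 0.0
    return int(i), int(j), _u_to_t(u, C, x.shape[0])


def _split_stretch(x: np.ndarray, lo: int, hi: int, params: CbsParams,
                   boundaries: list[int]) -> None:
    n = hi - lo
    if n < 2 * params.min_width:
        return
    seg = x[lo:hi]
    i, j, u_obs, C = _max_arc_u(seg, params.min_width)
    if u_obs <= 0 or C <= 1e-300:
        return
    max_exceed = int(np.floor(params.alpha * params.n_permutations))
    count, _done = _perm_exceed_count(
        seg, u_obs, params.n_permutations, max_exceed, params.min_width,
        (params.seed * 2_654_435_761 + lo * 1_000_003 + hi) % (2**31 - 1),
    )
    if count > max_exceed:
        return  # p > alpha
    cuts = [c for c in (i, j) if 0 < c < n]
    if not cuts:
        return
    boundaries.extend(lo + c for c in cuts)
    pieces = sorted({0, *cuts, n})
    for a, b in zip(pieces, pieces[1:]):
        _split_stretch(x, lo + a, lo + b, params, boundaries)


def cbs_segment(values: np.ndarray, params: CbsParams = CbsParams()) -> list[tuple[int, int, float]]:
    """Segment one chromosome's (gap-free) value vector.

    Returns (start, end, mean) triples in vector-index space covering every
    index exactly once.  Deterministic given ``params.seed``; stretches
    shorter than 2*min_width are returned as a single segment.
    """
    x = np.asarray(values, dtype=np.float64)
    n = x.shape[0]
    if n == 0:
        return []
    boundaries: list[int] = []
    if n >= 2 * params.min_width:
        _split_stretch(x, 0, n, params, boundaries)
    cuts = sorted({0, *boundaries, n})
    segs = [(a, b, float(x[a:b].mean())) for a, b in zip(cuts, cuts[1:])]
    merged: list[tuple[int, int, float]] = []
    for seg in segs:
        if merged and abs(merged[-1][2] - seg[2]) < params.merge_tol:
            a, _, _ = merged[-1]
            merged[-1] = (a, seg[1], float(x[a:seg[1]].mean()))
        else:
            merged.append(seg)
    return merged


def segment_profile(
    values: np.ndarray,
    mask: np.ndarray,
    grid: BinGrid,
    params: CbsParams = CbsParams(),
) -> list[Segment]:
    """Run CBS per chromosome on masked log-ratio values over a grid.

    Masked bins are dropped before segmentation; segment bin ranges are
    re-inflated so spans include interior masked gaps.
    """
    out: list[Segment] = []
    for chrom in grid.genome.chrom_names:
        idx = grid.chrom_indices(chrom)
        if idx.size == 0:
            continue
        use = idx[mask[idx]]
        if use.size == 0:
            continue
        for a, b, mean in cbs_segment(values[use], params):
            bins = use[a:b]
            out.append(Segment(
                chrom=chrom,
                start_bin=int(bins[0]),
                end_bin=int(bins[-1]) + 1,
                n_bins=int(b - a),
                mean_value=mean,
            ))
    return segments_to_bp(out, grid)


def segments_to_bp(segments: list[Segment], grid: BinGrid) -> list[Segment]:
    """Attach bp coordinates and Mb sizes (spans include masked gaps)."""
    for seg in segments:
        seg.start_bp = int(grid.start[seg.start_bin])
        seg.end_bp = int(grid.end[seg.end_bin - 1])
        seg.size_mb = (seg.end_bp - seg.start_bp) / 1e6
    return segments
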