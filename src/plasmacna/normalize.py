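"""Bin-level normalization: exclusion, LOESS GC adjustment, PCA smoothing.

The pipeline order is

1. :func:`exclusion_filter` — drop bins with high cross-panel variance, low
   mappability or high repeat content;
2. :func:`loess_gc_adjust` — per-sample locally-weighted quadratic fit of
   count vs GC; counts are rescaled so the fitted GC curve is flattened and
   the sample's median count preserved;
3. :func:`fit_reference_panel` — panel medians/MADs of autosomal bin
   fractions and the top-K principal components of the panel's log-ratio
   matrix;
4. :func:`pca_smooth` — subtract from a sample's log2(fraction/median)
   profile its projection onto the panel component subspace, removing
   higher-order population artifacts while leaving signal orthogonal to
   that subspace (e.g. tumour copy-number deviations) intact.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import BinGrid, CountProfile
from .io import check_same_grid

__all__ = [
    "ExclusionThresholds",
    "NormalizedProfile",
    "ReferencePanel",
    "exclusion_filter",
    "loess_gc_adjust",
    "fit_reference_panel",
    "pca_smooth",
    "normalize_sample",
]

_COUNT_FLOOR = 0.5  # avoids log(0) for empty bins at very low depth


@dataclass(frozen=True)
class ExclusionThresholds:
    """Bin exclusion rules applied to the reference panel.

    ``vmr_quantile``: bins whose cross-panel variance-to-mean ratio exceeds
    this quantile of all panel bins are dropped (captures systematically
    noisy regions); ``min_mappability`` and ``max_repeat_fraction`` act on
    the grid annotations.
    """

    vmr_quantile: float = 0.99
    min_mappability: float = 0.75
    max_repeat_fraction: float = 0.5


@dataclass
class NormalizedProfile:
    """One sample's GC-adjusted counts and (after smoothing) log2 ratios.

    ``values`` holds per-bin log2(fraction / panel median) after PCA
    smoothing, NaN on masked bins.  ``adjusted_counts`` holds normalized
    counts — GC-flattened after :func:`loess_gc_adjust`, additionally
    artifact-corrected after :func:`pca_smooth` — retained because segment
    fractions are computed on the count scale, not the log scale.
    """

    sample_id: str
    adjusted_counts: np.ndarray
    mask: np.ndarray                      # True = usable
    values: np.ndarray | None = None
    batch_id: str | None = None

    def usable_values(self) -> np.ndarray:
        if self.values is None:
            raise ValueError("profile not yet smoothed")
        return self.values[self.mask]


def exclusion_filter(
    panel: list[CountProfile],
    grid: BinGrid,
    thresholds: ExclusionThresholds = ExclusionThresholds(),
) -> tuple[BinGrid, dict[str, int]]:
    """Flag unusable bins from panel statistics and grid annotations.

    Returns a grid copy with updated ``excluded`` flags and the number of
    bins newly excluded under each criterion (a bin may trip several).
    """
    if not panel:
        raise ValueError("panel is empty")
    mat = np.stack([p.counts for p in panel]).astype(float)
    mean = mat.mean(axis=0)
    var = mat.var(axis=0, ddof=1) if len(panel) > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        vmr = np.where(mean > 0, var / mean, 0.0)
    cut = np.quantile(vmr, thresholds.vmr_quantile)
    high_var = vmr > cut
    low_map = grid.mappability < thresholds.min_mappability
    repeats = grid.repeat_fraction > thresholds.max_repeat_fraction
    out = grid.copy()
    out.excluded = grid.excluded | high_var | low_map | repeats
    if out.excluded.all():
        raise ValueError("exclusion filter removed every bin")
    counts = {
        "high_variance": int(high_var.sum()),
        "low_mappability": int(low_map.sum()),
        "high_repeat": int(repeats.sum()),
    }
    return out, counts


def _demean_orthonormalize(components: np.ndarray) -> np.ndarray:
    """Make loading vectors orthogonal to the constant direction.

    A global offset of a log-ratio profile carries no copy-number
    information, so smoothing must never project onto it; each loading has
    its mean removed and the set is re-orthonormalized.
    """
    v = components - components.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(v.T)
    return q.T[: components.shape[0]]


def _loess_quadratic(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, span: float) -> np.ndarray:
    """Locally weighted quadratic regression with tricube weights.

    Fits at each evaluation point using the nearest ``span`` fraction of the
    data. Evaluation points outside [min(x), max(x)] are clamped.
    """
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    n = len(xs)
    k = max(int(np.ceil(span * n)), 8)
    xe = np.clip(x_eval, xs[0], xs[-1])
    out = np.empty_like(xe, dtype=float)
    for i, x0 in enumerate(xe):
        lo = np.searchsorted(xs, x0)
        a, b = max(0, lo - k // 2), min(n, lo + k // 2)
        if b - a < k:  # window hit an edge; extend inward
            a, b = (0, min(n, k)) if a == 0 else (max(0, n - k), n)
        xi, yi = xs[a:b], ys[a:b]
        h = max(np.max(np.abs(xi - x0)), 1e-12)
        w = (1 - np.clip(np.abs(xi - x0) / h, 0, 1) ** 3) ** 3
        X = np.column_stack([np.ones_like(xi), xi - x0, (xi - x0) ** 2])
        wx = X * w[:, None]
        try:
            beta = np.linalg.solve(wx.T @ X, wx.T @ yi)
        except np.linalg.LinAlgError:
            beta = np.array([np.average(yi, weights=w), 0.0, 0.0])
        out[i] = beta[0]
    return out


def loess_gc_adjust(
    profile: CountProfile,
    grid: BinGrid,
    span: float = 0.3,
    n_grid: int = 60,
) -> NormalizedProfile:
    """Sample-specific LOESS flattening of the count-vs-GC relationship.

    The curve is fitted on unmasked autosomal bins (evaluated on an ``n_grid``
    point GC lattice and interpolated, which is numerically identical to a
    dense fit for these smooth curves but far cheaper).  Each bin's count is
    multiplied by (median fitted value / fitted value at its GC), so the
    sample's median level is preserved while the GC trend is removed.
    """
    mask = grid.usable.copy()
    fit_mask = mask & grid.autosomal
    if fit_mask.sum() < 100:
        raise ValueError("need >= 100 unmasked autosomal bins to fit the GC curve")
    gc_fit = grid.gc[fit_mask]
    y_fit = profile.counts[fit_mask].astype(float)
    gc_span = gc_fit.max() - gc_fit.min()
    adjusted = profile.counts.astype(float).copy()
    if gc_span <= 0.05:
        if gc_span == 0:
            warnings.warn("degenerate GC annotation (all equal); identity adjustment")
            return NormalizedProfile(profile.sample_id, adjusted, mask, batch_id=profile.batch_id)
        raise ValueError("GC range too narrow (<= 0.05) for a GC fit")
    # evaluate at GC quantiles: every lattice point sits in a data-dense
    # region, so the local quadratic never extrapolates into a GC gap
    lattice = np.unique(np.quantile(gc_fit, np.linspace(0, 1, n_grid)))
    fitted_lattice = _loess_quadratic(gc_fit, y_fit, lattice, span)
    level = np.median(y_fit)
    # a fitted GC bias outside [0.1x, 10x] the sample level is a fit artifact
    fitted_lattice = np.clip(fitted_lattice, 0.1 * level, 10 * level)
    fitted = np.interp(np.clip(grid.gc, lattice[0], lattice[-1]), lattice, fitted_lattice)
    ref = np.median(fitted[fit_mask])
    adjusted = adjusted * (ref / fitted)
    return NormalizedProfile(profile.sample_id, adjusted, mask, batch_id=profile.batch_id)


@dataclass
class ReferencePanel:
    """Panel-derived per-bin reference statistics and artifact subspace.

    ``fractions`` is the (panel_size, n_bins) matrix of fully normalized
    (GC-adjusted, PCA-smoothed, autosomal-renormalized) bin fractions; any
    segment's reference fraction distribution derives from it.  ``median``
    holds the pre-smoothing per-bin medians used for log-ratio centering,
    ``mad`` the post-smoothing per-bin MADs.  ``components`` are orthonormal
    loadings over unmasked bins of the top-K principal components of the
    panel's log2(fraction/median) matrix.
    """

    grid: BinGrid
    grid_hash: str
    mask: np.ndarray
    fractions: np.ndarray                 # (panel_size, n_bins), PCA-smoothed
    median: np.ndarray
    mad: np.ndarray
    components: np.ndarray                # (K, n_unmasked)
    k: int
    panel_size: int
    batch_median: dict[str, np.ndarray] = field(default_factory=dict)
    fractions_raw: np.ndarray | None = None

    @property
    def autosomal_usable(self) -> np.ndarray:
        return self.mask & self.grid.autosomal

    def save(self, path: str) -> None:
        """Serialize the panel to a single .npz archive.

        Layout: grid_hash, mask, fractions, median, mad, components, k,
        panel_size, plus batch medians under ``batch_median_<id>`` keys.
        """
        arrays = {
            "grid_hash": np.array(self.grid_hash),
            "mask": self.mask,
            "fractions": self.fractions,
            "median": self.median,
            "mad": self.mad,
            "components": self.components,
            "k": np.array(self.k),
            "panel_size": np.array(self.panel_size),
        }
        for batch, med in self.batch_median.items():
            arrays[f"batch_median_{batch}"] = med
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str, grid: BinGrid) -> "ReferencePanel":
        """Load a panel archive; refuses a grid whose hash mismatches."""
        with np.load(path, allow_pickle=False) as data:
            grid_hash = str(data["grid_hash"])
            if grid_hash != grid.grid_hash():
                raise ValueError("panel archive grid hash does not match the given grid")
            batch_median = {
                key[len("batch_median_"):]: data[key]
                for key in data.files if key.startswith("batch_median_")
            }
            return cls(
                grid=grid,
                grid_hash=grid_hash,
                mask=data["mask"],
                fractions=data["fractions"],
                median=data["median"],
                mad=data["mad"],
                components=data["components"],
                k=int(data["k"]),
                panel_size=int(data["panel_size"]),
                batch_median=batch_median,
            )

    def segment_reference(self, bin_indices: np.ndarray) -> tuple[float, float]:
        """Median and MAD across panel samples of a segment's fraction.

        The segment is the exact set of (unmasked) bins discovered by CBS,
        evaluated in every panel sample; the MAD is the panel-wide "static"
        scale used by every z-statistic.
        """
        idx = bin_indices[self.mask[bin_indices]]
        frac = self.fractions[:, idx].sum(axis=1)
        med = float(np.median(frac))
        mad = float(np.median(np.abs(frac - med)))
        return med, mad


def _bin_fractions(adjusted: np.ndarray, mask: np.ndarray, autosomal: np.ndarray) -> np.ndarray:
    counts = np.clip(adjusted, _COUNT_FLOOR, None)
    total = counts[mask & autosomal].sum()
    if total <= 0:
        raise ValueError("zero autosomal total")
    frac = np.where(mask, counts / total, np.nan)
    return frac


def fit_reference_panel(
    panel: list[NormalizedProfile],
    grid: BinGrid,
    k: int = 10,
    min_batch: int = 8,
) -> ReferencePanel:
    """Build the population reference from GC-adjusted panel profiles.

    K is capped at panel_size - 2; per-batch medians are stored for batches
    with at least ``min_batch`` members (flow-cell-specific centering).
    """
    if not panel:
        raise ValueError("panel is empty")
    if k >= len(panel):
        raise ValueError(f"K={k} must be < panel size {len(panel)}")
    k = min(k, len(panel) - 2)
    mask = grid.usable & np.array([m for m in panel[0].mask])
    for p in panel:
        mask &= p.mask
    autosomal = grid.autosomal
    fracs = np.stack([_bin_fractions(p.adjusted_counts, mask, autosomal) for p in panel])
    median = np.full(grid.n_bins, np.nan)
    mad = np.full(grid.n_bins, np.nan)
    median[mask] = np.median(fracs[:, mask], axis=0)
    mad[mask] = np.median(np.abs(fracs[:, mask] - median[mask]), axis=0)
    if np.all(mad[mask] == 0):
        warnings.warn("degenerate panel (identical samples); PCA smoothing disabled")
        k = 0
    components = np.zeros((0, int(mask.sum())))
    logratio = np.log2(fracs[:, mask] / np.clip(median[mask], 1e-300, None))
    resid = logratio
    if k > 0:
        from sklearn.decomposition import PCA

        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(logratio)
        components = _demean_orthonormalize(pca.components_)
        # Panel members are smoothed leave-one-out: components refitted
        # without the sample being smoothed, so the reference fraction
        # distribution reflects out-of-sample residual variance (in-sample
        # projection would overfit the panel's own noise and understate the
        # MAD every z-statistic divides by).
        resid = np.empty_like(logratio)
        for s in range(logratio.shape[0]):
            rest = np.delete(logratio, s, axis=0)
            loo = PCA(n_components=min(k, rest.shape[0] - 1), svd_solver="full")
            loo.fit(rest)
            v = _demean_orthonormalize(loo.components_)
            resid[s] = logratio[s] - v.T @ (v @ logratio[s])
    # artifact-free panel fractions: residual log-ratios mapped back to the
    # fraction scale and renormalized over unmasked autosomal bins; every
    # reference segment-fraction distribution derives from these
    smooth = np.zeros_like(fracs)
    smooth[:, mask] = median[mask] * np.exp2(resid)
    auto_cols = (mask & autosomal)
    smooth /= smooth[:, auto_cols].sum(axis=1, keepdims=True)
    mad[mask] = np.median(
        np.abs(smooth[:, mask] - np.median(smooth[:, mask], axis=0)), axis=0
    )
    batch_median: dict[str, np.ndarray] = {}
    batches: dict[str, list[int]] = {}
    for i, p in enumerate(panel):
        if p.batch_id is not None:
            batches.setdefault(p.batch_id, []).append(i)
    for batch, idx in batches.items():
        if len(idx) >= min_batch:
            batch_median[batch] = np.nanmedian(fracs[idx], axis=0)
    return ReferencePanel(
        grid=grid,
        grid_hash=grid.grid_hash(),
        mask=mask,
        fractions=smooth,
        median=median,
        mad=mad,
        components=components,
        k=k,
        panel_size=len(panel),
        batch_median=batch_median,
        fractions_raw=fracs,
    )


def pca_smooth(profile: NormalizedProfile, panel: ReferencePanel) -> NormalizedProfile:
    """Remove the panel artifact subspace from a sample's log-ratio profile.

    The profile's log2(fraction / panel median) vector over unmasked bins is
    projected onto the panel's top-K components and the projection
    subtracted; the residual is the smoothed value used for segmentation.
    The residuals are also mapped back to the count scale (median * 2**value,
    renormalized to the sample's autosomal total) so that segment fractions
    and the bootstrap operate on fully normalized counts.
    """
    if len(profile.adjusted_counts) != panel.grid.n_bins:
        raise ValueError("profile grid does not match panel grid")
    mask = panel.mask
    median = panel.median
    if profile.batch_id is not None and profile.batch_id in panel.batch_median:
        median = panel.batch_median[profile.batch_id]
    auto = panel.grid.autosomal
    frac = _bin_fractions(profile.adjusted_counts, mask, auto)
    r = np.log2(frac[mask] / np.clip(median[mask], 1e-300, None))
    # anchor the log-ratio baseline at its median: a global multiplicative
    # offset carries no information once fractions are renormalized, and the
    # median is robust to even large altered shares
    r = r - np.median(r)
    if panel.k > 0:
        proj = panel.components.T @ (panel.components @ r)
        r = r - proj
        r = r - np.median(r)
    values = np.full(panel.grid.n_bins, np.nan)
    values[mask] = r
    auto_total = float(np.clip(profile.adjusted_counts, _COUNT_FLOOR, None)[mask & auto].sum())
    smooth_frac = np.zeros(panel.grid.n_bins)
    smooth_frac[mask] = np.clip(median[mask], 1e-300, None) * np.exp2(r)
    smooth_frac /= smooth_frac[mask & auto].sum()
    smoothed_counts = smooth_frac * auto_total
    return NormalizedProfile(
        sample_id=profile.sample_id,
        adjusted_counts=smoothed_counts,
        mask=mask.copy(),
        values=values,
        batch_id=profile.batch_id,
    )


def normalize_sample(
    profile: CountProfile,
    grid: BinGrid,
    panel: ReferencePanel,
    span: float = 0.3,
) -> NormalizedProfile:
    """LOESS GC adjustment followed by PCA smoothing against ``panel``."""
    if panel.grid_hash != grid.grid_hash():
        raise ValueError("grid hash mismatch between sample grid and panel")
    adj = loess_gc_adjust(profile, grid, span=span)
    return pca_smooth(adj, panel)
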