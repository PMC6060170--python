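"""Regression estimator of tumour DNA fraction from regional read depth.

A multivariate (ridge) linear model maps per-bin read-depth fractions to the
tumour fraction of the sample, in the style of count-based cell-free DNA
fraction estimators.  Bins on chromosomes 13, 18, 21, X and Y carry no
coefficient: those chromosomes host the aneuploidies the platform screens
for, so their depth must not influence the fraction estimate.  Predictors
are fractions over *included* bins only (bin count / sum of included-bin
counts), which makes the estimate exactly invariant to perturbations
confined to the excluded chromosomes.

The published estimator's trained coefficients are proprietary; this model
is trained afresh, e.g. on the synthetic panels of :mod:`plasmacna.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import BinGrid, CountProfile
from .normalize import NormalizedProfile

__all__ = ["TumorFractionModel", "train_tf_model", "estimate_tumor_fraction",
           "EXCLUDED_CHROMS", "included_bin_fractions"]

EXCLUDED_CHROMS = ("chr13", "chr18", "chr21", "chrX", "chrY")


@dataclass
class TumorFractionModel:
    """Ridge coefficients over included bins plus scaler state."""

    grid_hash: str
    included: np.ndarray          # bool over grid bins
    coef: np.ndarray              # per included bin, on standardized scale
    intercept: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    regularization: float
    training_rmse: float
    n_train: int
    seed: int

    def save(self, path: str) -> None:
        """Serialize to a .npz archive (grid hash, coefficients, scaler)."""
        np.savez_compressed(
            path,
            grid_hash=np.array(self.grid_hash),
            included=self.included,
            coef=self.coef,
            intercept=np.array(self.intercept),
            x_mean=self.x_mean,
            x_scale=self.x_scale,
            regularization=np.array(self.regularization),
            training_rmse=np.array(self.training_rmse),
            n_train=np.array(self.n_train),
            seed=np.array(self.seed),
        )

    @classmethod
    def load(cls, path: str, grid: BinGrid) -> "TumorFractionModel":
        """Load a model archive; refuses a grid whose hash mismatches."""
        with np.load(path, allow_pickle=False) as d:
            grid_hash = str(d["grid_hash"])
            if grid_hash != grid.grid_hash():
                raise ValueError("model archive grid hash does not match the given grid")
            return cls(
                grid_hash=grid_hash,
                included=d["included"],
                coef=d["coef"],
                intercept=float(d["intercept"]),
                x_mean=d["x_mean"],
                x_scale=d["x_scale"],
                regularization=float(d["regularization"]),
                training_rmse=float(d["training_rmse"]),
                n_train=int(d["n_train"]),
                seed=int(d["seed"]),
            )

    def predict_from_features(self, x: np.ndarray) -> float:
        z = (x - self.x_mean) / self.x_scale
        return float(np.clip(z @ self.coef + self.intercept, 0.0, 1.0 - 1e-9))


def included_mask(grid: BinGrid, mask: np.ndarray | None = None) -> np.ndarray:
    inc = grid.usable if mask is None else (grid.usable & mask)
    for chrom in EXCLUDED_CHROMS:
        inc = inc & (grid.chrom != chrom)
    return inc


def included_bin_fractions(counts: np.ndarray, inc: np.ndarray) -> np.ndarray:
    sel = counts[inc].astype(float)
    total = sel.sum()
    if total <= 0:
        raise ValueError("zero total count over included bins")
    return sel / total


def _features(profile, grid: BinGrid, inc: np.ndarray) -> np.ndarray:
    if isinstance(profile, CountProfile):
        counts = profile.counts
    elif isinstance(profile, NormalizedProfile):
        counts = profile.adjusted_counts
    else:
        counts = np.asarray(profile, dtype=float)
    if counts.shape[0] != grid.n_bins:
        raise ValueError("profile not aligned to model grid")
    return included_bin_fractions(counts, inc)


def train_tf_model(
    training: list[tuple[object, float]],
    grid: BinGrid,
    regularization: float = 1.0,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> TumorFractionModel:
    """Fit the ridge model on (profile, known fraction) pairs.

    Features are standardized (zero-variance features kept at scale 1 so
    their coefficient is exactly the ridge null).  With regularization 0 a
    rank-deficient design raises rather than silently pseudo-inverting.
    """
    if len(training) < 20:
        raise ValueError("need >= 20 training samples")
    y = np.array([f for _, f in training], dtype=float)
    if np.any((y < 0) | (y >= 1)):
        raise ValueError("training fractions must be in [0,1)")
    if y.max() - y.min() < 0.1 and y.max() != y.min():
        raise ValueError("training fractions must span a range >= 0.1")
    inc = included_mask(grid, mask)
    if y.max() == y.min():
        # degenerate but well-defined: intercept-only model
        x0 = np.stack([_features(p, grid, inc) for p, _ in training]).mean(axis=0)
        return TumorFractionModel(
            grid_hash=grid.grid_hash(), included=inc,
            coef=np.zeros(int(inc.sum())), intercept=float(y[0]),
            x_mean=x0, x_scale=np.ones(int(inc.sum())),
            regularization=regularization, training_rmse=0.0,
            n_train=len(training), seed=seed,
        )
    X = np.stack([_features(p, grid, inc) for p, _ in training])
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    Z = (X - x_mean) / x_scale
    if regularization == 0 and np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("design is rank-deficient; use regularization > 0")
    from sklearn.linear_model import Ridge

    model = Ridge(alpha=regularization, fit_intercept=True)
    model.fit(Z, y)
    pred = model.predict(Z)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    return TumorFractionModel(
        grid_hash=grid.grid_hash(),
        included=inc,
        coef=np.asarray(model.coef_, dtype=float),
        intercept=float(model.intercept_),
        x_mean=x_mean,
        x_scale=x_scale,
        regularization=regularization,
        training_rmse=rmse,
        n_train=len(training),
        seed=seed,
    )


def estimate_tumor_fraction(
    model: TumorFractionModel, profile, grid: BinGrid
) -> tuple[float, float]:
    """Predict a sample's tumour fraction; returns (estimate, training RMSE).

    The RMSE is reported as a crude uncertainty of the point estimate.
    """
    if model.grid_hash != grid.grid_hash():
        raise ValueError("profile grid does not match the model grid")
    x = _features(profile, grid, model.included)
    return model.predict_from_features(x), model.training_rmse
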