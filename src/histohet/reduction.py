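"""Feature selection and composite heterogeneity scores (CP1–CP3).

The per-slide heterogeneity features have incommensurable units, so
they are standardized, pruned of redundant (highly correlated)
members, and projected onto the first three principal components of
the correlation matrix.  The resulting composite scores CP1–CP3 are
oriented so that a higher score means more heterogeneity (positive
loading on a reference feature, Fisher's index by default), which
makes "high heterogeneity → poor prognosis" a testable statement
downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Standardizer",
    "PCAModel",
    "standardize",
    "select_nonredundant",
    "fit_pca",
    "orient_components",
    "upper_tercile_flag",
    "CANONICAL_FEATURE_SET",
]

# the four canonical nonredundant features of the validated surface; pass as
# PipelineConfig.feature_columns to bypass data-driven selection
CANONICAL_FEATURE_SET = (
    "haralick_correlation",
    "haralick_energy",
    "fisher_index",
    "voronoi_variance",
)


@dataclass(frozen=True)
class Standardizer:
    """Per-column mean/SD (sample SD, ddof=1) for reproducible scaling."""

    columns: tuple
    means: np.ndarray
    sds: np.ndarray

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        z = (df[list(self.columns)] - self.means) / self.sds
        return z

    def inverse_transform(self, z: pd.DataFrame) -> pd.DataFrame:
        return z[list(self.columns)] * self.sds + self.means

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(tuple(d["columns"]), np.asarray(d["means"]), np.asarray(d["sds"]))


def standardize(matrix: pd.DataFrame, columns=None) -> tuple[pd.DataFrame, Standardizer]:
    """Zero-mean, unit-sample-SD each column; returns (z, fitted scaler)."""
    cols = list(columns) if columns is not None else list(matrix.columns)
    sub = matrix[cols].astype(float)
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}")
    means = sub.mean(axis=0).to_numpy()
    sds = sub.std(axis=0, ddof=1).to_numpy()
    for c, s in zip(cols, sds):
        if not s > 0:
            raise ValueError(f"column {c!r} has zero standard deviation")
    scaler = Standardizer(tuple(cols), means, sds)
    return scaler.transform(sub), scaler


def select_nonredundant(matrix: pd.DataFrame, r_max: float = 0.8) -> list:
    """Greedy pruning of redundant features by pairwise correlation.

    While any pair of surviving features has |Pearson r| > r_max, the
    member of the worst pair with the larger mean |r| to all other
    survivors is dropped (ties: the later column goes).  Deterministic
    for a fixed column order; returns survivors in original order.
    """
    cols = list(matrix.columns)
    if len(cols) < 2:
        return cols
    corr = matrix[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    alive = list(range(len(cols)))
    while len(alive) > 1:
        sub = corr[np.ix_(alive, alive)]
        k = int(np.argmax(sub))
        i, j = sorted(divmod(k, len(alive)))
        if sub[i, j] <= r_max:
            break
        mean_i = sub[i].sum() / (len(alive) - 1)
        mean_j = sub[j].sum() / (len(alive) - 1)
        # drop the member with larger mean |r| to the others; tie → later column
        local_drop = j if mean_j >= mean_i else i
        alive.remove(alive[local_drop])
    return [cols[i] for i in sorted(alive)]


@dataclass(frozen=True)
class PCAModel:
    """Loadings and explained variance of the composite-score projection."""

    feature_names: tuple
    component_names: tuple  # ("CP1", "CP2", "CP3", ...)
    loadings: np.ndarray  # (n_features, k), orthonormal columns
    explained_variance: np.ndarray  # eigenvalues, non-increasing
    total_variance: float
    orientation_reference: str | None = None

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.total_variance

    def transform(self, z: pd.DataFrame) -> pd.DataFrame:
        scores = z[list(self.feature_names)].to_numpy() @ self.loadings
        return pd.DataFrame(scores, columns=list(self.component_names), index=z.index)

    def to_json(self, path=None) -> str:
        d = {
            "feature_names": list(self.feature_names),
            "component_names": list(self.component_names),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "total_variance": self.total_variance,
            "orientation_reference": self.orientation_reference,
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "PCAModel":
        if isinstance(src, (str, bytes)) and str(src).lstrip().startswith("{"):
            d = json.loads(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        return cls(
            tuple(d["feature_names"]),
            tuple(d["component_names"]),
            np.asarray(d["loadings"]),
            np.asarray(d["explained_variance"]),
            float(d["total_variance"]),
            d.get("orientation_reference"),
        )


def fit_pca(z: pd.DataFrame, k: int = 3) -> PCAModel:
    """Top-k eigenvectors of the correlation matrix of standardized data.

    Input must be standardized (column means ≈ 0).  Loadings are
    orthonormal with non-increasing explained variance; component
    signs are fixed afterwards with :func:`orient_components`.
    """
    n, p = z.shape
    if k > p:
        raise ValueError(f"k={k} exceeds the number of features ({p})")
    if n <= p:
        raise ValueError("need more observations than features")
    zm = z.to_numpy(float)
    if np.abs(zm.mean(axis=0)).max() > 1e-6:
        raise ValueError("fit_pca expects standardized (zero-mean) input")
    cov = zm.T @ zm / (n - 1)  # correlation matrix for unit-SD input
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    loadings = evecs[:, order]
    explained = np.maximum(evals[order], 0.0)
    names = tuple(f"CP{i + 1}" for i in range(k))
    return PCAModel(tuple(z.columns), names, loadings, explained, float(np.trace(cov)))


def orient_components(model: PCAModel, reference: str = "fisher_index") -> PCAModel:
    """Fix component signs: positive loading on the reference feature.

    Any component whose loading on ``reference`` is negative is
    negated (scores flip accordingly); a zero loading is left alone
    with a warning.  Idempotent; explained variance unchanged.
    """
    if reference not in model.feature_names:
        raise ValueError(f"reference feature {reference!r} not in the model")
    ridx = model.feature_names.index(reference)
    loadings = model.loadings.copy()
    for c in range(loadings.shape[1]):
        v = loadings[ridx, c]
        if v < 0:
            loadings[:, c] = -loadings[:, c]
        elif v == 0:
            warnings.warn(
                f"component {model.component_names[c]} has zero loading on "
                f"{reference!r}; sign left unchanged"
            )
    return PCAModel(
        model.feature_names,
        model.component_names,
        loadings,
        model.explained_variance,
        model.total_variance,
        orientation_reference=reference,
    )


def upper_tercile_flag(scores) -> np.ndarray:
    """True where a score exceeds the empirical 2/3 quantile.

    Linear-interpolation (type-7) quantile; ties at the cutpoint are
    not flagged (strict >), so all-equal scores yield no flags.
    """
    s = np.asarray(scores, float)
    if s.size < 3:
        raise ValueError("need at least 3 scores for terciles")
    cut = float(np.quantile(s, 2.0 / 3.0))
    return s > cut
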