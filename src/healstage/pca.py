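"""PCA on z-scored expression profiles: nearest-training-sample staging
and loading x eigenvalue ranking of variance-driving features.

Training samples (rows) are z-scored per feature, decomposed into
principal components, and a test profile — standardized with the
*training* means and standard deviations, then projected — is assigned
the class label of the nearest training sample by Euclidean distance
over the leading components.  Feature importance is the sum over
components of |loading| x eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConfigError, DimensionError
from .types import ClassificationResult, ClassLabel, best_class


@dataclass
class ComponentSpace:
    """A fitted principal-component space over training profiles."""

    loadings: pd.DataFrame  # features x components
    eigenvalues: np.ndarray  # nonincreasing, >= 0
    coords: pd.DataFrame  # training samples x components
    labels: pd.Series  # per-training-sample class label
    mean: pd.Series  # per-feature z-scoring parameters
    sd: pd.Series

    @property
    def features(self) -> pd.Index:
        return self.loadings.index

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    def zscore(self, x: pd.Series) -> np.ndarray:
        """Standardize a profile with the training means/sds."""
        v = x.reindex(self.features)
        if v.isna().any():
            raise DimensionError("test profile lacks features of the fitted space")
        return ((v - self.mean) / self.sd).to_numpy()

    def project(self, x: pd.Series, n_components: int | None = None) -> np.ndarray:
        n = self._check_n(n_components)
        return self.zscore(x) @ self.loadings.to_numpy()[:, :n]

    def _check_n(self, n_components: int | None) -> int:
        if n_components is None:
            return self.n_components
        if not 1 <= n_components <= self.n_components:
            raise ConfigError(
                f"n_components must lie in [1, {self.n_components}]"
            )
        return n_components

    def coords_tsv(self, path: str | PathLike, header_comment: str | None = None) -> None:
        out = self.coords.copy()
        out.insert(0, "label", [str(l) for l in self.labels])
        out.index.name = "sample_id"
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out.to_csv(fh, sep="\t")


def fit_pca(X: pd.DataFrame, labels: Sequence[ClassLabel]) -> ComponentSpace:
    """Fit principal components of the z-scored sample x feature matrix.

    Zero-variance features are dropped before standardization (their
    z-score is undefined).  Standard deviations use ddof=1, matching the
    eigenvalues of the sample covariance.
    """
    if X.shape[0] < 2:
        raise ConfigError("PCA needs at least 2 samples")
    if len(labels) != X.shape[0]:
        raise ConfigError("one label per training sample required")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Xk = X.loc[:, keep]
    mean = Xk.mean(axis=0)
    sdk = sd[keep]
    Z = (Xk - mean) / sdk

    if Xk.shape[1] == 0:
        # nothing varies: a degenerate space with no components
        return ComponentSpace(
            loadings=pd.DataFrame(index=Xk.columns),
            eigenvalues=np.zeros(0),
            coords=pd.DataFrame(index=X.index),
            labels=pd.Series(list(labels), index=X.index),
            mean=mean,
            sd=sdk,
        )

    pca = PCA()
    coords = pca.fit_transform(Z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return ComponentSpace(
        loadings=pd.DataFrame(pca.components_.T, index=Xk.columns, columns=comp_names),
        eigenvalues=pca.explained_variance_.copy(),
        coords=pd.DataFrame(coords, index=X.index, columns=comp_names),
        labels=pd.Series(list(labels), index=X.index),
        mean=mean,
        sd=sdk,
    )


def classify_nearest(
    space: ComponentSpace,
    x: pd.Series,
    n_components: int | None = None,
) -> tuple[ClassificationResult, pd.Series]:
    """Assign the label of the nearest training sample in component space.

    Euclidean distance over the first ``n_components`` (default: all).
    Returns the result plus the full per-training-sample distance table.
    ``scores`` holds each class's minimal distance; exact distance ties
    resolve toward the earlier class, flagged.
    """
    n = space._check_n(n_components)
    proj = space.project(x, n)
    diffs = space.coords.to_numpy()[:, :n] - proj
    dists = pd.Series(np.linalg.norm(diffs, axis=1), index=space.coords.index)

    per_class: dict[ClassLabel, float] = {}
    for sid, d in dists.items():
        lbl = space.labels[sid]
        if lbl not in per_class or d < per_class[lbl]:
            per_class[lbl] = float(d)
    winner, margin, tie = best_class(per_class, higher_is_better=False)
    result = ClassificationResult(
        scores=per_class,
        winner=winner,
        margin=margin,
        tie=tie,
        higher_is_better=False,
        method="pca",
    )
    return result, dists


def rank_loading_features(space: ComponentSpace) -> pd.DataFrame:
    """Rank features by sum over components of |loading| x eigenvalue.

    Magnitudes are used so opposite-sign loadings cannot cancel; the
    returned frame is sorted by descending weight (stable order).
    """
    weights = space.loadings.abs().to_numpy() @ space.eigenvalues
    out = pd.DataFrame(
        {"feature_id": space.features, "weight": weights}
    ).sort_values("weight", ascending=False, kind="stable")
    return out.reset_index(drop=True)
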