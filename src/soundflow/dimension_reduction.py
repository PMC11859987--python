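"""PCA over the eco-acoustic index matrix and representative-index selection.

Observations are the pooled (site, window) rows of the index matrix; the
eight index columns are standardized to zero mean and unit variance, so the
PCA diagonalizes their correlation structure.  Each principal dimension
carries an explained-variance fraction V_i with sum_i V_i = 1; the
contribution of index j to dimension i is the squared-loading share
100 * w_ij^2 / sum_k w_kj^2.  Analyses retain the leading dimensions (top-2
by default) and pick one representative index per retained dimension —
normally the top contributor, with a manual override for interpretability-
driven choices (e.g. preferring BI over a marginally stronger contributor
because BI reads directly as biophony level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .index_engine import INDEX_NAMES

__all__ = [
    "PCAResult",
    "RepresentativeChoice",
    "standardize",
    "run_pca",
    "retain_dimensions",
    "select_representatives",
]


@dataclass
class PCAResult:
    """Eigenstructure of the standardized index matrix."""

    eigenvalues: np.ndarray
    explained_variance: np.ndarray  # V_i fractions, descending
    cumulative_ev: np.ndarray
    loadings: pd.DataFrame       # index x dimension, unit-norm columns
    contributions: pd.DataFrame  # index x dimension, percent, columns sum 100
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "cumulative_ev": self.cumulative_ev.tolist(),
            "loadings": self.loadings.round(12).to_dict(),
            "contributions": self.contributions.round(12).to_dict(),
            "n_obs": self.n_obs,
        }


@dataclass
class RepresentativeChoice:
    """The index chosen to stand for one retained dimension."""

    dimension: int          # 1-based
    chosen_index: str
    policy: str             # 'top_contribution' or 'manual'
    contribution_pct: float


def standardize(matrix: pd.DataFrame, columns=None):
    """Zero-mean, unit-variance columns; incomplete rows dropped and counted.

    Returns ``(standardized DataFrame, n_dropped)``.  Raises on fewer than
    9 complete rows (one more than the variable count) or on a constant
    column, which is named in the error.
    """
    columns = list(columns) if columns is not None else [
        c for c in INDEX_NAMES if c in matrix.columns
    ]
    data = matrix[columns].astype(float)
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    if len(complete) < 9:
        raise ValueError(
            f"need at least 9 complete rows, got {len(complete)}"
        )
    for col in columns:
        if complete[col].nunique() == 1:
            raise ValueError(f"constant column: {col!r}")
    std = complete.std(ddof=1)
    z = (complete - complete.mean()) / std
    return z, n_dropped


def run_pca(standardized: pd.DataFrame) -> PCAResult:
    """Full eigendecomposition of the standardized matrix.

    Signs are fixed so each loading vector's largest-magnitude entry is
    positive (PCA signs are otherwise arbitrary).  Rank-deficient input is
    allowed; trailing eigenvalues are then ~0.
    """
    z = standardized.to_numpy(float)
    n_obs, n_var = z.shape
    model = PCA(n_components=n_var)
    model.fit(z)
    components = model.components_  # (dim, index), unit-norm rows
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] *= -1.0
    ev = model.explained_variance_ratio_
    dims = [f"Dim{i + 1}" for i in range(n_var)]
    loadings = pd.DataFrame(
        components.T, index=standardized.columns, columns=dims
    )
    contributions = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    return PCAResult(
        eigenvalues=model.explained_variance_,
        explained_variance=ev,
        cumulative_ev=np.cumsum(ev),
        loadings=loadings,
        contributions=contributions,
        n_obs=n_obs,
    )


def retain_dimensions(
    result: PCAResult,
    policy: str = "top_k",
    k: int = 2,
    mean_fraction: float = 1.0,
):
    """Number of leading dimensions to keep, plus their cumulative EV.

    ``top_k`` keeps the first ``k`` dimensions (default 2).  ``threshold``
    keeps every dimension whose V_i exceeds ``mean_fraction`` times the mean
    variance V-bar = 1/8, dropping the clearly sub-average ones.
    """
    v = result.explained_variance
    if policy == "top_k":
        kept = min(k, len(v))
    elif policy == "threshold":
        kept = int((v > mean_fraction * v.mean()).sum())
        kept = max(kept, 1)
    else:
        raise ValueError("policy must be 'top_k' or 'threshold'")
    return kept, float(result.cumulative_ev[kept - 1])


def select_representatives(
    result: PCAResult,
    retained: int,
    policy: str = "top_contribution",
    overrides: dict | None = None,
) -> list[RepresentativeChoice]:
    """One representative index per retained dimension.

    The default policy picks the maximum-contribution index, ties broken by
    the canonical order H, ACI, ADI, AEI, NDSI, BI, DSC, ZCR.  ``overrides``
    maps 1-based dimension numbers to index names and is recorded as a
    manual choice.
    """
    if retained < 1:
        raise ValueError("retained must be >= 1")
    overrides = overrides or {}
    order = {name: i for i, name in enumerate(INDEX_NAMES)}
    known = set(result.contributions.index)
    choices = []
    for dim in range(1, retained + 1):
        col = result.contributions[f"Dim{dim}"]
        if dim in overrides:
            name = overrides[dim]
            if name not in known:
                raise ValueError(f"override names unknown index {name!r}")
            choices.append(
                RepresentativeChoice(dim, name, "manual", float(col[name]))
            )
            continue
        best = max(
            col.index, key=lambda n: (col[n], -order.get(n, len(order)))
        )
        choices.append(
            RepresentativeChoice(
                dim, best, "top_contribution", float(col[best])
            )
        )
    return choices
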