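"""Principal component analysis of the annual vintage table.

Vintage chemistry (probable alcohol, pH, total acidity, berry weight),
phenology dates and production variables are condensed into a few
uncorrelated annual score series.  The leading component typically captures
the maturity axis: warm years with high alcohol and pH, low acidity and
early veraison/harvest sit at one end, cool late years at the other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import robust_stats
from .robust_stats import TrendResult

__all__ = ["PCDecomposition", "run_pca", "score_trend_report", "DEFAULT_PCA_COLUMNS"]

log = logging.getLogger(__name__)

DEFAULT_PCA_COLUMNS = (
    "pvad", "ph", "tta", "wb100", "veraison_doy", "harvest_doy",
    "production", "yield",
)


@dataclass
class PCDecomposition:
    """Loadings, explained-variance fractions and annual scores.

    ``loadings`` is variable x component (orthonormal columns),
    ``explained_fraction`` the per-component share of total variance,
    ``scores`` the year x component series (zero mean), ``means``/``sds``
    the centering (and optional standardization) applied, ``n_dropped``
    the number of incomplete rows removed before fitting.
    """

    loadings: pd.DataFrame
    explained_fraction: pd.Series
    scores: pd.DataFrame
    means: pd.Series
    sds: pd.Series | None
    n_dropped: int = 0

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def run_pca(
    table: pd.DataFrame,
    n_components: int = 3,
    scaling: str = "center+standardize",
    columns=DEFAULT_PCA_COLUMNS,
) -> PCDecomposition:
    """Mean-centered (optionally standardized) PCA of the vintage table.

    Rows with missing values in the analysis columns are dropped and logged.
    Components are ordered by decreasing eigenvalue with a deterministic sign
    convention: the largest-magnitude loading of each component is positive,
    and the first component is further flipped if needed so probable alcohol
    (``pvad``) loads positively — making high PC1 mean hot-year maturity.

    The default standardizes as well as centers because the variables mix
    units (% vol, g/L, grams, day-of-year, volumes); pass ``scaling="center"``
    for covariance-matrix PCA.
    """
    if scaling not in ("center", "center+standardize"):
        raise ValueError("scaling must be 'center' or 'center+standardize'")
    cols = [c for c in columns if c in table.columns]
    if len(cols) < 2:
        raise ValueError("need at least two analysis variables")
    data = table[cols].astype(float)
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    if n_dropped:
        log.warning("dropping %d incomplete vintage row(s)", n_dropped)
    n, p = complete.shape
    rank = min(n - 1, p)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    if n < n_components + 1:
        raise ValueError("need at least n_components + 1 complete rows")

    means = complete.mean()
    centered = complete - means
    sds = None
    if scaling == "center+standardize":
        sds = complete.std(ddof=1)
        if (sds == 0).any():
            raise ValueError(f"constant column(s): {list(sds.index[sds == 0])}")
        centered = centered / sds

    eigvals = np.linalg.eigvalsh(np.cov(centered.to_numpy(), rowvar=False))
    if np.sum(eigvals > 1e-10 * eigvals.max()) < p:
        warnings.warn("analysis matrix is rank deficient")

    pca = PCA(n_components=n_components, svd_solver="full")
    raw_scores = pca.fit_transform(centered.to_numpy())
    load = pca.components_.T.copy()  # variable x component

    for j in range(n_components):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] *= -1.0
            raw_scores[:, j] *= -1.0
    if "pvad" in cols:
        j_pvad = cols.index("pvad")
        if load[j_pvad, 0] < 0:
            load[:, 0] *= -1.0
            raw_scores[:, 0] *= -1.0

    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCDecomposition(
        loadings=pd.DataFrame(load, index=cols, columns=comp_names),
        explained_fraction=pd.Series(pca.explained_variance_ratio_, index=comp_names),
        scores=pd.DataFrame(raw_scores, index=complete.index, columns=comp_names),
        means=means,
        sds=sds,
        n_dropped=n_dropped,
    )


def score_trend_report(decomp: PCDecomposition, component: str | int = "PC1") -> TrendResult:
    """Mann-Kendall test and Theil-Sen slope for one PC score series."""
    if isinstance(component, int):
        component = f"PC{component}"
    series = decomp.scores[component]
    years = np.asarray(series.index, dtype=float)
    return robust_stats.mann_kendall(series.to_numpy(), years)
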