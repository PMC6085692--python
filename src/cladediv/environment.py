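"""Environmental heterogeneity within a clade's range.

The climatic description of each locality (19 bioclim-style variables plus
percent tree cover) is normalized by principal components analysis on the
correlation matrix — variables are centered and scaled to unit variance so
that precipitation-scale variables cannot dominate temperature-scale ones —
and environmental dissimilarity between localities is the Euclidean distance
on the leading axes (axes 1–5 by default). A clade's environmental
heterogeneity is the mean dissimilarity over its unordered locality pairs:
low when its range is climatically homogeneous, high otherwise.
"""
from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .distance import DistanceMatrix
from .geodesy import EARTH_RADIUS_KM, mean_pairwise

__all__ = [
    "ENV_COLUMNS",
    "EnvScores",
    "pca_scores",
    "env_dissimilarity",
    "clade_env_heterogeneity",
    "grid_average",
]

logger = logging.getLogger(__name__)

#: Canonical environment column names: 19 bioclim-style variables + tree cover.
ENV_COLUMNS: tuple[str, ...] = tuple(f"env{i:02d}" for i in range(1, 20)) + ("tree_cover",)

_KM_PER_DEG_LAT = np.pi * EARTH_RADIUS_KM / 180.0


@dataclass(frozen=True)
class EnvScores:
    """PCA scores per locality plus everything needed to reproduce them.

    ``scores`` has one row per locality (index = locality id) and columns
    PC1..PCK. ``loadings`` maps standardized variables to axes, so that
    ``(X - center)/scale @ loadings == scores``.
    """

    scores: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame
    center: pd.Series
    scale: pd.Series
    dropped: tuple[str, ...]

    @property
    def locality_ids(self) -> tuple[str, ...]:
        return tuple(self.scores.index)

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def pca_scores(
    localities: pd.DataFrame,
    k: int = 5,
    *,
    id_col: str = "locality",
    var_cols: Sequence[str] | None = None,
    use_correlation: bool = True,
) -> EnvScores:
    """Project localities onto the top-``k`` principal axes of their environment.

    Variables are centered and (for the default correlation-matrix PCA)
    scaled to unit variance (ddof=1). Constant variables are dropped with a
    warning. Axis signs follow the convention that the largest-magnitude
    loading on each axis is positive.
    """
    if var_cols is None:
        var_cols = [c for c in localities.columns if c not in (id_col, "lat", "lon")]
    ids = localities[id_col].astype(str)
    if ids.duplicated().any():
        raise ValueError("duplicate locality ids")
    x = localities[list(var_cols)].astype(float)
    if x.isna().any().any():
        bad = sorted(x.columns[x.isna().any()])
        raise ValueError(f"missing values in environment variables: {bad}")
    if len(x) < 2:
        raise ValueError("PCA needs at least 2 localities")
    sd = x.std(ddof=1)
    dropped = tuple(sd.index[sd == 0.0])
    if dropped:
        logger.warning("dropping constant environment variables: %s", list(dropped))
        x = x.drop(columns=list(dropped))
        sd = sd.drop(index=list(dropped))
    if x.shape[1] == 0:
        raise ValueError("no non-constant environment variables")
    k = min(k, x.shape[1], len(x) - 1)
    if len(x) < k + 1:
        raise ValueError(f"PCA with k={k} needs at least {k + 1} localities")
    center = x.mean()
    scale = sd if use_correlation else pd.Series(1.0, index=x.columns)
    z = (x - center) / scale
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    components = pca.components_  # (k, n_vars)
    # Sign convention: the largest-|loading| variable on each axis loads positively.
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    axis_names = [f"PC{i + 1}" for i in range(k)]
    return EnvScores(
        scores=pd.DataFrame(scores, index=pd.Index(ids, name=id_col), columns=axis_names),
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(components.T, index=x.columns, columns=axis_names),
        center=center,
        scale=scale,
        dropped=dropped,
    )


def env_dissimilarity(scores: EnvScores) -> DistanceMatrix:
    """Euclidean distance between locality score vectors on axes 1..K."""
    d = squareform(pdist(scores.scores.to_numpy(), metric="euclidean"))
    return DistanceMatrix(scores.locality_ids, d)


def clade_env_heterogeneity(dm: DistanceMatrix, localities: Sequence[str]) -> float:
    """Mean environmental dissimilarity over a clade's unordered locality pairs."""
    return mean_pairwise(dm, localities)


def grid_average(
    points: pd.DataFrame,
    value_cols: Sequence[str],
    cell_km: float = 5.0,
    *,
    lat_col: str = "lat",
    lon_col: str = "lon",
) -> pd.DataFrame:
    """Replace point values by the mean of their square grid cell.

    Emulates coarsening a fine raster: points falling in the same cell of a
    ``cell_km`` grid anchored at the data bounding box share the cell mean.
    Uses an equirectangular local projection, adequate at few-km cells.
    """
    if len(points) == 0:
        raise ValueError("empty input")
    lat = points[lat_col].to_numpy(dtype=float)
    lon = points[lon_col].to_numpy(dtype=float)
    y = (lat - lat.min()) * _KM_PER_DEG_LAT
    x = (lon - lon.min()) * _KM_PER_DEG_LAT * np.cos(np.radians(lat.mean()))
    cells = pd.MultiIndex.from_arrays(
        [np.floor(x / cell_km).astype(int), np.floor(y / cell_km).astype(int)]
    )
    out = points.copy()
    for col in value_cols:
        out[col] = points[col].groupby(cells).transform("mean").to_numpy()
    return out
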