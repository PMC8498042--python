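"""Genotype-by-environment diagnostics and environment characterization.

Arranges the female-GCA-by-environment BLUPs as a genotypes x environments
matrix, computes Euclidean distances between environments, clusters them by
complete linkage, summarizes them by PCA, relates interaction distances to
environmental-profile distances with a permutation Mantel test, and
rescales EVI series to the vegetation condition index (VCI).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .lmm import MixedModelFit
from .types import EnvironmentProfile

__all__ = [
    "DistanceMatrix",
    "PCAResult",
    "interaction_effects",
    "euclidean_distances",
    "complete_linkage",
    "linkage_to_newick",
    "pca",
    "project_onto",
    "mantel",
    "vci",
    "profile_distances",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < -1e-10).any():
            raise ValueError("distances must be nonnegative")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def interaction_effects(fit: MixedModelFit) -> pd.DataFrame:
    """Female-GCA-by-environment BLUPs as a females x environments table.

    Consumes the variance-component fit of the combining-ability model; the
    interaction term's levels are labelled ``female@environment``.
    """
    if "gca_female_x_env" not in fit.blups:
        raise KeyError("fit does not contain a female-GCA-by-environment term")
    levels = fit.level_names["gca_female_x_env"]
    values = fit.blups["gca_female_x_env"]
    rows = []
    for lvl, v in zip(levels, values):
        female, env = lvl.split("@", 1)
        rows.append({"female": female, "environment": env, "effect": v})
    mat = pd.DataFrame(rows).pivot(index="female", columns="environment", values="effect")
    return mat.fillna(0.0)


def euclidean_distances(matrix: pd.DataFrame, axis: str = "columns") -> DistanceMatrix:
    """Pairwise Euclidean distances between columns (or rows) of a matrix."""
    if matrix.isna().any().any():
        raise ValueError("matrix has missing cells")
    data = matrix.T if axis == "columns" else matrix
    if data.shape[0] < 2:
        raise ValueError("need at least 2 vectors to compare")
    d = squareform(pdist(data.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(ids=list(map(str, data.index)), values=d)


def complete_linkage(
    dist: DistanceMatrix, n_clusters: int | None = None
) -> tuple[np.ndarray, dict[str, int] | None]:
    """Agglomerative clustering under the maximum-linkage rule.

    Returns the scipy linkage matrix (merge heights are non-decreasing)
    and, if ``n_clusters`` is given, a flat id -> cluster-label assignment
    from cutting the tree.
    """
    Z = hierarchy.linkage(dist.condensed(), method="complete")
    flat = None
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        flat = dict(zip(dist.ids, map(int, labels)))
    return Z, flat


def linkage_to_newick(Z: np.ndarray, ids: list[str]) -> str:
    """Render a linkage matrix as a Newick string with merge-height branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a PCA."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray
    means: np.ndarray
    scales: np.ndarray


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = False) -> PCAResult:
    """Principal component analysis by SVD of the (optionally scaled) matrix.

    Explained fractions sum to one; the sign convention makes the largest-
    magnitude loading of each component positive.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    means = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - means
    scales = Xc.std(axis=0, ddof=1) if scale else np.ones(X.shape[1])
    if scale and np.any(scales == 0):
        raise ValueError("constant column; cannot scale")
    Xc = Xc / scales
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix has no principal components")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-magnitude loading per component positive
    for j in range(Vt.shape[0]):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * S
    explained = S**2 / np.sum(S**2)
    comp = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=matrix.columns, columns=comp),
        explained=explained,
        means=means,
        scales=scales,
    )


def project_onto(model: PCAResult, new_rows: pd.DataFrame) -> pd.DataFrame:
    """Project new observations onto a reference PCA's axes.

    Rows are centered (and scaled) with the reference statistics, then
    multiplied by the reference loadings; a row equal to the reference mean
    maps to the origin.
    """
    if list(new_rows.columns) != list(model.loadings.index):
        raise ValueError("column space does not match the reference PCA")
    Xc = (new_rows.to_numpy(dtype=float) - model.means) / model.scales
    return pd.DataFrame(
        Xc @ model.loadings.to_numpy(),
        index=new_rows.index,
        columns=model.loadings.columns,
    )


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Mantel test of association between two distance matrices.

    r is the Pearson correlation of the off-diagonal entries; the one-sided
    upper p-value comes from permuting the id order of the second matrix:
    p = (1 + #{r_perm >= r}) / (1 + n_permutations). With ``exhaustive``
    every permutation is enumerated (tiny matrices only) and
    p = #{r_perm >= r} / n!.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share the same ids")
    n = len(d1.ids)
    iu = np.triu_indices(n, k=1)

    def corr(m2: np.ndarray) -> float:
        return float(np.corrcoef(d1.values[iu], m2[iu])[0, 1])

    r_obs = corr(d2.values)
    if exhaustive:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            p = np.asarray(perm)
            if corr(d2.values[np.ix_(p, p)]) >= r_obs - 1e-12:
                count += 1
            total += 1
        return r_obs, count / total
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        if corr(d2.values[np.ix_(p, p)]) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + n_permutations)


def vci(profile: EnvironmentProfile) -> np.ndarray:
    """Vegetation condition index: (EVI - EVI_min) / (EVI_max - EVI_min).

    Rescales each observation by the reference-period extremes and clamps
    to [0, 1] (observed EVI may exceed the reference range).
    """
    if profile.evi_max <= profile.evi_min:
        raise ValueError("EVI_max must exceed EVI_min")
    v = (profile.evi - profile.evi_min) / (profile.evi_max - profile.evi_min)
    return np.clip(v, 0.0, 1.0)


def profile_distances(
    profiles: list[EnvironmentProfile], on: str = "vci"
) -> DistanceMatrix:
    """Euclidean distances between per-location VCI (or PAW) series.

    Profiles are linearly interpolated onto the overlapping date range of
    all series before comparison.
    """
    if on not in ("vci", "paw"):
        raise ValueError("on must be 'vci' or 'paw'")
    lo = max(float(p.dates.astype(float).min()) for p in profiles)
    hi = min(float(p.dates.astype(float).max()) for p in profiles)
    if hi <= lo:
        raise ValueError("profiles have non-overlapping date ranges")
    grid = np.linspace(lo, hi, max(len(p.dates) for p in profiles))
    series = []
    for p in profiles:
        y = vci(p) if on == "vci" else np.asarray(p.paw, dtype=float)
        series.append(np.interp(grid, p.dates.astype(float), y))
    mat = pd.DataFrame(
        np.asarray(series).T, columns=[p.location_id for p in profiles]
    )
    return euclidean_distances(mat, axis="columns")
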