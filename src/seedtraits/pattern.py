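"""Pattern analysis: PCA biplot and Ward clustering of standardized BLUP means.

The accession x trait BLUP matrix is standardized trait-wise (mean 0,
sample sd 1), then

* PCA is the eigendecomposition of the trait correlation matrix of the
  standardized values: scores = z V, loadings = V sqrt(eigenvalues),
  percentage variance = 100 eigenvalue / sum;
* accessions are clustered by agglomerative hierarchical clustering with
  Euclidean distance and Ward linkage, and the dendrogram is cut at a
  user-chosen number of groups k (the truncation level).

A deterministic eigenvector sign convention is applied: within each
component the loading with the largest absolute value is made positive
(ties broken by earliest trait index), so biplots are reproducible
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .repeatability import BlupMatrix

__all__ = [
    "PatternResult",
    "standardize",
    "pca_biplot",
    "cluster_accessions",
    "group_means",
    "pattern_analysis",
]


@dataclass(frozen=True)
class PatternResult:
    accessions: tuple
    traits: tuple
    scores: pd.DataFrame  # accession x component
    loadings: pd.DataFrame  # trait x component
    pct_var: np.ndarray  # % of total variation per component
    clusters: pd.Series | None = None  # accession -> group id (1..k)
    group_means: pd.DataFrame | None = None  # group x trait, original units
    merge_history: np.ndarray | None = None  # scipy linkage matrix


def _as_frame(bm) -> pd.DataFrame:
    return bm.values if isinstance(bm, BlupMatrix) else pd.DataFrame(bm)


def standardize(bm: BlupMatrix | pd.DataFrame) -> pd.DataFrame:
    """Center each trait column to mean 0 and scale to unit sample sd
    (n-1 denominator)."""
    df = _as_frame(bm)
    sds = df.std(ddof=1)
    constant = sds.index[sds == 0].tolist()
    if constant:
        raise ValueError(f"constant trait column(s): {', '.join(map(str, constant))}")
    return (df - df.mean()) / sds


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Largest-|loading| entry of each component made positive; ties go to
    the earliest trait index."""
    V = V.copy()
    for c in range(V.shape[1]):
        col = np.abs(V[:, c])
        # earliest index among maxima
        j = int(np.flatnonzero(col == col.max())[0])
        if V[j, c] < 0:
            V[:, c] = -V[:, c]
    return V


def pca_biplot(z: pd.DataFrame) -> PatternResult:
    """PCA of a standardized matrix via the trait correlation matrix."""
    zz = np.asarray(z, float)
    n, p = zz.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 accessions and 2 traits")
    C = (zz.T @ zz) / (n - 1)  # correlation matrix of standardized columns
    if not np.any(C):
        raise ValueError("rank-0 input: all correlations undefined")
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = _fix_signs(eigvec[:, order])
    pct = 100.0 * eigval / eigval.sum()
    comp = [f"PC{i + 1}" for i in range(p)]
    scores = pd.DataFrame(zz @ eigvec, index=z.index, columns=comp)
    loadings = pd.DataFrame(
        eigvec * np.sqrt(eigval), index=z.columns, columns=comp
    )
    return PatternResult(
        accessions=tuple(z.index),
        traits=tuple(z.columns),
        scores=scores,
        loadings=loadings,
        pct_var=pct,
    )


def cluster_accessions(z: pd.DataFrame, k: int, linkage: str = "ward"):
    """Hierarchical clustering of accessions (rows of z), cut at k groups.

    Returns ``(clusters, merge_history)`` where clusters maps accession to
    a group id in 1..k assigned in order of first accession appearance,
    and merge_history is the scipy linkage matrix (heights non-decreasing
    for Ward).
    """
    n = len(z)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    Z = hierarchy.linkage(pdist(np.asarray(z, float)), method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel 1..k by first appearance for determinism
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    clusters = pd.Series([relabel[lab] for lab in raw], index=z.index, name="group")
    return clusters, Z


def group_means(bm: BlupMatrix | pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Mean BLUP value per group per trait, in original trait units.

    The returned frame is indexed by group id and carries a ``n_accessions``
    column with the group sizes.
    """
    df = _as_frame(bm)
    unknown = [a for a in clusters.index if a not in df.index]
    if unknown:
        raise ValueError(f"unknown accession(s) in assignment: {unknown}")
    missing = [a for a in df.index if a not in clusters.index]
    if missing:
        raise ValueError(f"accession(s) without a group: {missing}")
    out = df.groupby(clusters).mean()
    out.index.name = "group"
    out.insert(0, "n_accessions", df.groupby(clusters).size())
    return out


def pattern_analysis(
    bm: BlupMatrix | pd.DataFrame, k: int, linkage: str = "ward"
) -> PatternResult:
    """Full pattern analysis: standardize, PCA, cluster, group means."""
    df = _as_frame(bm)
    z = standardize(df)
    pca = pca_biplot(z)
    clusters, Z = cluster_accessions(z, k, linkage=linkage)
    gm = group_means(df, clusters)
    return PatternResult(
        accessions=pca.accessions,
        traits=pca.traits,
        scores=pca.scores,
        loadings=pca.loadings,
        pct_var=pca.pct_var,
        clusters=clusters,
        group_means=gm,
        merge_history=Z,
    )
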