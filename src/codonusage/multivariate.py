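"""Correlation, clustering, PCA and k-means stages.

These wrap scipy/scikit-learn behind the shapes the rest of the pipeline
uses: an index-pair correlation matrix with significance stars, a
hierarchical dendrogram over species RSCU profiles, PCA in species or codon
mode, and k-means on the normalized two-gene CAI plane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .indices import RscuTable

DEFAULT_SEED = 20241004

STAR_BANDS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


@dataclass(frozen=True)
class IndexCorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def stars(self) -> pd.DataFrame:
        """Significance stars at the 0.05 / 0.01 / 0.001 / 0.0001 bands
        (unadjusted two-sided p-values)."""
        def star(p):
            if math.isnan(p):
                return ""
            for cut, s in STAR_BANDS:
                if p <= cut:
                    return s
            return ""
        return self.p.map(star)


@dataclass(frozen=True)
class ClusterTree:
    """scipy linkage over species labels, with metric/linkage recorded."""

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]
    metric: str
    method: str

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Dendrogram as a rooted newick string with merge heights as depths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                label = self.labels[node.id].replace(" ", "_")
                return f"{label}:{parent_height:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        body = render(tree, tree.dist).rsplit(":", 1)[0]
        return body + ";"


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    mode: str


@dataclass(frozen=True)
class KmeansResult:
    k: int
    assignments: pd.Series
    centroids: np.ndarray
    inertia: float
    seed: int
    normalized: pd.DataFrame


def index_correlations(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> IndexCorrelationMatrix:
    """Pairwise Pearson r and two-sided p over index columns.

    Rows with a missing value in a pair are dropped pairwise; a
    zero-variance column yields NaN for all its pairs.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    if len(table) < 3:
        raise ValueError("need at least 3 rows for correlations")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            sub = table[[a, b]].dropna()
            if len(sub) < 3 or sub[a].nunique() == 1 or sub[b].nunique() == 1:
                rv = pv = math.nan
            else:
                rv, pv = pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return IndexCorrelationMatrix(r=r, p=p, n=len(table))


def rscu_matrix(
    per_species_rscu: Mapping[str, RscuTable], impute_neutral: bool = True
) -> pd.DataFrame:
    """Species x codon RSCU matrix for clustering/PCA.

    A species missing an amino-acid family has that family's codons imputed
    at the neutral value 1.0 (no bias), with a warning, so no species is
    dropped.
    """
    df = pd.DataFrame(
        {sp: t.as_series() for sp, t in per_species_rscu.items()}
    ).T
    if df.isna().any().any():
        if impute_neutral:
            missing = df.index[df.isna().any(axis=1)].tolist()
            warnings.warn(
                f"imputing neutral RSCU=1 for absent families in: {missing}"
            )
            df = df.fillna(1.0)
        else:
            df = df.dropna(axis=0)
    return df


def hierarchical_cluster_rscu(
    matrix: pd.DataFrame, metric: str = "euclidean", method: str = "ward"
) -> ClusterTree:
    """Agglomerative dendrogram over species RSCU profiles (rows)."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 species to cluster")
    # stable row order => deterministic scipy tie-breaking
    matrix = matrix.sort_index()
    link = hierarchy.linkage(matrix.to_numpy(), method=method, metric=metric)
    return ClusterTree(
        linkage_matrix=link,
        labels=tuple(matrix.index),
        metric=metric,
        method=method,
    )


def pca_rscu(matrix: pd.DataFrame, mode: str = "species",
             n_components: int | None = None) -> PcaResult:
    """PCA of the RSCU matrix, column-centered and unscaled.

    ``species`` mode scores the rows (species); ``codons`` mode transposes
    first, scoring codons so their PC1/PC2 loadings rank codon contributions.
    """
    if mode not in {"species", "codons"}:
        raise ValueError(f"unknown PCA mode: {mode}")
    data = matrix if mode == "species" else matrix.T
    if len(data) < 2:
        raise ValueError("need at least 2 rows for PCA")
    max_rank = min(len(data) - 1, data.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant matrix
        scores = pca.fit_transform(data.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=data.index, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=data.columns, columns=comp_names
        ),
        explained_variance_ratio=np.nan_to_num(pca.explained_variance_ratio_),
        mode=mode,
    )


def _normalize(df: pd.DataFrame, how: str) -> pd.DataFrame:
    if how == "zscore":
        std = df.std(ddof=0).replace(0, 1.0)
        return (df - df.mean()) / std
    if how == "minmax":
        rng = (df.max() - df.min()).replace(0, 1.0)
        return (df - df.min()) / rng
    raise ValueError(f"unknown normalization: {how}")


def kmeans_cai(
    cai_pairs: pd.DataFrame,
    k: int = 3,
    normalization: str = "zscore",
    seed: int = DEFAULT_SEED,
    n_init: int = 50,
) -> KmeansResult:
    """k-means on the per-gene-normalized CAI plane (one row per species).

    Both CAI columns are normalized independently before clustering; the
    best of ``n_init`` seeded restarts (by inertia) is returned.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(cai_pairs):
        raise ValueError(f"k={k} exceeds the {len(cai_pairs)} species")
    norm = _normalize(cai_pairs.astype(float), normalization)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(norm.to_numpy())
    return KmeansResult(
        k=k,
        assignments=pd.Series(labels, index=cai_pairs.index, name="cluster"),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        normalized=norm,
    )
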