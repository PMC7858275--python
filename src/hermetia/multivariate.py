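"""Multivariate analysis of substrate physicochemical profiles.

PCA on standardized sample-by-variable tables, k-means grouping of variable
loadings in the first component plane, hierarchical clustering of sample
replicates, and gap-statistic selection of the cluster number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "PcaResult",
    "ClusterResult",
    "pca",
    "kmeans_variables",
    "hierarchical_cluster",
    "gap_statistic",
]


@dataclass
class PcaResult:
    scores: pd.DataFrame         # samples x components
    loadings: pd.DataFrame       # variables x components (orthonormal columns)
    explained_variance_fraction: np.ndarray

    def reconstruct(self, standardized: bool = True) -> pd.DataFrame:
        """Scores @ loadings.T; equals the standardized input for a full decomposition."""
        rec = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(rec, index=self.scores.index, columns=self.loadings.index)


@dataclass
class ClusterResult:
    assignments: dict[str, int]
    k: int
    method: str
    criterion_trace: dict[int, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _standardize(x: pd.DataFrame) -> pd.DataFrame:
    sd = x.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance variables: {list(zero.index)}")
    return (x - x.mean()) / sd


def pca(table: pd.DataFrame, standardize: bool = True,
        n_components: int | None = None) -> PcaResult:
    """Principal component analysis with a deterministic sign convention.

    Variables are centered and (by default) scaled to unit variance; each
    loading column's largest-magnitude entry is made positive so results do
    not depend on the eigensolver's sign choice.
    """
    if table.isna().any().any():
        raise ValueError("missing values in input")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 variables")
    x = _standardize(table) if standardize else table - table.mean()
    k = n_components or min(x.shape)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x.to_numpy())
    loadings = model.components_.T  # variables x components, orthonormal
    # sign convention
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=table.columns, columns=comp_names),
        explained_variance_fraction=model.explained_variance_ratio_,
    )


def kmeans_variables(loadings: pd.DataFrame, k: int, n_starts: int = 25,
                     seed: int = 0) -> ClusterResult:
    """k-means on variable loadings restricted to the first two components."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(loadings):
        raise ValueError("k exceeds number of variables")
    x = loadings.iloc[:, :2].to_numpy()
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    labels = km.fit_predict(x)
    return ClusterResult(
        assignments=dict(zip(loadings.index, (int(v) for v in labels))),
        k=k, method="kmeans",
        criterion_trace={k: float(km.inertia_)},
    )


def hierarchical_cluster(table: pd.DataFrame, linkage: str = "ward",
                         metric: str = "euclidean", k: int | None = None,
                         standardize: bool = True) -> ClusterResult:
    """Agglomerative clustering of samples with a flat cut at ``k``."""
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if len(table) < 2:
        raise ValueError("need at least 2 samples")
    x = _standardize(table).to_numpy() if standardize else table.to_numpy()
    z = hierarchy.linkage(x, method=linkage, metric=metric)
    kk = k or 2
    flat = hierarchy.fcluster(z, t=kk, criterion="maxclust")
    return ClusterResult(
        assignments=dict(zip(table.index, (int(v) for v in flat))),
        k=int(len(set(flat))), method=f"hierarchical-{linkage}",
        extra={"linkage_matrix": z},
    )


def _wss(x: np.ndarray, k: int, seed: int, n_starts: int = 10) -> float:
    if k == 1:
        centered = x - x.mean(axis=0)
        return float((centered ** 2).sum())
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    km.fit(x)
    return float(km.inertia_)


def gap_statistic(table: pd.DataFrame, k_range: range | list[int] = range(1, 11),
                  b_references: int = 50, seed: int = 0,
                  standardize: bool = True) -> tuple[int, pd.DataFrame]:
    """Gap statistic for the number of clusters.

    ``Gap(k) = mean_b log(W_kb) - log(W_k)`` with B reference datasets drawn
    uniformly over the data's bounding box in PCA-rotated coordinates (the
    original recommendation).  The selected k is the smallest with
    ``Gap(k) >= Gap(k+1) - s(k+1)`` where ``s = sd * sqrt(1 + 1/B)``.
    """
    if b_references < 10:
        raise ValueError("need at least 10 reference datasets")
    ks = list(k_range)
    n = len(table)
    if max(ks) > n - 1:
        raise ValueError("k_range too large for sample count")
    x = _standardize(table).to_numpy() if standardize else table.to_numpy()
    rng = np.random.default_rng(seed)

    # rotate into principal axes for the reference bounding box
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    xr = xc @ vt.T
    lo, hi = xr.min(axis=0), xr.max(axis=0)

    log_w = np.array([np.log(_wss(x, k, seed)) for k in ks])
    log_w_ref = np.empty((b_references, len(ks)))
    for b in range(b_references):
        ref_r = rng.uniform(lo, hi, size=xr.shape)
        ref = ref_r @ vt  # back to original coordinates
        ref_seed = int(rng.integers(2 ** 31 - 1))
        for i, k in enumerate(ks):
            log_w_ref[b, i] = np.log(_wss(ref, k, ref_seed, n_starts=3))

    gap = log_w_ref.mean(axis=0) - log_w
    sk = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1 + 1 / b_references)
    optimal = ks[-1]
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            optimal = ks[i]
            break
    curve = pd.DataFrame({"k": ks, "gap": gap, "s_k": sk, "log_W": log_w})
    return optimal, curve
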