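"""Peak/sample clustering and stage structure.

Peaks and samples are clustered hierarchically on 1 - Pearson correlation
with average linkage; the number of clusters is picked by mean silhouette
over a candidate range. Samples are additionally embedded by PCA and
partitioned with a small deterministic k-medoids (PAM), from which the
early/interim/late stage structure is read. Stage-specific and conserved
("conservative") elements are called on linear normalized stage means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score


def center_rows(matrix: pd.DataFrame, scale: bool = True) -> tuple[pd.DataFrame, pd.Series]:
    """Row-center (and by default unit-variance scale) a matrix.

    Zero-variance rows are left centered but unscaled; the returned flag
    series marks them.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    centered = matrix.sub(matrix.mean(axis=1), axis=0)
    flags = pd.Series(False, index=matrix.index)
    if scale:
        sd = centered.std(axis=1, ddof=0)
        flags = sd == 0
        safe = sd.where(~flags, 1.0)
        centered = centered.div(safe, axis=0)
    return centered, flags


def correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; constant rows treated as r=0."""
    x = np.asarray(matrix, dtype=float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)
    r[np.ix_(sd == 0, sd == 0)] = 0.0
    np.fill_diagonal(r, 1.0)
    d = 1.0 - r
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ClusterResult:
    labels: pd.Series                 # item -> cluster label (1-based ints)
    k: int
    silhouette: dict[int, float] = field(default_factory=dict)
    linkage: np.ndarray | None = None


def hier_cluster(
    matrix: pd.DataFrame,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 8),
    axis: int = 0,
) -> ClusterResult:
    """Average-linkage hierarchical clustering on correlation distance.

    With ``k`` fixed, cuts the tree there; otherwise selects k in
    ``k_range`` by maximum mean silhouette (computed on the same distance).
    """
    data = matrix.values if axis == 0 else matrix.values.T
    index = matrix.index if axis == 0 else matrix.columns
    n = data.shape[0]
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds {n} items")
    d = correlation_distance(data)
    link = hierarchy.average(squareform(d, checks=False))
    sil: dict[int, float] = {}
    if k is None:
        lo, hi = k_range
        hi = min(hi, n - 1)
        best_k, best_s = lo, -np.inf
        for kk in range(lo, hi + 1):
            lab = hierarchy.fcluster(link, kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(d, lab, metric="precomputed")
            sil[kk] = float(s)
            if s > best_s + 1e-12:
                best_k, best_s = kk, s
        k = best_k
    labels = hierarchy.fcluster(link, k, criterion="maxclust")
    # relabel contiguously from 1 in order of first appearance
    remap, out = {}, []
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out.append(remap[lab])
    return ClusterResult(
        labels=pd.Series(out, index=index), k=int(k), silhouette=sil, linkage=link
    )


def pca_samples(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the sample (column) vectors after row-centering.

    Returns (coordinates indexed by sample, explained variance ratios).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    centered, _ = center_rows(matrix, scale=False)
    n_components = min(n_components, matrix.shape[1] - 1, matrix.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(centered.values.T)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def k_medoids(d: np.ndarray, k: int) -> np.ndarray:
    """Deterministic PAM on a precomputed distance matrix (BUILD + swap)."""
    n = d.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} items")
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        gains = np.array(
            [np.maximum(cur - d[:, j], 0.0).sum() if j not in medoids else -1.0
             for j in range(n)]
        )
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    for _ in range(100):
        assign = np.argmin(d[:, medoids], axis=1)
        cost = d[np.arange(n), np.array(medoids)[assign]].sum()
        best = (cost, None)
        for mi in range(k):
            for j in range(n):
                if j in medoids:
                    continue
                trial = sorted(medoids[:mi] + [j] + medoids[mi + 1 :])
                a = np.argmin(d[:, trial], axis=1)
                c = d[np.arange(n), np.array(trial)[a]].sum()
                if c < best[0] - 1e-12:
                    best = (c, trial)
        if best[1] is None:
            break
        medoids = best[1]
    assign = np.argmin(d[:, medoids], axis=1)
    return assign


def cluster_samples_pca(
    matrix: pd.DataFrame,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 8),
    n_components: int = 2,
) -> ClusterResult:
    """k-medoids on the leading PCs of the samples, k by silhouette."""
    coords, _ = pca_samples(matrix, n_components=n_components)
    x = coords.values
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    sil: dict[int, float] = {}
    if k is None:
        lo, hi = k_range
        hi = min(hi, x.shape[0] - 1)
        best_k, best_s = lo, -np.inf
        for kk in range(lo, hi + 1):
            lab = k_medoids(d, kk)
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(d, lab, metric="precomputed")
            sil[kk] = float(s)
            if s > best_s + 1e-12:
                best_k, best_s = kk, s
        k = best_k
    lab = k_medoids(d, k)
    remap, out = {}, []
    for l in lab:
        if l not in remap:
            remap[l] = len(remap) + 1
        out.append(remap[l])
    return ClusterResult(labels=pd.Series(out, index=matrix.columns), k=int(k), silhouette=sil)


# ---------------------------------------------------------------------------
# stage-specific / conserved elements


def stage_specific_elements(
    matrix: pd.DataFrame,
    design: dict[str, list],
    fc: float = 1.5,
) -> dict[str, list]:
    """Elements more accessible/expressed in one stage than in every other.

    ``matrix`` holds linear-scale normalized values (elements x columns);
    ``design`` maps stage name -> list of its columns. An element is
    stage-S-specific iff mean(S) / max over other stages of mean > fc.
    """
    if fc <= 0:
        raise ValueError("fc must be positive")
    for stage, cols in design.items():
        if not cols:
            raise ValueError(f"stage {stage!r} has no columns")
    means = pd.DataFrame(
        {stage: matrix[cols].mean(axis=1) for stage, cols in design.items()}
    )
    out: dict[str, list] = {}
    for stage in design:
        others = means.drop(columns=stage).max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = means[stage] / others
        out[stage] = list(matrix.index[ratio > fc])
    return out


def conservative_elements(
    matrix: pd.DataFrame,
    design: dict[str, list],
    min_signal: float | None = None,
) -> list:
    """Elements whose stage-mean signal reaches min_signal at every stage.

    When ``min_signal`` is None, the 25th percentile of all element-stage
    means is used.
    """
    means = pd.DataFrame(
        {stage: matrix[cols].mean(axis=1) for stage, cols in design.items()}
    )
    if min_signal is None:
        min_signal = float(np.percentile(means.values, 25))
    if min_signal < 0:
        raise ValueError("min_signal must be >= 0")
    ok = (means >= min_signal).all(axis=1)
    return list(matrix.index[ok])


def default_stage_design(meta: pd.DataFrame, boundaries: tuple[int, int] = (21, 28)) -> dict[str, list]:
    """Map samples to early/interim/late stages by day cutoffs (inclusive)."""
    early_end, interim_end = boundaries
    design: dict[str, list] = {"early": [], "interim": [], "late": []}
    for sample, row in meta.iterrows():
        d = row["timepoint"]
        if d <= early_end:
            design["early"].append(sample)
        elif d <= interim_end:
            design["interim"].append(sample)
        else:
            design["late"].append(sample)
    return {k: v for k, v in design.items() if v}
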