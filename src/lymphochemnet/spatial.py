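"""Spatial analysis of segmented cell tables.

Neighborhood detection follows the multiplexed-imaging workflow: each
cell's k=20 nearest neighbors define a cell-type composition vector,
compositions are clustered with k-means (k=20), redundant clusters with
similar centroid compositions are merged, and cell-type enrichment per
merged neighborhood is reported as log2 odds ratios with Fisher tests.
Transcript-bearing tables additionally support the QC filter
(>50 transcripts/cell), a 20-μm-radius ligand–receptor proximity score,
Otsu marker positivity, and a KDE-based chemoattraction test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import fisher_exact, ranksums
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError

logger = logging.getLogger(__name__)


def qc_filter_cells(t: pd.DataFrame, min_transcripts: int = 50) -> pd.DataFrame:
    """Keep cells with total_transcripts strictly above the threshold."""
    if "total_transcripts" not in t.columns:
        raise ValidationError("spatial table lacks total_transcripts")
    kept = t[t["total_transcripts"] > min_transcripts].reset_index(drop=True)
    if kept.empty:
        logger.warning("QC filter removed every cell")
    return kept


def neighbor_composition(t: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Cell-type frequency vector of each cell's k nearest neighbors.

    Euclidean distance on μm coordinates, self excluded; ties at the k-th
    neighbor resolve by table order (deterministic). Rows sum to 1.
    """
    n = len(t)
    if n < k + 1:
        raise ValidationError(f"need ≥ {k + 1} cells for k={k} neighbors")
    xy = t[["x_um", "y_um"]].to_numpy(float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(xy)
    _, idx = nn.kneighbors(xy)
    neighbor_idx = idx[:, 1:]  # drop self
    types = t["cell_type"].to_numpy()
    all_types = sorted(pd.unique(types))
    type_code = {ty: i for i, ty in enumerate(all_types)}
    codes = np.vectorize(type_code.__getitem__)(types)
    comp = np.zeros((n, len(all_types)))
    for j in range(k):
        np.add.at(comp, (np.arange(n), codes[neighbor_idx[:, j]]), 1.0)
    comp /= k
    return pd.DataFrame(comp, columns=all_types, index=t["cell_id"].to_numpy())


def cluster_neighborhoods(
    comp: pd.DataFrame, k_clusters: int = 20, seed: int = 0, n_init: int = 10
) -> Tuple[np.ndarray, float]:
    """K-means over composition vectors; returns labels and inertia."""
    if len(comp) < k_clusters:
        raise ValidationError("fewer composition rows than clusters")
    km = KMeans(n_clusters=k_clusters, random_state=seed, n_init=n_init)
    labels = km.fit_predict(comp.to_numpy(float))
    return labels, float(km.inertia_)


def merge_similar_clusters(
    labels: np.ndarray,
    comp: pd.DataFrame,
    similarity_threshold: float = 0.8,
) -> Tuple[np.ndarray, Dict[int, int]]:
    """Agglomerative merge of clusters with correlated centroid compositions.

    Repeatedly merges the cluster pair with the highest centroid Pearson
    correlation ≥ threshold (recomputing centroids after each merge) until
    no pair qualifies. Returns merged labels (0..m-1, ordered by smallest
    original member) and the raw→merged mapping.
    """
    X = comp.to_numpy(float)
    groups = {int(l): [int(l)] for l in np.unique(labels)}

    def centroid(members):
        mask = np.isin(labels, members)
        return X[mask].mean(axis=0)

    while True:
        keys = sorted(groups)
        if len(keys) < 2:
            break
        cents = {k: centroid(groups[k]) for k in keys}
        best: Optional[Tuple[float, int, int]] = None
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                ca, cb = cents[a], cents[b]
                if ca.std() == 0 or cb.std() == 0:
                    r = 1.0 if np.allclose(ca, cb) else 0.0
                else:
                    r = float(np.corrcoef(ca, cb)[0, 1])
                if r >= similarity_threshold and (best is None or r > best[0]):
                    best = (r, a, b)
        if best is None:
            break
        _, a, b = best
        groups[a].extend(groups[b])
        del groups[b]

    mapping: Dict[int, int] = {}
    for new_id, key in enumerate(sorted(groups)):
        for raw in groups[key]:
            mapping[raw] = new_id
    merged = np.vectorize(mapping.__getitem__)(labels.astype(int))
    logger.info("merged %d raw clusters into %d", len(np.unique(labels)), len(groups))
    return merged, mapping


def enrichment_matrix(labels: np.ndarray, t: pd.DataFrame) -> pd.DataFrame:
    """Cell-type enrichment per neighborhood: log2 odds ratio + Fisher p.

    2×2 table per (neighborhood, type): membership × identity. Haldane–
    Anscombe 0.5 correction is applied to the odds ratio only when a cell
    of the table is zero; p-values are two-sided Fisher, BH-adjusted across
    the whole matrix.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("need ≥ 2 neighborhoods for enrichment")
    types = t["cell_type"].to_numpy()
    rows = []
    for nh in np.unique(labels):
        in_nh = labels == nh
        for ty in sorted(pd.unique(types)):
            is_ty = types == ty
            a = int(np.sum(in_nh & is_ty))
            b = int(np.sum(in_nh & ~is_ty))
            c = int(np.sum(~in_nh & is_ty))
            d = int(np.sum(~in_nh & ~is_ty))
            if min(a, b, c, d) == 0:
                orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
            else:
                orr = (a * d) / (b * c)
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {
                    "neighborhood": nh,
                    "cell_type": ty,
                    "log2_or": float(np.log2(orr)),
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def otsu_positivity(values, n_bins: int = 256) -> Tuple[np.ndarray, float]:
    """Marker positivity via Otsu's between-class-variance threshold."""
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValidationError("Otsu thresholding needs ≥ 2 distinct values")
    thr = float(threshold_otsu(values, nbins=n_bins))
    return values > thr, thr


def positivity_from_transcripts(
    t: pd.DataFrame,
    gene: str,
    normalized: bool = False,
    threshold: float = 2.0,
) -> np.ndarray:
    """Per-cell positivity for a gene column (``tx_<gene>``).

    Raw counts: positive ⇔ count ≥ 1. Normalized expression: positive ⇔
    value > threshold (default 2).
    """
    col = f"tx_{gene}"
    if col not in t.columns:
        raise ValidationError(f"no transcript column for gene {gene!r}")
    v = t[col].to_numpy(float)
    return v > threshold if normalized else v >= 1


def lr_proximity_score(
    t: pd.DataFrame,
    ligand_pos: np.ndarray,
    receptor_pos: np.ndarray,
    radius_um: float = 20.0,
) -> np.ndarray:
    """Radius-based ligand–receptor proximity score per cell.

    score(c) counts neighbors d within the radius such that c is ligand+
    and d receptor+, or c is receptor+ and d ligand+. Each qualifying
    orientation of a neighbor pair contributes once to each involved cell.
    """
    if radius_um <= 0:
        raise ValidationError("radius must be > 0")
    ligand_pos = np.asarray(ligand_pos, dtype=bool)
    receptor_pos = np.asarray(receptor_pos, dtype=bool)
    if len(ligand_pos) != len(t) or len(receptor_pos) != len(t):
        raise ValidationError("positivity vectors must align with the table")
    xy = t[["x_um", "y_um"]].to_numpy(float)
    tree = cKDTree(xy)
    scores = np.zeros(len(t), dtype=int)
    for i, j in tree.query_pairs(radius_um):
        hit = (ligand_pos[i] and receptor_pos[j]) or (
            ligand_pos[j] and receptor_pos[i]
        )
        if hit:
            scores[i] += 1
            scores[j] += 1
    return scores


def silverman_bandwidth(xy: np.ndarray) -> float:
    """Scalar Silverman bandwidth for a 2-D point set: mean per-dim
    σ · n^(−1/6)."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    sigma = xy.std(axis=0, ddof=1).mean()
    return float(sigma * n ** (-1.0 / 6.0)) if sigma > 0 else 1.0


def kde_density(targets_xy: np.ndarray, eval_xy: np.ndarray, bandwidth: float) -> np.ndarray:
    """Fixed-bandwidth 2-D Gaussian KDE of targets, evaluated at points.

    density(p) = (1 / (n · 2πh²)) Σ_i exp(−‖p − t_i‖² / (2h²)); a single
    target evaluated at itself gives 1/(2πh²).
    """
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be > 0")
    targets_xy = np.atleast_2d(np.asarray(targets_xy, dtype=float))
    eval_xy = np.atleast_2d(np.asarray(eval_xy, dtype=float))
    d2 = (
        ((eval_xy[:, None, :] - targets_xy[None, :, :]) ** 2).sum(axis=2)
        if len(targets_xy) * len(eval_xy) < 4_000_000
        else None
    )
    if d2 is None:
        from scipy.spatial.distance import cdist

        d2 = cdist(eval_xy, targets_xy, "sqeuclidean")
    kern = np.exp(-d2 / (2 * bandwidth**2))
    return kern.mean(axis=1) / (2 * np.pi * bandwidth**2)


@dataclass
class KdeAttractionResult:
    densities_pos: np.ndarray
    densities_neg: np.ndarray
    statistic: float
    p: float
    bandwidth: float


def kde_attraction_test(
    targets_xy: np.ndarray,
    senders_xy: np.ndarray,
    sender_ligand_pos: np.ndarray,
    bandwidth_um: Optional[float] = None,
) -> KdeAttractionResult:
    """Do ligand+ senders sit in regions dense in target (receptor+) cells?

    A Gaussian KDE of target coordinates is interpolated at ligand-positive
    and ligand-negative sender positions; the two density samples are
    compared with a two-sided Wilcoxon rank-sum test.
    """
    targets_xy = np.atleast_2d(np.asarray(targets_xy, dtype=float))
    senders_xy = np.atleast_2d(np.asarray(senders_xy, dtype=float))
    sender_ligand_pos = np.asarray(sender_ligand_pos, dtype=bool)
    if len(targets_xy) < 5:
        raise ValidationError("need ≥ 5 target cells for a stable KDE")
    if sender_ligand_pos.all() or not sender_ligand_pos.any():
        raise ValidationError("both ligand+ and ligand− sender groups must be non-empty")
    h = bandwidth_um if bandwidth_um is not None else silverman_bandwidth(targets_xy)
    dens = kde_density(targets_xy, senders_xy, h)
    pos, neg = dens[sender_ligand_pos], dens[~sender_ligand_pos]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = ranksums(pos, neg)
    return KdeAttractionResult(pos, neg, float(stat), float(p), h)
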