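"""Embedding, clustering and summaries of the cell-pair feature matrix.

The geometric-mean attraction scores are treated as features of each
directed cell pair: PCA to 20 components (centered, not re-scaled), a
cosine k-nearest-neighbor graph (k=30) on the PC coordinates, a UMAP layout
of that graph, and Leiden community detection on it. The diffuseness score
summarizes per-patient heterogeneity as the mean Euclidean distance between
pair vectors in PC space after downsampling pairs to a fixed fraction (30%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import pearsonr
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datatypes import (
    AnalysisConfig,
    CellAnnotationTable,
    PairFeatureMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

ZONE_FOLLICLE = "follicle-like"
ZONE_TZONE = "t-zone-like"
ZONE_INFLAMMATORY = "inflammatory"
ZONE_UNASSIGNED = "unassigned"


@dataclass
class PairEmbedding:
    """PCA coordinates, kNN graph, optional 2-D layout and cluster labels."""

    pairs: pd.DataFrame
    pc_coords: np.ndarray
    knn_indices: np.ndarray  # (n, k) including self in column 0
    knn_dists: np.ndarray
    umap_coords: Optional[np.ndarray] = None
    cluster: Optional[np.ndarray] = None
    zone_annotation: Dict[int, str] = field(default_factory=dict)
    cluster_top_pair: Dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def embed_pairs(
    m: PairFeatureMatrix,
    cfg: AnalysisConfig,
    compute_layout: bool = True,
) -> PairEmbedding:
    """PCA + cosine kNN graph (+ UMAP layout) of the filtered pair matrix."""
    X = m.scores.to_numpy(dtype=float)
    n, n_cols = X.shape
    n_pcs = min(cfg.n_pcs, n_cols)
    if n < n_pcs + 1:
        raise ValidationError(
            f"{n} pairs is too few for {n_pcs} principal components; "
            "reduce n_pcs or provide more pairs"
        )
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=cfg.seed)
    pcs = pca.fit_transform(X)

    k = min(cfg.knn, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1, metric=cfg.pair_metric)
    nn.fit(pcs)
    knn_dists, knn_indices = nn.kneighbors(pcs)

    umap_coords = None
    if compute_layout:
        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_neighbors=k + 1,
                metric=cfg.pair_metric,
                random_state=cfg.seed,
                precomputed_knn=(knn_indices, knn_dists),
            )
            umap_coords = np.asarray(reducer.fit_transform(pcs), dtype=float)

    return PairEmbedding(
        pairs=m.pairs.copy(),
        pc_coords=pcs,
        knn_indices=knn_indices,
        knn_dists=knn_dists,
        umap_coords=umap_coords,
    )


def _knn_igraph(e: PairEmbedding) -> igraph.Graph:
    n, k = e.knn_indices.shape
    src = np.repeat(np.arange(n), k - 1)
    dst = e.knn_indices[:, 1:].ravel()
    w = 1.0 - e.knn_dists[:, 1:].ravel()  # cosine similarity weights
    w = np.clip(w, 1e-9, None)
    g = igraph.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())), directed=False)
    g.es["weight"] = w.tolist()
    g.simplify(combine_edges="max")
    return g


def cluster_pairs(
    e: PairEmbedding, resolution: float = 0.1, seed: int = 0
) -> PairEmbedding:
    """Leiden community detection on the cosine kNN graph.

    The default resolution is deliberately coarse: attraction-potential
    features are few and strongly structured, and the biological unit of
    interest is the zone-level interaction program, not fine-grained
    expression flicker.
    """
    g = _knn_igraph(e)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    e.cluster = np.asarray(part.membership, dtype=int)
    return e


@dataclass
class CompositionSummary:
    """Per-cluster sender/receiver cell-type frequency tables.

    ``sender``/``receiver`` are the full tables (clusters × cell types,
    rows sum to 1); the ``*_display`` copies blank contributions below the
    display percentile, mirroring how minor contributions are hidden in
    alluvial representations without altering the stored data.
    """

    sender: pd.DataFrame
    receiver: pd.DataFrame
    sender_display: pd.DataFrame
    receiver_display: pd.DataFrame


def _frequency_table(labels: np.ndarray, types: pd.Series) -> pd.DataFrame:
    df = pd.DataFrame({"cluster": labels, "cell_type": types.to_numpy()})
    tab = pd.crosstab(df["cluster"], df["cell_type"])
    return tab.div(tab.sum(axis=1), axis=0)


def _display_filter(tab: pd.DataFrame, percentile: float) -> pd.DataFrame:
    out = tab.copy()
    for idx, row in tab.iterrows():
        pos = row[row > 0]
        if pos.empty:
            continue
        cut = np.percentile(pos.to_numpy(), percentile)
        out.loc[idx, row < cut] = np.nan
    return out


def summarize_composition(
    e: PairEmbedding,
    cells: CellAnnotationTable,
    display_percentile: float = 50.0,
) -> CompositionSummary:
    """Sender and receiver cell-type frequencies per pair cluster."""
    if e.cluster is None:
        raise ValidationError("clusters not assigned; run cluster_pairs first")
    type_of = dict(zip(cells.table["cell_id"], cells.table["cell_type"]))
    for role in ("sender", "receiver"):
        unknown = set(e.pairs[role]) - type_of.keys()
        if unknown:
            raise ValidationError(f"unknown {role} cell ids: {sorted(unknown)[:5]}")
    sender = _frequency_table(e.cluster, e.pairs["sender"].map(type_of))
    receiver = _frequency_table(e.cluster, e.pairs["receiver"].map(type_of))
    return CompositionSummary(
        sender,
        receiver,
        _display_filter(sender, display_percentile),
        _display_filter(receiver, display_percentile),
    )


def annotate_clusters(e: PairEmbedding, m: PairFeatureMatrix) -> Dict[int, str]:
    """Label each cluster by its dominant (top-mean) ligand–receptor pair.

    Clusters dominated by CXCL13–CXCR5 are follicle-like, by CCL19/CCL21–CCR7
    T-zone-like, by CXCL9/10/11 inflammatory; all-zero clusters are
    unassigned. Ties break lexicographically (logged).
    """
    if e.cluster is None:
        raise ValidationError("clusters not assigned; run cluster_pairs first")
    means = m.scores.groupby(e.cluster).mean()
    annotations: Dict[int, str] = {}
    top_pairs: Dict[int, str] = {}
    for cl, row in means.iterrows():
        if (row == 0).all():
            annotations[cl] = ZONE_UNASSIGNED
            top_pairs[cl] = ""
            continue
        best = row.max()
        tied = sorted(row.index[row == best])
        if len(tied) > 1:
            logger.info("cluster %s: tie among %s, lexicographic pick", cl, tied)
        top = tied[0]
        top_pairs[cl] = top
        ligand, receptor = top.split("--")
        if (ligand, receptor) == ("CXCL13", "CXCR5"):
            annotations[cl] = ZONE_FOLLICLE
        elif ligand in ("CCL19", "CCL21") and receptor == "CCR7":
            annotations[cl] = ZONE_TZONE
        elif ligand in ("CXCL9", "CXCL10", "CXCL11"):
            annotations[cl] = ZONE_INFLAMMATORY
        else:
            annotations[cl] = f"other:{top}"
    e.zone_annotation = annotations
    e.cluster_top_pair = top_pairs
    return annotations


def mean_pairwise_distance(X: np.ndarray, block: int = 2048) -> float:
    """Exact mean Euclidean distance over all unordered point pairs,
    computed blockwise so large groups never materialize the full matrix."""
    n = len(X)
    if n < 2:
        raise ValidationError("need ≥ 2 points")
    total = 0.0
    for i0 in range(0, n, block):
        a = X[i0 : i0 + block]
        if len(a) > 1:
            total += float(pdist(a).sum())
        for j0 in range(i0 + block, n, block):
            total += float(cdist(a, X[j0 : j0 + block]).sum())
    return total / (n * (n - 1) / 2)


def diffuseness(
    e: PairEmbedding,
    groups: pd.DataFrame,
    fraction: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-patient mean pair-to-pair Euclidean distance in PC space.

    ``groups`` must align with the embedding rows and carry ``patient`` and
    ``entity`` columns. Pairs are downsampled to ``fraction`` per patient
    before the exact all-pairs mean distance; patients reduced below 2 pairs
    are skipped with a warning.
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    if len(groups) != len(e):
        raise ValidationError("groups must align with embedding rows")
    rng = np.random.default_rng(seed)
    records = []
    for (patient, entity), idx in sorted(
        groups.groupby(["patient", "entity"]).groups.items()
    ):
        rows = np.asarray(idx)
        n_sub = int(round(fraction * len(rows)))
        if n_sub < 2:
            logger.warning("patient %s: <2 pairs after downsampling, skipped", patient)
            continue
        chosen = rng.choice(rows, size=n_sub, replace=False)
        score = mean_pairwise_distance(e.pc_coords[chosen])
        records.append(
            {
                "patient": patient,
                "entity": entity,
                "score": score,
                "n_pairs": n_sub,
                "fraction": fraction,
            }
        )
    return pd.DataFrame(records)


def entity_contribution(e: PairEmbedding, groups: pd.DataFrame) -> pd.DataFrame:
    """Entity fractions per cluster, normalized by entity totals.

    Raw per-cluster entity counts are divided by each entity's total pair
    count before renormalizing to 1 per cluster, so differently sized
    entities contribute on equal footing.
    """
    if e.cluster is None:
        raise ValidationError("clusters not assigned; run cluster_pairs first")
    if len(groups) != len(e):
        raise ValidationError("groups must align with embedding rows")
    counts = pd.crosstab(e.cluster, groups["entity"].to_numpy())
    weighted = counts.div(counts.sum(axis=0), axis=1)
    return weighted.div(weighted.sum(axis=1), axis=0)


def _scale(v: np.ndarray, method: str) -> np.ndarray:
    if method == "minmax":
        rng_ = v.max() - v.min()
        return (v - v.min()) / rng_ if rng_ > 0 else np.zeros_like(v)
    if method == "z":
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    raise ValidationError(f"unknown scaling {method!r}")


@dataclass
class ConcordanceResult:
    per_zone: pd.DataFrame
    unmatched_insilico: List[str]
    unmatched_spatial: List[str]


def concordance_with_spatial(
    insilico: pd.DataFrame,
    spatial: pd.DataFrame,
    scaling: str = "minmax",
) -> ConcordanceResult:
    """Compare in-silico interaction composition with spatial neighborhoods.

    Both inputs are zone-label × cell-type frequency tables. For each shared
    zone label the two frequency vectors (over shared cell types) are
    min–max scaled (or z-scaled) and their Pearson correlation reported.
    """
    shared_zones = sorted(set(insilico.index) & set(spatial.index))
    if not shared_zones:
        raise ValidationError("no shared zone labels between the two tables")
    shared_types = sorted(set(insilico.columns) & set(spatial.columns))
    if len(shared_types) < 3:
        raise ValidationError("fewer than 3 shared cell types")
    rows = []
    for zone in shared_zones:
        a = _scale(insilico.loc[zone, shared_types].to_numpy(float), scaling)
        b = _scale(spatial.loc[zone, shared_types].to_numpy(float), scaling)
        r, p = pearsonr(a, b)
        rows.append({"zone": zone, "pearson_r": r, "p": p})
    return ConcordanceResult(
        per_zone=pd.DataFrame(rows),
        unmatched_insilico=sorted(set(insilico.index) - set(spatial.index)),
        unmatched_spatial=sorted(set(spatial.index) - set(insilico.index)),
    )
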