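"""Core domain types shared by all analysis stages.

The containers here are deliberately thin: a gene × cell expression matrix
with explicit ids and a normalization flag, a per-cell annotation table, a
curated chemokine ligand→receptor registry, and the analysis configuration
holding every tunable constant of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

ENTITIES = ("rLN", "FL", "DLBCL")

#: Chemokines maintaining B/T zonation of the lymph node.
HOMEOSTATIC_CHEMOKINES = frozenset({"CXCL12", "CXCL13", "CCL19", "CCL21"})
#: IFN-inducible ligands of CXCR3.
INFLAMMATORY_CHEMOKINES = frozenset({"CXCL9", "CXCL10", "CXCL11"})


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class FormatError(ValueError):
    """File content is inconsistent with its declared format."""


@dataclass
class GeneExpressionMatrix:
    """Dense gene × cell expression matrix.

    ``normalized`` distinguishes raw UMI counts (False) from log-normalized
    expression (True); several stages require one or the other and refuse
    the wrong kind.
    """

    values: np.ndarray
    gene_ids: List[str]
    cell_ids: List[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if self.values.ndim != 2:
            raise ValidationError("expression matrix must be 2-D")
        n_g, n_c = self.values.shape
        if n_g != len(self.gene_ids) or n_c != len(self.cell_ids):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids × {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != n_g:
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_c:
            raise ValidationError("duplicate cell ids")
        if np.any(self.values < 0):
            raise ValidationError("negative expression entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([idx[g] for g in genes], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_cells(self, cell_ids: Sequence[str]) -> "GeneExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        cols = np.array([idx[c] for c in cell_ids], dtype=int)
        return GeneExpressionMatrix(
            self.values[:, cols], list(self.gene_ids), list(cell_ids), self.normalized
        )


@dataclass
class CellAnnotationTable:
    """Per-cell metadata: sample, disease entity, cell type, compartment."""

    table: pd.DataFrame

    REQUIRED = ("cell_id", "sample_id", "entity", "cell_type", "compartment")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation table missing columns: {missing}")
        if self.table["cell_id"].duplicated().any():
            raise ValidationError("duplicate cell_id in annotation table")
        bad = set(self.table["entity"]) - set(ENTITIES)
        if bad:
            raise ValidationError(f"unknown entities: {sorted(bad)}")
        if (self.table["cell_type"].astype(str) == "").any():
            raise ValidationError("empty cell_type")
        self.table = self.table.reset_index(drop=True)

    def validate_against(self, expr: GeneExpressionMatrix) -> None:
        missing = set(self.table["cell_id"]) - set(expr.cell_ids)
        if missing:
            raise ValidationError(
                f"{len(missing)} annotated cells absent from expression matrix"
            )

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.table[self.table["sample_id"] == sample_id]

    @property
    def samples(self) -> List[str]:
        return list(pd.unique(self.table["sample_id"]))


@dataclass
class LigandReceptorRegistry:
    """Curated chemokine ligand → receptor pairs with a class per ligand.

    Pairs are ordered (ligand, receptor) tuples; one ligand may bind several
    receptors. Ligand classes follow the lymph-node zonation literature:
    homeostatic (CXCL12/CXCL13/CCL19/CCL21), inflammatory (CXCL9/10/11),
    everything else "other".
    """

    pairs: List[Tuple[str, str]]
    class_of: Dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("duplicate ligand–receptor pairs")
        for lig, cls in self.class_of.items():
            if cls not in ("homeostatic", "inflammatory", "other"):
                raise ValidationError(f"unknown ligand class {cls!r} for {lig}")

    @property
    def ligands(self) -> List[str]:
        return [l for l, _ in self.pairs]

    @property
    def receptors(self) -> List[str]:
        return [r for _, r in self.pairs]

    @property
    def labels(self) -> List[str]:
        return [f"{l}--{r}" for l, r in self.pairs]

    def class_of_pair(self, label: str) -> str:
        ligand = label.split("--")[0]
        return self.class_of.get(ligand, "other")

    def subset_to_genes(self, genes: Sequence[str]) -> "LigandReceptorRegistry":
        """Drop pairs whose ligand or receptor is absent from ``genes``."""
        gene_set = set(genes)
        kept = [(l, r) for l, r in self.pairs if l in gene_set and r in gene_set]
        return LigandReceptorRegistry(kept, dict(self.class_of))


@dataclass
class GeneSignature:
    """Named gene set used for per-cell / per-sample signature scoring."""

    name: str
    genes: frozenset
    sig_class: str = "custom"

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValidationError("empty gene signature")


HOMEOSTATIC_SIGNATURE = GeneSignature(
    "homeostatic", HOMEOSTATIC_CHEMOKINES, "homeostatic"
)
INFLAMMATORY_SIGNATURE = GeneSignature(
    "inflammatory", INFLAMMATORY_CHEMOKINES, "inflammatory"
)


@dataclass
class AnalysisConfig:
    """Every tunable constant of the pipeline, with field defaults equal to
    the published analysis settings.

    min_lr_pairs: minimum strictly positive ligand–receptor entries per
        retained cell pair (4).
    n_pcs / knn / pair_metric: pair-space embedding (20 PCs, 30 neighbors,
        cosine).
    diffuseness_fraction: pair downsampling fraction before the mean-distance
        diffuseness score (0.3).
    nhood_k / nhood_kmeans_k: spatial neighborhood composition (k=20
        neighbors) and its k-means clustering (k=20).
    lr_radius_um: radius of the spatial ligand–receptor proximity score
        (20 μm).
    positivity_threshold: normalized-expression positivity cutoff (2).
    min_transcripts: per-cell transcript QC threshold, strict > (50).
    clonal_threshold: clonotype size above which a clone is expanded (7).
    """

    min_lr_pairs: int = 4
    n_pcs: int = 20
    knn: int = 30
    pair_metric: str = "cosine"
    diffuseness_fraction: float = 0.3
    nhood_k: int = 20
    nhood_kmeans_k: int = 20
    lr_radius_um: float = 20.0
    positivity_threshold: float = 2.0
    min_transcripts: int = 50
    clonal_threshold: int = 7
    norm_scale: float = 10_000.0
    downsample_per_type: int = 100
    merge_correlation: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "min_lr_pairs n_pcs knn diffuseness_fraction nhood_k nhood_kmeans_k "
            "lr_radius_um positivity_threshold min_transcripts clonal_threshold "
            "norm_scale downsample_per_type"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name} must be > 0")
        if not (0 < self.diffuseness_fraction <= 1):
            raise ValidationError("diffuseness_fraction must be in (0, 1]")

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


@dataclass
class PairFeatureMatrix:
    """Directed cell-pair × ligand–receptor-pair attraction potentials.

    ``pairs`` holds one row per directed (sender, receiver) combination with
    its sample id; ``scores`` is the aligned numeric block whose columns are
    "LIGAND--RECEPTOR" labels and whose entries are geometric-mean scores.
    """

    pairs: pd.DataFrame  # columns: sender, receiver, sample_id
    scores: pd.DataFrame  # columns: L--R labels

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.scores):
            raise ValidationError("pairs and scores row counts differ")
        if (self.scores.values < 0).any():
            raise ValidationError("negative attraction scores")
        self.pairs = self.pairs.reset_index(drop=True)
        self.scores = self.scores.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def columns(self) -> List[str]:
        return list(self.scores.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.pairs, self.scores], axis=1)


@dataclass
class SurvivalTable:
    """Subjects with follow-up time (months), event indicator and a score."""

    table: pd.DataFrame

    REQUIRED = ("subject_id", "time", "event", "score")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"survival table missing columns: {missing}")
        t = self.table
        if (t["time"] <= 0).any():
            raise ValidationError("non-positive survival times")
        if not set(np.unique(t["event"])) <= {0, 1}:
            raise ValidationError("event must be 0/1")
        if not np.all(np.isfinite(t["score"])):
            raise ValidationError("non-finite scores")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)
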