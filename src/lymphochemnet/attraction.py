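"""Cell-pair chemokine attraction potentials.

For every ordered pair of distinct cells within a sample and every
ligand–receptor pair (l, r) in the registry, the attraction potential is
the geometric mean of ligand expression in the sender and receptor
expression in the receiver: sqrt(expr_sender(l) · expr_receiver(r)),
computed on log-normalized expression. Cell pairs supported by fewer than
``min_lr_pairs`` strictly positive ligand–receptor entries are discarded,
and samples are processed individually before being merged — cross-sample
pairs are never formed.

The all-pairs construction is quadratic in cells per sample;
``downsample_per_type`` caps each cell type at a seeded random subset to
keep desk-scale problems tractable.
"""

from __future__ import annotations

import logging
from typing import List, Optional

import numpy as np
import pandas as pd

from .datatypes import (
    CellAnnotationTable,
    GeneExpressionMatrix,
    LigandReceptorRegistry,
    PairFeatureMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)


def compute_attraction(
    expr: GeneExpressionMatrix,
    cells: CellAnnotationTable,
    registry: LigandReceptorRegistry,
    sample_id: str,
    downsample_per_type: Optional[int] = None,
    seed: int = 0,
    include_self: bool = False,
) -> PairFeatureMatrix:
    """Geometric-mean attraction scores for all ordered cell pairs of one sample."""
    if not expr.normalized:
        raise ValidationError("attraction requires log-normalized expression")
    reg = registry.subset_to_genes(expr.gene_ids)
    dropped = len(registry.pairs) - len(reg.pairs)
    if dropped:
        logger.warning(
            "%d/%d registry pairs dropped (genes absent from matrix)",
            dropped, len(registry.pairs),
        )
    if not reg.pairs:
        raise ValidationError("no registry gene present in the expression matrix")

    sample = cells.for_sample(sample_id)
    if len(sample) < 2:
        raise ValidationError(f"sample {sample_id!r} has fewer than 2 cells")

    cell_ids = sample["cell_id"].tolist()
    if downsample_per_type is not None:
        rng = np.random.default_rng(seed)
        kept: List[str] = []
        for _, grp in sample.groupby("cell_type", sort=True):
            ids = grp["cell_id"].to_numpy()
            if len(ids) > downsample_per_type:
                ids = rng.choice(ids, size=downsample_per_type, replace=False)
            kept.extend(ids)
        order = {c: i for i, c in enumerate(cell_ids)}
        cell_ids = sorted(kept, key=order.__getitem__)

    sub = expr.subset_cells(cell_ids)
    lig = sub.values[sub.gene_index(reg.ligands), :]  # k × n
    rec = sub.values[sub.gene_index(reg.receptors), :]
    n = len(cell_ids)

    sender_idx = np.repeat(np.arange(n), n)
    receiver_idx = np.tile(np.arange(n), n)
    if not include_self:
        keep = sender_idx != receiver_idx
        sender_idx, receiver_idx = sender_idx[keep], receiver_idx[keep]

    scores = np.sqrt(lig[:, sender_idx] * rec[:, receiver_idx]).T
    ids = np.asarray(cell_ids)
    pairs = pd.DataFrame(
        {
            "sender": ids[sender_idx],
            "receiver": ids[receiver_idx],
            "sample_id": sample_id,
        }
    )
    return PairFeatureMatrix(pairs, pd.DataFrame(scores, columns=reg.labels))


def filter_pairs(m: PairFeatureMatrix, min_lr_pairs: int = 4) -> PairFeatureMatrix:
    """Retain cell pairs with at least ``min_lr_pairs`` strictly positive entries."""
    if min_lr_pairs < 1:
        raise ValidationError("min_lr_pairs must be ≥ 1")
    keep = (m.scores.to_numpy() > 0).sum(axis=1) >= min_lr_pairs
    if not keep.any():
        logger.warning("filter_pairs removed every cell pair")
    return PairFeatureMatrix(m.pairs.loc[keep], m.scores.loc[keep])


def merge_samples(ms: List[PairFeatureMatrix]) -> PairFeatureMatrix:
    """Row-concatenate per-sample pair matrices, aligning columns by name."""
    if not ms:
        raise ValidationError("nothing to merge")
    ref = ms[0].columns
    for m in ms[1:]:
        if set(m.columns) != set(ref):
            diff = set(m.columns) ^ set(ref)
            raise ValidationError(f"column sets differ between samples: {sorted(diff)}")
    pairs = pd.concat([m.pairs for m in ms], ignore_index=True)
    scores = pd.concat([m.scores[ref] for m in ms], ignore_index=True)
    return PairFeatureMatrix(pairs, scores)
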