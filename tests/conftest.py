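"""Shared fixtures: tiny expression matrices, registries, planted profiles."""

import logging

import numpy as np
import pandas as pd
import pytest

from lymphochemnet import (
    AnalysisConfig,
    CellAnnotationTable,
    GeneExpressionMatrix,
    LigandReceptorRegistry,
)
from lymphochemnet.synthetic import EntityProfile

logging.getLogger("lymphochemnet").setLevel(logging.ERROR)


def make_annotations(cell_ids, sample_id="S1", entity="rLN", cell_types=None):
    n = len(cell_ids)
    types = cell_types if cell_types is not None else ["B"] * n
    return CellAnnotationTable(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "sample_id": sample_id,
                "entity": entity,
                "cell_type": types,
                "compartment": "hematopoietic",
            }
        )
    )


@pytest.fixture
def toy_registry():
    return LigandReceptorRegistry(
        pairs=[("CXCL13", "CXCR5"), ("CXCL12", "CXCR4"), ("CCL19", "CCR7")],
        class_of={"CXCL13": "homeostatic", "CXCL12": "homeostatic", "CCL19": "homeostatic"},
    )


@pytest.fixture
def random_normalized_expr():
    """20-cell × 10-gene matrix of positive log-normalized-like values."""
    rng = np.random.default_rng(11)
    genes = ["CXCL13", "CXCR5", "CXCL12", "CXCR4", "CCL19", "CCR7"] + [
        f"G{i}" for i in range(4)
    ]
    vals = rng.uniform(0, 5, size=(10, 20))
    vals[rng.uniform(size=vals.shape) < 0.3] = 0.0
    return GeneExpressionMatrix(vals, genes, [f"C{i}" for i in range(20)], normalized=True)


def planted_two_program_profile() -> EntityProfile:
    """Follicular (FDC: CXCL13→CXCR5) vs T-zone (FRC: CCL19/21→CCR7) senders
    addressing one pooled lymphocyte receiver type; programs strong enough
    that positivity flicker does not blur the two interaction modes."""
    return EntityProfile(
        entity="rLN",
        cell_type_proportions={"FDC": 0.15, "FRC": 0.15, "L": 0.70},
        chemokine_program={
            ("FDC", "CXCL13"): 10.0, ("FDC", "CXCL12"): 6.0, ("FDC", "CCL20"): 6.0,
            ("FRC", "CCL19"): 10.0, ("FRC", "CCL21"): 10.0,
            ("FRC", "CXCL12"): 6.0, ("FRC", "CCL2"): 6.0,
        },
        receptor_program={
            ("L", "CXCR5"): 8.0, ("L", "CXCR4"): 8.0, ("L", "ACKR3"): 8.0,
            ("L", "CCR6"): 8.0, ("L", "CCR7"): 8.0, ("L", "CCR2"): 8.0,
        },
        dispersion=6.0,
    )


@pytest.fixture
def default_cfg():
    return AnalysisConfig()
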