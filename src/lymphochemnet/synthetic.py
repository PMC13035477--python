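"""Synthetic lymph-node data generator.

Emulates the statistical structure the downstream analyses assume, per
disease entity:

* **rLN** (reactive lymph node): stromal cells carry the homeostatic
  chemokine programs (FDC: CXCL13; FRC: CCL19/CCL21/CXCL12), lymphocytes
  the matching receptors; tissue is organized into follicles, T zone and a
  sinus band.
* **FL** (follicular lymphoma): intermediate — homeostatic programs at ~60%
  of rLN, a small remodeled-FRC population with inflammatory chemokines at
  ~40% of DLBCL levels; follicular spatial layout preserved.
* **DLBCL** (diffuse large B cell lymphoma): remodeled FRCs with high
  inflammatory CXCL9/10/11, homeostatic ligands reduced to 20% of rLN,
  CXCR3 on cytotoxic T cells, ectopic CXCL13 in a subset of them; spatially
  diffuse (no zonation).

Counts are negative-binomial with an entity-specific dispersion; the
dispersion gradient (rLN tightest, DLBCL most overdispersed) encodes the
greater transcriptional heterogeneity of the malignant microenvironment.
All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import (
    CellAnnotationTable,
    GeneExpressionMatrix,
    HOMEOSTATIC_CHEMOKINES,
    INFLAMMATORY_CHEMOKINES,
    SurvivalTable,
    ValidationError,
)

STROMAL_TYPES = frozenset({"FDC", "FRC", "rFRC", "BEC", "LEC"})


# ---------------------------------------------------------------------------
# expression profiles


@dataclass
class EntityProfile:
    """Per-entity generative model for single-cell chemokine expression.

    ``chemokine_program`` and ``receptor_program`` map (cell_type, gene) to
    the mean count of a negative-binomial draw; ``ectopic`` maps
    (cell_type, gene) to (fraction, mean) for genes acquired by only a
    subset of a population (e.g. CXCL13 in DLBCL cytotoxic T cells).
    """

    entity: str
    cell_type_proportions: Dict[str, float]
    chemokine_program: Dict[Tuple[str, str], float]
    receptor_program: Dict[Tuple[str, str], float]
    dispersion: float
    background_genes: int = 60
    background_mean: float = 0.5
    ectopic: Dict[Tuple[str, str], Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"cell type proportions sum to {total}, expected 1"
            )
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        for prog in (self.chemokine_program, self.receptor_program):
            for (ct, gene), mean in prog.items():
                if mean < 0:
                    raise ValidationError(f"negative mean for ({ct}, {gene})")

    @property
    def cell_types(self) -> List[str]:
        return list(self.cell_type_proportions)

    @property
    def program_genes(self) -> List[str]:
        genes = {g for _, g in self.chemokine_program}
        genes |= {g for _, g in self.receptor_program}
        genes |= {g for _, g in self.ectopic}
        return sorted(genes)


def programmed_class_totals(profile: EntityProfile) -> Dict[str, float]:
    """Proportion-weighted programmed expression per chemokine class.

    Sums mean ligand levels over cell types weighted by their abundance;
    ectopic programs contribute fraction × mean. Used to assert the entity
    gradient: homeostatic rLN > FL > DLBCL, inflammatory rLN < FL < DLBCL.
    """
    totals = {"homeostatic": 0.0, "inflammatory": 0.0}
    props = profile.cell_type_proportions
    for (ct, gene), mean in profile.chemokine_program.items():
        for cls, members in (
            ("homeostatic", HOMEOSTATIC_CHEMOKINES),
            ("inflammatory", INFLAMMATORY_CHEMOKINES),
        ):
            if gene in members:
                totals[cls] += props.get(ct, 0.0) * mean
    for (ct, gene), (frac, mean) in profile.ectopic.items():
        for cls, members in (
            ("homeostatic", HOMEOSTATIC_CHEMOKINES),
            ("inflammatory", INFLAMMATORY_CHEMOKINES),
        ):
            if gene in members:
                totals[cls] += props.get(ct, 0.0) * frac * mean
    return totals


def default_profiles() -> Dict[str, EntityProfile]:
    """Bundled rLN / FL / DLBCL expression profiles."""
    rln = EntityProfile(
        entity="rLN",
        cell_type_proportions={
            "B": 0.40, "T": 0.23, "T_FH": 0.10, "T_tox": 0.12,
            "FDC": 0.05, "FRC": 0.06, "BEC": 0.02, "LEC": 0.02,
        },
        chemokine_program={
            ("FDC", "CXCL13"): 8.0, ("FDC", "CXCL12"): 3.0, ("FDC", "CCL20"): 3.0,
            ("FRC", "CCL19"): 7.0, ("FRC", "CCL21"): 7.0,
            ("FRC", "CXCL12"): 5.0, ("FRC", "CCL2"): 3.0,
            ("LEC", "CCL21"): 3.0, ("LEC", "CXCL12"): 2.0,
            ("BEC", "CXCL12"): 2.0,
            ("T_tox", "CCL3"): 1.5, ("T_tox", "CCL4"): 1.5, ("T_tox", "CCL5"): 2.0,
        },
        receptor_program={
            ("B", "CXCR5"): 6.0, ("B", "CXCR4"): 6.0, ("B", "ACKR3"): 3.0,
            ("B", "CCR7"): 2.0, ("B", "CCR6"): 3.0,
            ("T", "CCR7"): 6.0, ("T", "CXCR4"): 5.0, ("T", "CCR2"): 1.5,
            ("T_FH", "CXCR5"): 6.0, ("T_FH", "CXCR4"): 4.0, ("T_FH", "CCR7"): 2.0,
            ("T_tox", "CCR7"): 4.0, ("T_tox", "CXCR4"): 4.0,
            ("T_tox", "CXCR3"): 1.0, ("T_tox", "CCR5"): 2.0, ("T_tox", "CCR2"): 1.5,
        },
        dispersion=4.0,
    )
    fl = EntityProfile(
        entity="FL",
        cell_type_proportions={
            "B": 0.45, "T": 0.15, "T_FH": 0.14, "T_tox": 0.10,
            "FDC": 0.04, "FRC": 0.05, "rFRC": 0.02, "BEC": 0.03, "LEC": 0.02,
        },
        # homeostatic ligands at 60% of rLN; inflammatory at 40% of DLBCL
        chemokine_program={
            ("FDC", "CXCL13"): 4.8, ("FDC", "CXCL12"): 1.8, ("FDC", "CCL20"): 3.0,
            ("FRC", "CCL19"): 4.2, ("FRC", "CCL21"): 4.2,
            ("FRC", "CXCL12"): 3.0, ("FRC", "CCL2"): 3.0,
            ("rFRC", "CXCL9"): 3.2, ("rFRC", "CXCL10"): 3.2,
            ("rFRC", "CXCL11"): 2.4, ("rFRC", "CCL2"): 3.0,
            ("LEC", "CCL21"): 1.8, ("LEC", "CXCL12"): 1.2,
            ("BEC", "CXCL12"): 1.2,
            ("T_tox", "CCL3"): 1.5, ("T_tox", "CCL4"): 1.5, ("T_tox", "CCL5"): 2.0,
        },
        receptor_program={
            ("B", "CXCR5"): 6.0, ("B", "CXCR4"): 6.0, ("B", "ACKR3"): 3.0,
            ("B", "CCR7"): 2.0, ("B", "CCR6"): 3.0,
            ("T", "CCR7"): 5.0, ("T", "CXCR4"): 5.0, ("T", "CCR2"): 1.5,
            ("T_FH", "CXCR5"): 6.0, ("T_FH", "CXCR4"): 4.0, ("T_FH", "CCR7"): 2.0,
            ("T_tox", "CXCR3"): 3.0, ("T_tox", "CXCR4"): 4.0,
            ("T_tox", "CCR7"): 3.0, ("T_tox", "CCR5"): 2.0, ("T_tox", "CCR2"): 1.5,
        },
        dispersion=2.0,
    )
    dlbcl = EntityProfile(
        entity="DLBCL",
        cell_type_proportions={
            "B": 0.53, "T": 0.08, "T_FH": 0.02, "T_tox": 0.18,
            "FDC": 0.01, "FRC": 0.03, "rFRC": 0.08, "BEC": 0.04, "LEC": 0.03,
        },
        # homeostatic ligands at 20% of rLN levels; inflammatory high in rFRC
        chemokine_program={
            ("FDC", "CXCL13"): 1.6, ("FDC", "CXCL12"): 0.6, ("FDC", "CCL20"): 3.0,
            ("FRC", "CCL19"): 1.4, ("FRC", "CCL21"): 1.4,
            ("FRC", "CXCL12"): 1.0, ("FRC", "CCL2"): 3.0,
            ("rFRC", "CXCL9"): 8.0, ("rFRC", "CXCL10"): 8.0,
            ("rFRC", "CXCL11"): 6.0, ("rFRC", "CCL2"): 4.0,
            ("rFRC", "CCL19"): 1.4, ("rFRC", "CCL21"): 1.4, ("rFRC", "CXCL12"): 1.0,
            ("LEC", "CCL21"): 0.6, ("LEC", "CXCL12"): 0.4,
            ("BEC", "CXCL12"): 0.4, ("BEC", "CXCL9"): 2.0, ("BEC", "CXCL10"): 2.0,
            ("T_tox", "CCL3"): 2.0, ("T_tox", "CCL4"): 2.0, ("T_tox", "CCL5"): 3.0,
        },
        receptor_program={
            ("B", "CXCR5"): 4.0, ("B", "CXCR4"): 6.0, ("B", "ACKR3"): 2.0,
            ("B", "CCR7"): 1.0, ("B", "CCR6"): 2.0,
            ("T", "CCR7"): 4.0, ("T", "CXCR4"): 5.0, ("T", "CCR2"): 1.5,
            ("T_FH", "CXCR5"): 5.0, ("T_FH", "CXCR4"): 4.0, ("T_FH", "CCR7"): 2.0,
            ("T_tox", "CXCR3"): 6.0, ("T_tox", "CXCR4"): 4.0,
            ("T_tox", "CCR7"): 2.0, ("T_tox", "CCR5"): 3.0, ("T_tox", "CCR2"): 2.0,
        },
        dispersion=0.9,
        ectopic={("T_tox", "CXCL13"): (0.3, 4.0)},
    )
    return {"rLN": rln, "FL": fl, "DLBCL": dlbcl}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and dispersion ``theta``
    (var = m + m²/θ). Zero means yield exact zeros."""
    p = theta / (theta + np.asarray(mean, dtype=float))
    return rng.negative_binomial(theta, p)


def generate_expression(
    profile: EntityProfile,
    n_cells: int,
    seed: int,
    sample_id: Optional[str] = None,
) -> Tuple[GeneExpressionMatrix, CellAnnotationTable]:
    """Draw a raw count matrix plus annotations from an entity profile.

    Cell types are sampled from the profile proportions; program genes are
    negative-binomial with type-specific means; background genes provide
    library size. Deterministic given the seed.
    """
    if n_cells < 50:
        raise ValidationError("n_cells must be ≥ 50")
    rng = np.random.default_rng(seed)
    sample_id = sample_id or f"{profile.entity}_s{seed}"

    types = profile.cell_types
    props = np.array([profile.cell_type_proportions[t] for t in types])
    cell_types = rng.choice(types, size=n_cells, p=props)

    program_genes = profile.program_genes
    bg_genes = [f"BG{i:03d}" for i in range(1, profile.background_genes + 1)]
    genes = program_genes + bg_genes
    n_prog = len(program_genes)
    gene_pos = {g: i for i, g in enumerate(program_genes)}
    type_pos = {t: i for i, t in enumerate(types)}

    # per-type mean vector over program genes
    mean_by_type = np.zeros((len(types), n_prog))
    for prog in (profile.chemokine_program, profile.receptor_program):
        for (ct, gene), mean in prog.items():
            mean_by_type[type_pos[ct], gene_pos[gene]] += mean

    mean_matrix = mean_by_type[[type_pos[t] for t in cell_types], :].T  # genes × cells
    # ectopic programs: a seeded subset of one population gains a gene
    for (ct, gene), (frac, mean) in profile.ectopic.items():
        cells_of_type = np.flatnonzero(cell_types == ct)
        n_pos = int(round(frac * cells_of_type.size))
        chosen = rng.choice(cells_of_type, size=n_pos, replace=False)
        mean_matrix[gene_pos[gene], chosen] = mean

    counts = np.zeros((len(genes), n_cells), dtype=float)
    counts[:n_prog] = _nb_draw(rng, mean_matrix, profile.dispersion)
    counts[n_prog:] = _nb_draw(
        rng,
        np.full((len(bg_genes), n_cells), profile.background_mean),
        profile.dispersion,
    )

    cell_ids = [f"{sample_id}_C{i:05d}" for i in range(n_cells)]
    expr = GeneExpressionMatrix(counts, genes, cell_ids, normalized=False)
    ann = CellAnnotationTable(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "sample_id": sample_id,
                "entity": profile.entity,
                "cell_type": cell_types,
                "compartment": [
                    "stromal" if t in STROMAL_TYPES else "hematopoietic"
                    for t in cell_types
                ],
            }
        )
    )
    return expr, ann


# ---------------------------------------------------------------------------
# spatial layouts


DEFAULT_INTENSITY_MODEL = {
    "CD21": {"neg_mu": 1.0, "neg_sd": 0.4, "pos_mu": 2.5, "pos_sd": 0.4},
    "PDPN": {"neg_mu": 1.0, "neg_sd": 0.4, "pos_mu": 2.5, "pos_sd": 0.4},
    "CD31": {"neg_mu": 1.0, "neg_sd": 0.4, "pos_mu": 2.5, "pos_sd": 0.4},
    "CD3": {"neg_mu": 1.0, "neg_sd": 0.4, "pos_mu": 2.5, "pos_sd": 0.4},
    "CD20": {"neg_mu": 1.0, "neg_sd": 0.4, "pos_mu": 2.5, "pos_sd": 0.4},
    "CXCL13": {"neg_mu": 1.0, "neg_sd": 0.4, "pos_mu": 2.5, "pos_sd": 0.4},
}

MARKER_POSITIVE_TYPES = {
    "CD21": {"FDC"},
    "PDPN": {"FDC", "FRC", "rFRC", "LEC"},
    "CD31": {"BEC", "LEC"},
    "CD3": {"T", "T_FH", "T_tox"},
    "CD20": {"B"},
    "CXCL13": {"FDC"},
}

ZONE_COMPOSITIONS = {
    "follicle_core": {"FDC": 0.45, "B": 0.45, "T_FH": 0.10},
    "follicle": {"B": 0.75, "T_FH": 0.15, "FDC": 0.05, "FRC": 0.05},
    "t_zone": {
        "T": 0.45, "T_tox": 0.18, "FRC": 0.20,
        "B": 0.07, "BEC": 0.05, "LEC": 0.05,
    },
    "sinus": {"LEC": 0.60, "B": 0.20, "T": 0.20},
}


@dataclass
class Follicle:
    cx: float
    cy: float
    radius: float
    core_radius: float


@dataclass
class SpatialLayoutConfig:
    """Geometry and marker model for the spatial generator.

    Follicle discs (FDC-rich core ringed by B cells with T_FH admixture) sit
    in a T-zone background; an optional sinus band runs along one edge.
    ``diffuse`` mode ignores all regions and mixes every type uniformly
    (the DLBCL growth pattern).
    """

    field_size_um: Tuple[float, float] = (1000.0, 1000.0)
    follicles: List[Follicle] = field(default_factory=list)
    sinus_band: Optional[Tuple[float, float, float, float]] = None  # x0,y0,x1,y1
    diffuse: bool = False
    density_per_um2: float = 0.005
    intensity_model: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INTENSITY_MODEL.items()}
    )
    zone_compositions: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in ZONE_COMPOSITIONS.items()}
    )
    diffuse_composition: Optional[Dict[str, float]] = None
    tx_background_genes: int = 20
    tx_background_mean: float = 3.0
    quality_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.density_per_um2 <= 0:
            raise ValidationError("density must be > 0")
        w, h = self.field_size_um
        for f in self.follicles:
            if (
                f.cx - f.radius < 0 or f.cx + f.radius > w
                or f.cy - f.radius < 0 or f.cy + f.radius > h
            ):
                raise ValidationError("follicle disc outside the field")
            if f.core_radius >= f.radius:
                raise ValidationError("follicle core must be smaller than the disc")
        for marker, comp in self.intensity_model.items():
            if comp["pos_mu"] <= comp["neg_mu"]:
                raise ValidationError(
                    f"marker {marker}: positive mean must exceed negative mean"
                )


def default_layout(entity: str) -> SpatialLayoutConfig:
    """Bundled spatial layouts: zonated rLN/FL fields, diffuse DLBCL."""
    if entity == "DLBCL":
        profile = default_profiles()["DLBCL"]
        return SpatialLayoutConfig(
            diffuse=True, diffuse_composition=dict(profile.cell_type_proportions)
        )
    if entity == "FL":
        follicles = [
            Follicle(220, 260, 150, 60), Follicle(640, 220, 140, 55),
            Follicle(300, 650, 150, 60), Follicle(750, 600, 130, 50),
        ]
    else:
        follicles = [
            Follicle(250, 300, 120, 50), Follicle(700, 250, 110, 45),
            Follicle(500, 700, 130, 55),
        ]
    return SpatialLayoutConfig(
        follicles=follicles, sinus_band=(0.0, 950.0, 1000.0, 1000.0)
    )


def _zone_of(x: np.ndarray, y: np.ndarray, layout: SpatialLayoutConfig) -> np.ndarray:
    zones = np.full(x.shape, "t_zone", dtype=object)
    if layout.sinus_band is not None:
        x0, y0, x1, y1 = layout.sinus_band
        zones[(x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)] = "sinus"
    for f in layout.follicles:
        d2 = (x - f.cx) ** 2 + (y - f.cy) ** 2
        zones[d2 <= f.radius**2] = "follicle"
        zones[d2 <= f.core_radius**2] = "follicle_core"
    return zones


def generate_spatial(
    layout: SpatialLayoutConfig,
    profile: EntityProfile,
    seed: int,
) -> pd.DataFrame:
    """Homogeneous Poisson placement with zone-conditional cell types.

    Returns a segmented-cell table with μm coordinates, cell types, bimodal
    marker intensities (log-normal negative/positive components conditioned
    on type), per-gene transcript counts drawn from the entity expression
    programs, their total, and the planted ``true_zone`` label.
    """
    rng = np.random.default_rng(seed)
    w, h = layout.field_size_um
    n = rng.poisson(layout.density_per_um2 * w * h)
    x = rng.uniform(0, w, n)
    y = rng.uniform(0, h, n)

    if layout.diffuse:
        zones = np.full(n, "diffuse", dtype=object)
        comp = layout.diffuse_composition or dict(profile.cell_type_proportions)
        comps = {"diffuse": comp}
    else:
        zones = _zone_of(x, y, layout)
        comps = layout.zone_compositions

    cell_types = np.empty(n, dtype=object)
    for zone, comp in comps.items():
        mask = zones == zone
        if not mask.any():
            continue
        types = sorted(comp)
        p = np.array([comp[t] for t in types], dtype=float)
        p = p / p.sum()
        cell_types[mask] = rng.choice(types, size=int(mask.sum()), p=p)

    df = pd.DataFrame(
        {
            "cell_id": [f"SP{i:06d}" for i in range(n)],
            "x_um": x,
            "y_um": y,
            "cell_type": cell_types.astype(str),
            "true_zone": zones.astype(str),
        }
    )

    for marker, model in layout.intensity_model.items():
        pos_types = MARKER_POSITIVE_TYPES.get(marker, set())
        pos = np.isin(df["cell_type"].to_numpy(), sorted(pos_types))
        mu = np.where(pos, model["pos_mu"], model["neg_mu"])
        sd = np.where(pos, model["pos_sd"], model["neg_sd"])
        df[f"intensity_{marker}"] = np.exp(rng.normal(mu, sd))

    # transcript counts: entity program means × per-cell quality factor
    quality = np.exp(rng.normal(0.0, layout.quality_sd, n))
    type_pos = {t: i for i, t in enumerate(profile.cell_types)}
    genes = profile.program_genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    mean_by_type = np.zeros((len(profile.cell_types), len(genes)))
    for prog in (profile.chemokine_program, profile.receptor_program):
        for (ct, gene), mean in prog.items():
            mean_by_type[type_pos[ct], gene_pos[gene]] += mean
    known = np.array([type_pos.get(t, -1) for t in df["cell_type"]])
    means = np.where(
        known[:, None] >= 0, mean_by_type[known, :], 0.0
    )  # cells × genes
    for (ct, gene), (frac, mean) in profile.ectopic.items():
        cells_of_type = np.flatnonzero(df["cell_type"].to_numpy() == ct)
        n_pos = int(round(frac * cells_of_type.size))
        if n_pos:
            chosen = rng.choice(cells_of_type, size=n_pos, replace=False)
            means[chosen, gene_pos[gene]] = mean
    tx = rng.poisson(means * quality[:, None])
    for j, gene in enumerate(genes):
        df[f"tx_{gene}"] = tx[:, j]
    bg = rng.poisson(
        layout.tx_background_mean * quality[:, None],
        size=(n, layout.tx_background_genes),
    )
    for j in range(layout.tx_background_genes):
        df[f"tx_BGS{j + 1:02d}"] = bg[:, j]
    tx_cols = [c for c in df.columns if c.startswith("tx_")]
    df["total_transcripts"] = df[tx_cols].sum(axis=1)
    return df


# ---------------------------------------------------------------------------
# survival cohorts


def generate_survival(
    n: int,
    effect: float,
    censor_fraction: float,
    cutpoint_quantile: float,
    seed: int,
    baseline_hazard: float = 0.02,
) -> Tuple[SurvivalTable, Dict[str, float]]:
    """Exponential survival cohort with a planted score cutpoint.

    Signature scores are standard normal; subjects below the planted
    cutpoint quantile have their hazard multiplied by exp(effect).
    Independent uniform censoring is calibrated so the expected censored
    fraction approximates the request. Returns the table and the planted
    truth (cutpoint value/quantile, group hazards).
    """
    if n < 20:
        raise ValidationError("n must be ≥ 20")
    if not (0 <= censor_fraction < 1):
        raise ValidationError("censor_fraction must be in [0, 1)")
    if not (0 < cutpoint_quantile < 1):
        raise ValidationError("cutpoint_quantile must be in (0, 1)")
    rng = np.random.default_rng(seed)
    score = rng.normal(0.0, 1.0, n)
    cutpoint = float(np.quantile(score, cutpoint_quantile))
    low = score <= cutpoint
    hazard = np.where(low, baseline_hazard * math.exp(effect), baseline_hazard)
    t_event = rng.exponential(1.0 / hazard)

    if censor_fraction > 0:
        # P(U(0,u) < Exp(λ)) = (1 - exp(-λu)) / (λu); solve mixture for u
        lams = np.unique(hazard)
        weights = np.array([(hazard == l).mean() for l in lams])

        def censored_prob(u: float) -> float:
            return float(
                np.sum(weights * (1.0 - np.exp(-lams * u)) / (lams * u))
            )

        lo_u, hi_u = 1e-6, 1e7
        for _ in range(200):
            mid = math.sqrt(lo_u * hi_u)
            if censored_prob(mid) > censor_fraction:
                lo_u = mid
            else:
                hi_u = mid
        c = rng.uniform(0, hi_u, n)
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    else:
        event = np.ones(n, dtype=int)
        time = t_event
    time = np.maximum(time, 1e-9)

    table = SurvivalTable(
        pd.DataFrame(
            {
                "subject_id": [f"P{i:04d}" for i in range(n)],
                "time": time,
                "event": event,
                "score": score,
                "true_group": np.where(low, "low", "high"),
            }
        )
    )
    truth = {
        "cutpoint": cutpoint,
        "cutpoint_quantile": cutpoint_quantile,
        "hazard_low": baseline_hazard * math.exp(effect),
        "hazard_high": baseline_hazard,
    }
    return table, truth
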