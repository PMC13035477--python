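"""End-to-end pipeline: synthesize → attraction → pairspace → spatial → signatures.

Driven by a YAML/JSON config naming a synthetic scenario (or input files),
the stages to run, a root seed and an output directory. All randomness
derives from the root seed, so identical config + seed yields byte-identical
outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import attraction as attr
from . import io as lio
from . import pairspace as ps
from . import spatial as sp
from . import survival as sv
from . import synthetic as syn
from .datatypes import AnalysisConfig, HOMEOSTATIC_SIGNATURE, ValidationError

STAGES = ("synthesize", "attraction", "pairspace", "spatial", "signatures")
SCENARIOS = ("rLN", "FL", "DLBCL", "rLN_small", "survival")

FLOAT_FMT = "%.10g"


class ConfigurationError(ValueError):
    pass


def _load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _scenario_params(scenario: str, cfg: dict) -> dict:
    if scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; valid scenarios: {', '.join(SCENARIOS)}"
        )
    entity = "rLN" if scenario == "rLN_small" else scenario
    defaults = {
        "entity": entity,
        "n_cells": 400 if scenario == "rLN_small" else 2000,
        "n_samples": 2,
        "survival_n": 300,
        "survival_effect": float(np.log(3.0)),
        "survival_censor": 0.2,
        "survival_cutpoint_quantile": 0.6,
        "density_scale": 0.2 if scenario == "rLN_small" else 1.0,
    }
    defaults.update(cfg.get("scenario_params", {}))
    return defaults


def stage_synthesize(outdir: Path, scenario: str, seed: int, params: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if scenario == "survival":
        tbl, truth = syn.generate_survival(
            n=params["survival_n"],
            effect=params["survival_effect"],
            censor_fraction=params["survival_censor"],
            cutpoint_quantile=params["survival_cutpoint_quantile"],
            seed=seed,
        )
        tbl.table.to_csv(outdir / "survival.csv", index=False, float_format=FLOAT_FMT)
        (outdir / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=1))
        return
    profile = syn.default_profiles()[params["entity"]]
    exprs, anns = [], []
    for i in range(params["n_samples"]):
        e, a = syn.generate_expression(
            profile, params["n_cells"], seed=seed + i,
            sample_id=f"{params['entity']}_p{i + 1}",
        )
        exprs.append(e)
        anns.append(a)
    genes = exprs[0].gene_ids
    values = np.concatenate([e.values for e in exprs], axis=1)
    cell_ids = sum((e.cell_ids for e in exprs), [])
    from .datatypes import GeneExpressionMatrix

    expr = GeneExpressionMatrix(values, genes, cell_ids, normalized=False)
    ann_tab = pd.concat([a.table for a in anns], ignore_index=True)
    lio.write_expression(
        expr, outdir / "expression.mtx", outdir / "genes.tsv", outdir / "cells.tsv"
    )
    ann_tab.to_csv(outdir / "cells.csv", index=False)

    layout = syn.default_layout(params["entity"])
    layout.density_per_um2 *= params["density_scale"]
    spatial = syn.generate_spatial(layout, profile, seed=seed + 1000)
    spatial.to_csv(outdir / "spatial.csv", index=False, float_format=FLOAT_FMT)

    tbl, truth = syn.generate_survival(
        n=params["survival_n"],
        effect=params["survival_effect"],
        censor_fraction=params["survival_censor"],
        cutpoint_quantile=params["survival_cutpoint_quantile"],
        seed=seed + 2000,
    )
    tbl.table.to_csv(outdir / "survival.csv", index=False, float_format=FLOAT_FMT)
    (outdir / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=1))


def stage_attraction(outdir: Path, seed: int, acfg: AnalysisConfig) -> None:
    expr = lio.load_expression(
        outdir / "expression.mtx", outdir / "genes.tsv", outdir / "cells.tsv"
    )
    cells = lio.load_annotations(outdir / "cells.csv")
    registry = lio.load_registry()
    norm = lio.log_normalize(expr, scale=acfg.norm_scale)
    mats = []
    for i, sample in enumerate(cells.samples):
        m = attr.compute_attraction(
            norm, cells, registry, sample,
            downsample_per_type=acfg.downsample_per_type, seed=seed + i,
        )
        mats.append(attr.filter_pairs(m, acfg.min_lr_pairs))
    merged = attr.merge_samples(mats)
    merged.to_frame().to_csv(
        outdir / "pair_matrix.csv", index=False, float_format=FLOAT_FMT
    )


def _load_pair_matrix(outdir: Path):
    df = pd.read_csv(outdir / "pair_matrix.csv")
    from .datatypes import PairFeatureMatrix

    meta = df[["sender", "receiver", "sample_id"]]
    scores = df.drop(columns=["sender", "receiver", "sample_id"])
    return PairFeatureMatrix(meta, scores)


def stage_pairspace(outdir: Path, seed: int, acfg: AnalysisConfig) -> None:
    m = _load_pair_matrix(outdir)
    cells = lio.load_annotations(outdir / "cells.csv")
    acfg = acfg.with_overrides(seed=seed)
    emb = ps.embed_pairs(m, acfg, compute_layout=True)
    emb = ps.cluster_pairs(emb, seed=seed)
    annotations = ps.annotate_clusters(emb, m)
    comp = ps.summarize_composition(emb, cells)

    entity_of = dict(zip(cells.table["sample_id"], cells.table["entity"]))
    groups = pd.DataFrame(
        {
            "patient": m.pairs["sample_id"],
            "entity": m.pairs["sample_id"].map(entity_of),
        }
    )
    diff = ps.diffuseness(emb, groups, fraction=acfg.diffuseness_fraction, seed=seed)

    out = emb.pairs.copy()
    for i in range(emb.pc_coords.shape[1]):
        out[f"PC{i + 1}"] = emb.pc_coords[:, i]
    out["umap1"] = emb.umap_coords[:, 0]
    out["umap2"] = emb.umap_coords[:, 1]
    out["cluster"] = emb.cluster
    out["zone"] = [annotations[c] for c in emb.cluster]
    out.to_csv(outdir / "pair_embedding.csv", index=False, float_format=FLOAT_FMT)
    diff.to_csv(outdir / "diffuseness.csv", index=False, float_format=FLOAT_FMT)
    comp.sender.to_csv(outdir / "composition_sender.csv", float_format=FLOAT_FMT)
    comp.receiver.to_csv(outdir / "composition_receiver.csv", float_format=FLOAT_FMT)


def stage_spatial(outdir: Path, seed: int, acfg: AnalysisConfig) -> None:
    t = lio.load_spatial_table(outdir / "spatial.csv")
    t = sp.qc_filter_cells(t, acfg.min_transcripts)
    comp = sp.neighbor_composition(t, acfg.nhood_k)
    raw, _ = sp.cluster_neighborhoods(comp, acfg.nhood_kmeans_k, seed=seed)
    merged, _ = sp.merge_similar_clusters(raw, comp, acfg.merge_correlation)
    enrich = sp.enrichment_matrix(merged, t)
    nh = t[["cell_id", "x_um", "y_um", "cell_type"]].copy()
    nh["raw_cluster"] = raw
    nh["neighborhood"] = merged
    nh.to_csv(outdir / "neighborhoods.csv", index=False, float_format=FLOAT_FMT)
    enrich.to_csv(outdir / "enrichment.csv", index=False, float_format=FLOAT_FMT)


def stage_signatures(outdir: Path, seed: int, acfg: AnalysisConfig) -> None:
    tbl = lio.load_survival_table(outdir / "survival.csv")
    res = sv.maxstat_cutpoint(tbl, n_perm=1000, seed=seed)
    t = tbl.table.copy()
    t["group"] = res.groups.to_numpy()
    from .datatypes import SurvivalTable

    km = sv.km_logrank(SurvivalTable(t))
    t.to_csv(outdir / "groups.csv", index=False, float_format=FLOAT_FMT)
    km.curves.to_csv(outdir / "km_curves.csv", index=False, float_format=FLOAT_FMT)
    summary = {
        "cutpoint": res.cutpoint,
        "maxstat_statistic": res.statistic,
        "p_permutation_selection_aware": res.p_perm,
        "p_logrank_naive": res.p_logrank,
        "logrank_statistic": km.statistic,
        "km_median_low": km.medians.get("low"),
        "km_median_high": km.medians.get("high"),
        "signature": HOMEOSTATIC_SIGNATURE.name,
    }
    (outdir / "survival_summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1)
    )


def run_pipeline(config_path) -> Path:
    """Execute the configured stages in order; returns the output directory."""
    cfg = _load_config(config_path)
    for key in ("outdir", "seed"):
        if key not in cfg:
            raise ConfigurationError(f"config is missing required key {key!r}")
    stages: List[str] = cfg.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ConfigurationError(
            f"unknown stage(s) {bad}; valid stages: {', '.join(STAGES)}"
        )
    scenario = cfg.get("scenario", "rLN_small")
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    params = _scenario_params(scenario, cfg)
    acfg = AnalysisConfig(**cfg.get("params", {}))

    for stage in stages:
        if stage == "synthesize":
            stage_synthesize(outdir, scenario, seed, params)
        elif stage == "attraction" and scenario != "survival":
            stage_attraction(outdir, seed, acfg)
        elif stage == "pairspace" and scenario != "survival":
            stage_pairspace(outdir, seed, acfg)
        elif stage == "spatial" and scenario != "survival":
            stage_spatial(outdir, seed, acfg)
        elif stage == "signatures":
            stage_signatures(outdir, seed, acfg)

    log = {
        "scenario": scenario,
        "seed": seed,
        "stages": stages,
        "scenario_params": {k: params[k] for k in sorted(params)},
        "analysis_config": {
            k: getattr(acfg, k) for k in sorted(vars(acfg))
        },
    }
    (outdir / "run_log.json").write_text(json.dumps(log, sort_keys=True, indent=1))
    return outdir
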