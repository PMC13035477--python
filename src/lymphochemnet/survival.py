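"""Chemokine signatures, clonal expansion, regulon enrichment and survival.

The survival workflow mirrors the bulk-transcriptomics analysis: a
signature score (mean expression of the homeostatic chemokines CXCL12,
CXCL13, CCL19, CCL21) per sample, dichotomization at the maximally selected
rank statistic's optimal cutpoint, and Kaplan–Meier curves with a log-rank
test. The maximal statistic uses the log-rank-scores formulation (each
candidate split's standardized statistic is a cumulative sum of per-subject
scores), so the cutpoint scan is O(n log n) and permutations are cheap; its
p-value comes from a seeded permutation null rather than an asymptotic
approximation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Set

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import fisher_exact

from .datatypes import (
    GeneExpressionMatrix,
    GeneSignature,
    SurvivalTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


def signature_score(expr: GeneExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """Per-column arithmetic mean of the signature genes' expression."""
    present = [g for g in sorted(sig.genes) if g in expr.gene_ids]
    missing = sorted(sig.genes - set(present))
    if not present:
        raise ValidationError(f"no gene of signature {sig.name!r} in the matrix")
    if missing:
        logger.warning("signature %s: %d genes absent, dropped", sig.name, len(missing))
    rows = expr.gene_index(present)
    return pd.Series(expr.values[rows].mean(axis=0), index=expr.cell_ids, name=sig.name)


def classify_clonotypes(
    clone_sizes: Dict[str, int], threshold: int = 7
) -> Dict[str, bool]:
    """A clonotype is expanded when detected in strictly more cells than the
    threshold (default: > 7 cells)."""
    for clone, size in clone_sizes.items():
        if size < 1:
            raise ValidationError(f"clonotype {clone!r} has size {size} < 1")
    return {clone: size > threshold for clone, size in clone_sizes.items()}


def regulon_enrichment(
    target_genes: Set[str], deg_set: Set[str], universe: Set[str]
) -> Dict[str, float]:
    """Fisher exact enrichment of differentially expressed genes among the
    target genes of one regulon, within a gene universe."""
    target_genes, deg_set, universe = set(target_genes), set(deg_set), set(universe)
    if len(universe) < 4:
        raise ValidationError("universe must contain ≥ 4 genes")
    if not target_genes <= universe or not deg_set <= universe:
        raise ValidationError("target and DEG sets must be subsets of the universe")
    a = len(target_genes & deg_set)
    b = len(target_genes - deg_set)
    c = len(deg_set - target_genes)
    d = len(universe) - a - b - c
    orr, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {"odds_ratio": float(orr), "p": float(p), "overlap": a}


def regulon_enrichment_batch(
    regulons: Dict[str, Set[str]], deg_set: Set[str], universe: Set[str]
) -> pd.DataFrame:
    """Enrichment across regulons with Bonferroni-adjusted p-values."""
    rows = []
    for name in sorted(regulons):
        res = regulon_enrichment(regulons[name], deg_set, universe)
        res["regulon"] = name
        rows.append(res)
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    return out[["regulon", "overlap", "odds_ratio", "p", "p_adj"]]


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-subject log-rank scores a_i = δ_i − Λ̂(t_i) (Nelson–Aalen with
    ties). The two-group log-rank statistic with permutation variance is a
    sum of these scores over one group."""
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    n = len(time)
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    at_risk = n - first_idx
    deaths = np.add.reduceat(e_sorted, first_idx)
    cumhaz = np.cumsum(deaths / at_risk)
    haz_at = dict(zip(uniq, cumhaz))
    a = event - np.array([haz_at[t] for t in time])
    return a


@dataclass
class MaxstatResult:
    """Optimal cutpoint of a maximally selected rank statistic scan."""

    cutpoint: float
    statistic: float
    p_perm: Optional[float]
    p_logrank: float
    groups: pd.Series  # high/low per subject
    scan: pd.DataFrame  # cutpoint candidates with standardized statistics


def maxstat_cutpoint(
    tbl: SurvivalTable,
    min_group_fraction: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
) -> MaxstatResult:
    """Dichotomize a continuous score by the maximally selected rank statistic.

    Candidate cutpoints are the distinct score values whose induced low
    group holds between ``min_group_fraction`` and 1−``min_group_fraction``
    of subjects. At each candidate the standardized log-rank statistic of
    the split is computed from cumulative log-rank scores; the argmax is
    returned, with a permutation p-value for the maximal statistic (score
    labels permuted, selection repeated — so the p accounts for the scan).
    A naive log-rank p for the selected split is also reported.
    """
    t = tbl.table
    n = len(t)
    if n < 20:
        raise ValidationError("need ≥ 20 subjects")
    if t["event"].sum() < 5:
        raise ValidationError("need ≥ 5 events")
    if not (0 < min_group_fraction < 0.5):
        raise ValidationError("min_group_fraction must be in (0, 0.5)")
    score = t["score"].to_numpy(float)
    if np.unique(score).size < 2:
        raise ValidationError("all scores identical; no cutpoint exists")

    a = logrank_scores(t["time"].to_numpy(float), t["event"].to_numpy(float))
    order = np.argsort(score, kind="stable")
    s_sorted = score[order]
    a_sorted = a[order]

    # split after position k (1-based size of the low group); only between
    # distinct score values and within the group-size bounds
    ks = np.arange(1, n)
    distinct = s_sorted[:-1] < s_sorted[1:]
    lo = int(np.ceil(min_group_fraction * n))
    hi = int(np.floor((1 - min_group_fraction) * n))
    valid = distinct & (ks >= lo) & (ks <= hi)
    if not valid.any():
        raise ValidationError("no admissible cutpoint within the group-size bounds")
    ks = ks[valid]

    a_mean = a.mean()
    ss = ((a - a_mean) ** 2).sum()
    var = ks * (n - ks) / (n * (n - 1)) * ss

    cum = np.cumsum(a_sorted)
    z = (cum[ks - 1] - ks * a_mean) / np.sqrt(var)
    absz = np.abs(z)
    best = int(np.argmax(absz))
    statistic = float(absz[best])
    k_star = int(ks[best])
    cutpoint = float(s_sorted[k_star - 1])

    p_perm: Optional[float] = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(a, (n_perm, 1)), axis=1)
        cums = np.cumsum(perms, axis=1)[:, ks - 1]
        zs = np.abs(cums - ks * a_mean) / np.sqrt(var)
        m_perm = zs.max(axis=1)
        p_perm = float((1 + np.sum(m_perm >= statistic)) / (n_perm + 1))

    groups = pd.Series(
        np.where(score <= cutpoint, "low", "high"), index=t["subject_id"], name="group"
    )
    low_mask = score <= cutpoint
    lr = logrank_test(
        t["time"][low_mask], t["time"][~low_mask],
        event_observed_A=t["event"][low_mask], event_observed_B=t["event"][~low_mask],
    )
    scan = pd.DataFrame(
        {"cutpoint": s_sorted[ks - 1], "n_low": ks, "abs_z": absz}
    )
    return MaxstatResult(cutpoint, statistic, p_perm, float(lr.p_value), groups, scan)


@dataclass
class KmLogrankResult:
    curves: pd.DataFrame  # group, time, at_risk, survival
    statistic: float
    p: float
    medians: Dict[str, float]


def km_logrank(tbl: SurvivalTable, group_col: str = "group") -> KmLogrankResult:
    """Kaplan–Meier curves per group and the two-group log-rank test."""
    t = tbl.table
    if group_col not in t.columns:
        raise ValidationError(f"survival table lacks a {group_col!r} column")
    groups = sorted(pd.unique(t[group_col]))
    if len(groups) != 2 or any((t[group_col] == g).sum() == 0 for g in groups):
        raise ValidationError("need exactly two non-empty groups")
    curves = []
    medians: Dict[str, float] = {}
    for g in groups:
        sub = t[t[group_col] == g]
        if sub["event"].sum() == 0:
            warnings.warn(f"group {g!r} has zero events; KM curve is flat")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        sf = kmf.survival_function_
        ev = kmf.event_table
        curves.append(
            pd.DataFrame(
                {
                    "group": str(g),
                    "time": sf.index.to_numpy(float),
                    "at_risk": ev["at_risk"].to_numpy(float),
                    "survival": sf.iloc[:, 0].to_numpy(float),
                }
            )
        )
        medians[str(g)] = float(kmf.median_survival_time_)
    g0, g1 = groups
    res = logrank_test(
        t.loc[t[group_col] == g0, "time"],
        t.loc[t[group_col] == g1, "time"],
        event_observed_A=t.loc[t[group_col] == g0, "event"],
        event_observed_B=t.loc[t[group_col] == g1, "event"],
    )
    return KmLogrankResult(
        pd.concat(curves, ignore_index=True),
        float(res.test_statistic),
        float(res.p_value),
        medians,
    )
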