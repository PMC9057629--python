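"""Per-patient preranked gene-set enrichment on a bulk cohort.

Pipeline: per-gene z-scores across patients -> per-patient descending ranking
-> weighted Kolmogorov-Smirnov enrichment score (ES) -> gene-sampling
permutation null -> NES and permutation p -> Benjamini-Hochberg adjustment ->
enriched / depleted / neither classification.

Conventions
-----------
* Ranking statistic: each patient's own z relative to the cohort,
  z_gp = (x_gp - mean_g) / sd_g (sample sd). A cohort-averaged z would be
  identical for every patient and cannot yield per-patient classes.
* ES: walking the ranking, a gene-set hit increments the running sum by
  |z|^p_w / sum_hits |z|^p_w and a miss decrements by 1/(N - N_hits); the ES
  is the signed extremum. p_w = 0 recovers the classic unweighted KS
  statistic; p_w = 1 is the default.
* Null: ES of random same-size gene sets drawn from the universe (per-patient
  ranked lists admit no phenotype permutation). p uses the add-one estimator
  against same-sign null draws; NES divides the ES by the mean |null ES| of
  the same sign.
* BH family: "patients_per_set" (default) adjusts across patients for each
  gene set, matching cohort classification per set; "sets_per_patient" is the
  alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

ENRICHED = "enriched"
DEPLETED = "depleted"
NEITHER = "neither"


@dataclass
class BulkCohort:
    """Genes x patients log2 expression with per-patient clinical records."""

    expression: pd.DataFrame
    clinical: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.expression.columns.duplicated().any():
            raise ValueError("duplicate patient identifiers")
        if self.clinical is not None:
            missing = self.expression.columns.difference(self.clinical.index)
            if len(missing):
                raise ValueError(f"clinical records missing for {len(missing)} patients")


@dataclass
class RankedGeneList:
    """One patient's genes ordered by descending rank statistic."""

    patient: str
    genes: np.ndarray
    stats: np.ndarray


@dataclass(frozen=True)
class EnrichmentParams:
    p_w: float = 1.0
    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    bh_family: str = "patients_per_set"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.p_w < 0:
            raise ValueError("weight exponent must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if self.bh_family not in ("patients_per_set", "sets_per_patient"):
            raise ValueError("unknown bh_family")


@dataclass
class EnrichmentResult:
    patient: str
    gene_set: str
    es: float
    nes: float
    p: float
    padj: float | None = None
    label: str | None = None
    leading_edge: list[str] = field(default_factory=list)
    flagged: bool = False


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def per_patient_zranks(expression: pd.DataFrame) -> list[RankedGeneList]:
    """Rank every patient's genes by their z-score against the cohort.

    Genes with zero variance across patients are dropped (and recorded in the
    module logger); ties are broken by gene id so rankings are strictly
    reproducible.
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 patients to standardize genes")
    values = expression.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        import logging

        logging.getLogger(__name__).info(
            "dropping %d zero-variance genes from rankings", int((~keep).sum()))
    z = (values[keep] - mean[keep, None]) / sd[keep, None]
    genes = expression.index.to_numpy(dtype=object)[keep]
    out = []
    for j, patient in enumerate(expression.columns):
        order = np.lexsort((genes, -z[:, j]))
        out.append(RankedGeneList(patient=str(patient), genes=genes[order],
                                  stats=z[order, j]))
    return out


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def _es_from_masks(stats: np.ndarray, hit_masks: np.ndarray, p_w: float):
    """Vectorized ES for one ranking and many hit masks (M x N bool).

    Returns (es, extremum index) arrays of length M. Masks must be proper
    non-empty subsets of the universe.
    """
    hit_masks = np.atleast_2d(hit_masks)
    m, n = hit_masks.shape
    k = hit_masks.sum(axis=1)
    if np.any(k == 0) or np.any(k == n):
        raise ValueError("gene set must be a non-empty proper subset of the universe")
    absw = np.abs(stats) ** p_w
    w = hit_masks * absw[None, :]
    tot = w.sum(axis=1, keepdims=True)
    # all-zero weights (every hit stat is 0): fall back to equal hit steps
    hit_step = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0),
                        hit_masks / k[:, None])
    steps = hit_step - (~hit_masks) / (n - k)[:, None]
    run = np.cumsum(steps, axis=1)
    idx = np.abs(run).argmax(axis=1)
    es = run[np.arange(m), idx]
    return es, idx


def enrichment_score(ranked: RankedGeneList, gene_set, p_w: float = 1.0):
    """Weighted KS enrichment score of ``gene_set`` on one ranked list.

    Returns ``(es, running_sum, leading_edge)``. The leading edge contains the
    hits at or before the extremum (at or after it for a negative ES).
    """
    genes = ranked.genes
    hit = np.isin(genes, np.asarray(list(gene_set), dtype=object))
    if hit.sum() == 0:
        raise ValueError("gene set has no overlap with the ranked universe")
    es, idx = _es_from_masks(ranked.stats, hit[None, :], p_w)
    es, idx = float(es[0]), int(idx[0])
    absw = np.abs(ranked.stats) ** p_w
    w = hit * absw
    tot = w.sum()
    steps = (w / tot if tot > 0 else hit / hit.sum()) - (~hit) / (len(genes) - hit.sum())
    running = np.cumsum(steps)
    if es >= 0:
        leading = genes[:idx + 1][hit[:idx + 1]]
    else:
        leading = genes[idx:][hit[idx:]]
    return es, running, list(leading)


def _sample_hit_masks(rng: np.random.Generator, n_perm: int, n: int, k: int) -> np.ndarray:
    """n_perm uniform random k-subsets of an n-universe, as boolean masks."""
    keys = rng.random((n_perm, n))
    pos = np.argpartition(keys, k - 1, axis=1)[:, :k]
    masks = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(masks, pos, True, axis=1)
    return masks


def null_es(stats: np.ndarray, k: int, n_perm: int,
            rng: np.random.Generator, p_w: float = 1.0,
            chunk: int = 512) -> np.ndarray:
    """Null ES distribution: random size-k gene sets on one ranking."""
    n = len(stats)
    out = np.empty(n_perm)
    done = 0
    block = max(1, min(chunk, int(4e6 // max(n, 1)) or 1))
    while done < n_perm:
        m = min(block, n_perm - done)
        masks = _sample_hit_masks(rng, m, n, k)
        out[done:done + m] = _es_from_masks(stats, masks, p_w)[0]
        done += m
    return out


def _p_and_nes(es: float, null: np.ndarray):
    """Add-one permutation p against same-sign nulls, and null-normalized ES."""
    same = null[null >= 0] if es >= 0 else null[null < 0]
    if len(same) == 0:
        return 1.0, 0.0, True
    p = (1.0 + np.count_nonzero(np.abs(same) >= abs(es))) / (1.0 + len(same))
    nes = es / np.abs(same).mean()
    return float(p), float(nes), False


def gsea_significance(ranked: RankedGeneList, gene_set,
                      params: EnrichmentParams | None = None,
                      gene_set_name: str = "gene_set") -> EnrichmentResult:
    """ES, permutation p, and NES for one gene set on one patient's ranking."""
    params = params or EnrichmentParams()
    genes = ranked.genes
    hit = np.isin(genes, np.asarray(list(gene_set), dtype=object))
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set has no overlap with the ranked universe")
    if k == len(genes):
        # no misses: the running sum is degenerate
        return EnrichmentResult(ranked.patient, gene_set_name, es=float("nan"),
                                nes=0.0, p=1.0, flagged=True)
    es, _, leading = enrichment_score(ranked, gene_set, params.p_w)
    rng = np.random.default_rng(params.seed)
    null = null_es(ranked.stats, k, params.n_perm, rng, params.p_w)
    p, nes, flagged = _p_and_nes(es, null)
    return EnrichmentResult(ranked.patient, gene_set_name, es=es, nes=nes, p=p,
                            leading_edge=leading, flagged=flagged)


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------

def enrich_cohort(cohort: BulkCohort | pd.DataFrame,
                  gene_sets: dict[str, list[str]],
                  params: EnrichmentParams | None = None) -> pd.DataFrame:
    """ES/NES/p for every patient x gene set.

    The permutation null depends only on a patient's ranking and the set
    size, so it is drawn once per (patient, size) and shared across all
    gene sets of that size — the standard gene-sampling economy.
    """
    params = params or EnrichmentParams()
    expression = cohort.expression if isinstance(cohort, BulkCohort) else cohort
    rankings = per_patient_zranks(expression)
    universe = rankings[0].genes  # same gene filter for every patient
    set_items = [(name, np.isin(universe, np.asarray(list(genes), dtype=object)))
                 for name, genes in gene_sets.items()]
    rows = []
    seeds = np.random.SeedSequence(params.seed).spawn(len(rankings))
    for ranked, seed in zip(rankings, seeds):
        order_pos = {g: i for i, g in enumerate(ranked.genes)}
        idx = np.array([order_pos[g] for g in universe])
        rng = np.random.default_rng(seed)
        by_size: dict[int, np.ndarray] = {}
        names, masks, ks = [], [], []
        for name, base_mask in set_items:
            mask = np.zeros(len(universe), dtype=bool)
            mask[idx[base_mask]] = True
            k = int(mask.sum())
            if k == 0:
                raise ValueError(f"gene set {name!r} has no overlap with the universe")
            if k == len(universe):
                rows.append((ranked.patient, name, np.nan, 0.0, 1.0, True))
                continue
            names.append(name)
            masks.append(mask)
            ks.append(k)
        if not names:
            continue
        es_all, _ = _es_from_masks(ranked.stats, np.array(masks), params.p_w)
        for name, k, es in zip(names, ks, es_all):
            if k not in by_size:
                by_size[k] = null_es(ranked.stats, k, params.n_perm, rng, params.p_w)
            p, nes, flagged = _p_and_nes(float(es), by_size[k])
            rows.append((ranked.patient, name, float(es), nes, p, flagged))
    return pd.DataFrame(rows, columns=["patient", "gene_set", "es", "nes", "p",
                                       "flagged"])


# ---------------------------------------------------------------------------
# BH adjustment and classification
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_patients(results: pd.DataFrame,
                      params: EnrichmentParams | None = None) -> pd.DataFrame:
    """Attach BH-adjusted p and enriched/depleted/neither labels.

    Enriched: NES > 0 and padj < alpha. Depleted: NES < 0 and padj < alpha.
    Everything else (including flagged degenerate results) is "neither".
    """
    params = params or EnrichmentParams()
    out = results.copy()
    group_key = "gene_set" if params.bh_family == "patients_per_set" else "patient"
    out["padj"] = out.groupby(group_key, sort=False)["p"].transform(
        lambda s: bh_adjust(s.to_numpy()))
    label = np.full(len(out), NEITHER, dtype=object)
    sig = (out["padj"] < params.alpha) & ~out["flagged"]
    label[sig & (out["nes"] > 0)] = ENRICHED
    label[sig & (out["nes"] < 0)] = DEPLETED
    out["label"] = label
    return out
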