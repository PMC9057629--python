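"""Synthetic multiplexed droplet runs and bulk survival cohorts with ground truth.

Every downstream stage of the pipeline (demultiplexing, ADT linkage, marker
signatures, clonality, per-patient enrichment, survival stratification) is
exercised against data produced here, so each generator plants a known truth:

* :func:`simulate_multiplexed_run` emulates a hashed CITE-Seq run — per-cell
  hashtag (HTO) counts with singlet/doublet/ambient structure, antibody tag
  (ADT) counts with cluster-specific means, gene counts with cluster-specific
  marker elevation on a negative-binomial (Poisson-gamma) count model, and a
  TCR contig table with patient-restricted, Dirichlet-skewed clonal expansion.
* :func:`simulate_bulk_cohort` emulates a bulk tumor cohort — per-gene Gaussian
  log2 expression with a planted signature shift in enriched (+) and depleted
  (-) patients, and exponential survival whose hazard is multiplied for the
  depleted class (and optionally by stage), with random censoring.

The same seed always yields identical output. These are stand-ins: no
distributional description of the real assays exists, so the choices here are
documented conventions (see docs/methods.md), not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd

from . import io as tio

_NT = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_STAGES = ("I", "II", "III", "IV")


class ConfigurationError(ValueError):
    """Raised when a simulation config violates its invariants."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class MultiplexSimConfig:
    """Parameters of a simulated hashed CITE-Seq run.

    ``ambient_fraction`` is the share of a cell's HTO counts drawn uniformly
    from the non-own tags; ``clonotype_concentration`` is the Dirichlet
    concentration of per-patient clone probabilities (small values give a
    skewed repertoire with expanded clones); ``dispersion`` is the
    negative-binomial shape shared by HTO/ADT/RNA counts.
    """

    n_cells: int = 2000
    n_tags: int = 8
    doublet_rate: float = 0.08
    ambient_fraction: float = 0.05
    n_genes: int = 1000
    n_clusters: int = 5
    markers_per_cluster: int = 20
    marker_fold: float = 4.0
    adt_panel_size: int = 23
    clonotype_concentration: float = 0.3
    seed: int = 0
    dispersion: float = 2.0
    hto_depth: float = 200.0
    hto_total_shape: float = 10.0
    rna_depth: float = 2000.0
    adt_depth: float = 500.0
    tcr_assigned_rate: float = 0.93
    tcr_paired_rate: float = 0.86

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_tags", "n_genes", "n_clusters",
                     "markers_per_cluster", "adt_panel_size"):
            _check(int(getattr(self, name)) > 0, f"{name} must be a positive integer")
        for name in ("doublet_rate", "ambient_fraction", "tcr_assigned_rate",
                     "tcr_paired_rate"):
            _check(0.0 <= float(getattr(self, name)) <= 1.0, f"{name} must lie in [0, 1]")
        _check(self.marker_fold >= 1.0, "marker_fold must be >= 1")
        _check(self.clonotype_concentration > 0, "clonotype_concentration must be positive")
        _check(self.dispersion > 0, "dispersion must be positive")
        _check(self.n_clusters * self.markers_per_cluster <= self.n_genes,
               "marker blocks must fit into n_genes")
        _check(not (self.doublet_rate > 0 and self.n_tags < 2),
               "doublets require at least two tags")


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of a simulated bulk cohort with survival.

    ``effect_size`` is the mean shift in z-units applied to signature genes of
    enriched (+) and depleted (-) patients. Hazards are exponential:
    enriched patients sit at ``baseline_hazard`` events/month, depleted at
    ``baseline_hazard * hazard_ratio_depleted_vs_enriched``, unclassified
    ("neither") at the geometric mean of the two; each stage above I
    multiplies the hazard by ``stage_hazard_ratio``.
    """

    n_patients: int = 300
    n_genes: int = 1000
    signature_size: int = 50
    enriched_fraction: float = 0.2
    depleted_fraction: float = 0.2
    effect_size: float = 1.5
    baseline_hazard: float = 0.01
    hazard_ratio_depleted_vs_enriched: float = 3.0
    censor_rate: float = 0.3
    stage_probs: tuple[float, float, float, float] = (0.15, 0.30, 0.35, 0.20)
    seed: int = 0
    stage_hazard_ratio: float = 1.0
    msi_high_rate: float = 0.15

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_genes", "signature_size"):
            _check(int(getattr(self, name)) > 0, f"{name} must be a positive integer")
        for name in ("enriched_fraction", "depleted_fraction", "censor_rate",
                     "msi_high_rate"):
            _check(0.0 <= float(getattr(self, name)) <= 1.0, f"{name} must lie in [0, 1]")
        _check(self.enriched_fraction + self.depleted_fraction <= 1.0,
               "enriched_fraction + depleted_fraction must not exceed 1")
        _check(self.baseline_hazard > 0, "baseline_hazard must be positive")
        _check(self.hazard_ratio_depleted_vs_enriched > 0, "hazard ratio must be positive")
        _check(self.stage_hazard_ratio > 0, "stage_hazard_ratio must be positive")
        _check(len(self.stage_probs) == 4, "stage_probs must cover stages I-IV")
        _check(abs(sum(self.stage_probs) - 1.0) < 1e-8, "stage_probs must sum to 1")
        _check(self.signature_size <= self.n_genes, "signature must fit into n_genes")


@dataclass
class GroundTruth:
    """Planted truth for the simulators.

    Multiplexed-run fields: ``cells`` (per-barcode true tag, doublet flag,
    cluster, patient, tissue, clone id) and ``marker_genes`` (cluster ->
    planted markers). Bulk-cohort fields: ``patient_class`` (enriched /
    depleted / neither) and ``signature_genes``. Sections not produced by a
    given simulator are None.
    """

    cells: pd.DataFrame | None = None
    marker_genes: dict[str, list[str]] | None = None
    patient_class: pd.Series | None = None
    signature_genes: list[str] | None = None


def _nb_counts(rng: np.random.Generator, mean, shape, dispersion: float) -> np.ndarray:
    """Poisson-gamma (negative binomial) draw with mean ``mean`` and shape r."""
    lam = rng.gamma(dispersion, np.broadcast_to(mean, shape) / dispersion)
    return rng.poisson(lam)


def _random_seqs(rng: np.random.Generator, n: int, length: int, alphabet: np.ndarray) -> list[str]:
    """n distinct random strings over ``alphabet``; collisions are redrawn."""
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        block = rng.integers(0, len(alphabet), size=(n - len(seqs), length))
        for row in block:
            s = "".join(alphabet[row])
            if s not in seen:
                seen.add(s)
                seqs.append(s)
    return seqs


def _tag_metadata(n_tags: int) -> tuple[list[str], list[str], list[str]]:
    """Map tags to (patient, tissue): consecutive tag pairs share a patient
    (tumor/normal) when n_tags is even, otherwise one tumor sample per tag."""
    tags = [f"HTO{i + 1}" for i in range(n_tags)]
    if n_tags % 2 == 0:
        patients = [f"P{i // 2 + 1}" for i in range(n_tags)]
        tissues = ["tumor" if i % 2 == 0 else "normal" for i in range(n_tags)]
    else:
        patients = [f"P{i + 1}" for i in range(n_tags)]
        tissues = ["tumor"] * n_tags
    return tags, patients, tissues


def simulate_multiplexed_run(config: MultiplexSimConfig):
    """Simulate one hashed CITE-Seq run.

    Returns ``(hto, adt, expr, contigs, truth)``:

    * ``hto`` — tags x barcodes raw HTO count DataFrame,
    * ``adt`` — cells x antibodies AnnData of raw ADT counts,
    * ``expr`` — cells x genes AnnData of raw UMI counts with obs metadata
      (patient, tissue, condition, cluster),
    * ``contigs`` — 10x-style contig table (barcode, chain, cdr3, cdr3_nt,
      productive),
    * ``truth`` — :class:`GroundTruth` with per-barcode labels and the
      planted marker-gene blocks.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    tags, tag_patient, tag_tissue = _tag_metadata(cfg.n_tags)
    barcodes = [f"BC{i + 1:06d}" for i in range(n)]

    # --- sample-of-origin truth -------------------------------------------
    is_doublet = rng.random(n) < cfg.doublet_rate
    tag_idx = rng.integers(0, cfg.n_tags, size=n)
    if cfg.n_tags > 1:
        second_idx = (tag_idx + rng.integers(1, cfg.n_tags, size=n)) % cfg.n_tags
    else:
        second_idx = tag_idx.copy()

    # --- HTO counts: singlets concentrate on the own tag, doublets sum two
    # independently drawn singlet profiles (droplet co-encapsulation) -------
    def _singlet_probs(t: np.ndarray) -> np.ndarray:
        probs = np.full((len(t), cfg.n_tags),
                        cfg.ambient_fraction / max(cfg.n_tags - 1, 1))
        probs[np.arange(len(t)), t] = 1.0 - cfg.ambient_fraction
        if cfg.n_tags == 1:
            probs[:] = 1.0
        return probs

    # per-cell HTO totals vary moderately (NB shape hto_total_shape): both
    # members of a doublet contribute comparably, which is what makes
    # doublets detectable at all
    totals_a = _nb_counts(rng, cfg.hto_depth, (n,), cfg.hto_total_shape)
    totals_b = _nb_counts(rng, cfg.hto_depth, (n,), cfg.hto_total_shape)
    probs_a = _singlet_probs(tag_idx)
    probs_b = _singlet_probs(second_idx)
    hto_counts = np.empty((n, cfg.n_tags), dtype=np.int64)
    for i in range(n):
        hto_counts[i] = rng.multinomial(totals_a[i], probs_a[i])
        if is_doublet[i]:
            hto_counts[i] += rng.multinomial(totals_b[i], probs_b[i])
    hto = pd.DataFrame(hto_counts.T, index=pd.Index(tags, name="tag"),
                       columns=pd.Index(barcodes, name="barcode"))

    # --- clusters and gene counts -----------------------------------------
    clusters = [f"C{c}" for c in range(cfg.n_clusters)]
    cluster_idx = rng.integers(0, cfg.n_clusters, size=n)
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    base_w = rng.lognormal(0.0, 1.0, size=cfg.n_genes)
    marker_genes: dict[str, list[str]] = {}
    cluster_probs = np.empty((cfg.n_clusters, cfg.n_genes))
    for c in range(cfg.n_clusters):
        block = slice(c * cfg.markers_per_cluster, (c + 1) * cfg.markers_per_cluster)
        w = base_w.copy()
        w[block] *= cfg.marker_fold
        cluster_probs[c] = w / w.sum()
        marker_genes[clusters[c]] = genes[block]
    depths = _nb_counts(rng, cfg.rna_depth, (n,), cfg.dispersion).astype(float)
    mu = depths[:, None] * cluster_probs[cluster_idx]
    expr_counts = _nb_counts(rng, mu, mu.shape, cfg.dispersion)

    # --- ADT counts with cluster-specific means ---------------------------
    antibodies = [f"ADT{i + 1}" for i in range(cfg.adt_panel_size)]
    adt_means = rng.lognormal(2.0, 1.0, size=(cfg.n_clusters, cfg.adt_panel_size))
    adt_means *= cfg.adt_depth / adt_means.sum(axis=1, keepdims=True)
    adt_mu = adt_means[cluster_idx]
    adt_counts = _nb_counts(rng, adt_mu, adt_mu.shape, cfg.dispersion)

    # --- clonotypes: per-patient Dirichlet-skewed repertoire --------------
    patient = np.array(tag_patient)[tag_idx]
    tissue = np.array(tag_tissue)[tag_idx]
    clone_id = np.full(n, "", dtype=object)
    trb_nt: dict[str, str] = {}
    for p in np.unique(patient):
        cells_p = np.flatnonzero(patient == p)
        pool = max(len(cells_p), 1)
        probs = rng.dirichlet(np.full(pool, cfg.clonotype_concentration))
        draws = rng.choice(pool, size=len(cells_p), p=probs)
        seqs = _random_seqs(rng, pool, 36, _NT)
        for i, d in zip(cells_p, draws):
            cid = f"{p}_clone{d:04d}"
            clone_id[i] = cid
            trb_nt[cid] = seqs[d]

    assigned = rng.random(n) < cfg.tcr_assigned_rate
    paired = assigned & (rng.random(n) < cfg.tcr_paired_rate)
    rows = []
    tra_seqs = _random_seqs(rng, int(paired.sum()), 33, _NT)
    aa_seqs = _random_seqs(rng, n, 11, _AA)
    j = 0
    for i in range(n):
        if not assigned[i]:
            continue
        rows.append({"barcode": barcodes[i], "chain": "TRB",
                     "cdr3": "CASS" + aa_seqs[i] + "F",
                     "cdr3_nt": trb_nt[clone_id[i]], "productive": True})
        if paired[i]:
            rows.append({"barcode": barcodes[i], "chain": "TRA",
                         "cdr3": "CAV" + aa_seqs[i][:8] + "F",
                         "cdr3_nt": tra_seqs[j], "productive": True})
            j += 1
    contigs = pd.DataFrame(rows, columns=["barcode", "chain", "cdr3", "cdr3_nt", "productive"])

    # --- assemble ----------------------------------------------------------
    obs = pd.DataFrame({
        "patient": patient,
        "tissue": tissue,
        "condition": "nonstimulated",
        "cluster": np.array(clusters)[cluster_idx],
    }, index=pd.Index(barcodes, name="barcode"))
    expr = ad.AnnData(X=expr_counts.astype(np.int64), obs=obs.copy(),
                      var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adt = ad.AnnData(X=adt_counts.astype(np.int64), obs=obs.copy(),
                     var=pd.DataFrame(index=pd.Index(antibodies, name="antibody")))
    adt.uns["generating_means"] = pd.DataFrame(adt_means, index=clusters,
                                               columns=antibodies)
    truth_cells = obs.copy()
    truth_cells["true_tag"] = np.array(tags)[tag_idx]
    truth_cells["second_tag"] = np.where(is_doublet, np.array(tags)[second_idx], "")
    truth_cells["is_doublet"] = is_doublet
    truth_cells["clone_id"] = np.where(assigned, clone_id, "")
    truth = GroundTruth(cells=truth_cells, marker_genes=marker_genes)
    return hto, adt, expr, contigs, truth


def simulate_bulk_cohort(config: CohortSimConfig):
    """Simulate a bulk cohort with planted signature shift and survival.

    Returns ``(cohort, signature, truth)`` where ``cohort`` is a
    :class:`BulkCohort` (genes x patients log2 expression + clinical records),
    ``signature`` the planted gene set, and ``truth`` the per-patient class
    and signature membership.
    """
    from .enrichment import BulkCohort  # local import to avoid a cycle
    from .signatures import GeneSignature

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    patients = [f"PT{i + 1:04d}" for i in range(cfg.n_patients)]
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]

    n_e = int(round(cfg.enriched_fraction * cfg.n_patients))
    n_d = int(round(cfg.depleted_fraction * cfg.n_patients))
    labels = np.array(["enriched"] * n_e + ["depleted"] * n_d
                      + ["neither"] * (cfg.n_patients - n_e - n_d), dtype=object)
    labels = rng.permutation(labels)

    gene_mean = rng.normal(8.0, 2.0, size=cfg.n_genes)
    gene_sd = rng.uniform(0.5, 1.5, size=cfg.n_genes)
    expr = gene_mean[:, None] + gene_sd[:, None] * rng.standard_normal(
        (cfg.n_genes, cfg.n_patients))
    sig_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.signature_size, replace=False))
    shift = np.where(labels == "enriched", 1.0,
                     np.where(labels == "depleted", -1.0, 0.0))
    expr[sig_idx] += cfg.effect_size * gene_sd[sig_idx, None] * shift[None, :]
    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                           columns=pd.Index(patients, name="patient"))
    # generating baselines, kept for calibration checks against the model
    expr_df.attrs["generating_mean"] = pd.Series(gene_mean, index=expr_df.index)
    expr_df.attrs["generating_sd"] = pd.Series(gene_sd, index=expr_df.index)

    stage = rng.choice(_STAGES, size=cfg.n_patients, p=np.asarray(cfg.stage_probs))
    stage_num = np.array([_STAGES.index(s) + 1 for s in stage])
    hr = cfg.hazard_ratio_depleted_vs_enriched
    class_mult = np.where(labels == "depleted", hr,
                          np.where(labels == "neither", np.sqrt(hr), 1.0))
    hazard = (cfg.baseline_hazard * class_mult
              * cfg.stage_hazard_ratio ** (stage_num - 1))
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(cfg.n_patients) < cfg.censor_rate
    os_months = np.where(censored, rng.uniform(0.0, event_time), event_time)
    clinical = pd.DataFrame({
        "os_months": os_months,
        "os_event": (~censored).astype(int),
        "stage": stage,
        "msi_high": rng.random(cfg.n_patients) < cfg.msi_high_rate,
    }, index=pd.Index(patients, name="patient"))

    cohort = BulkCohort(expression=expr_df, clinical=clinical)
    signature = GeneSignature(
        name="planted_signature",
        genes=[genes[i] for i in sig_idx],
        meta={"derivation": "planted", "effect_size": cfg.effect_size},
    )
    truth = GroundTruth(
        patient_class=pd.Series(labels, index=expr_df.columns, name="true_class"),
        signature_genes=list(signature.genes),
    )
    return cohort, signature, truth


def write_fixtures(objects: Mapping[str, object], directory: str) -> dict[str, object]:
    """Write simulated objects to disk in the formats the readers consume.

    Recognized keys: ``expression`` (AnnData -> MTX triplet), ``adt``
    (AnnData -> wide CSV), ``hto`` (DataFrame -> CSV), ``contigs``
    (DataFrame -> CSV), ``cohort`` (BulkCohort -> expression.csv +
    clinical.csv), ``signatures`` (list -> GMT).
    """
    import os

    os.makedirs(directory, exist_ok=True)
    paths: dict[str, object] = {}
    for name, obj in objects.items():
        if name == "expression":
            paths[name] = tio.write_mtx_dir(obj, os.path.join(directory, "expression"))
        elif name == "adt":
            p = os.path.join(directory, "adt.csv")
            obj.to_df().to_csv(p)
            paths[name] = p
        elif name in ("hto", "contigs"):
            p = os.path.join(directory, f"{name}.csv")
            obj.to_csv(p, index=(name == "hto"))
            paths[name] = p
        elif name == "cohort":
            pe = os.path.join(directory, "expression.csv")
            pc = os.path.join(directory, "clinical.csv")
            obj.expression.to_csv(pe)
            obj.clinical.to_csv(pc)
            paths[name] = {"expression": pe, "clinical": pc}
        elif name == "signatures":
            paths[name] = tio.write_gmt(obj, os.path.join(directory, "signatures.gmt"))
        else:
            raise ValueError(f"unrecognized fixture kind: {name!r}")
    return paths
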