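"""ADT (antibody-derived tag) normalization, cluster profiles, and cluster linkage.

Raw ADT counts are depth-scaled (every cell rescaled to the mean per-cell
total), CLR-transformed within each cell, and standardized per antibody.
Per-cluster mean profiles then link stimulated to nonstimulated clusters by
Pearson correlation over a shared antibody subset; an expression-based
alternative links clusters by gene-set enrichment of marker sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .enrichment import EnrichmentParams, RankedGeneList, _es_from_masks, _p_and_nes, null_es


@dataclass
class LinkageMap:
    """Stimulated x nonstimulated cluster similarity with row-argmax pairing."""

    matrix: pd.DataFrame
    pairing: pd.Series


def depth_scale_adt(adata: ad.AnnData) -> ad.AnnData:
    """Rescale each cell so its ADT total equals the mean per-cell total."""
    X = np.asarray(adata.X, dtype=float)
    totals = X.sum(axis=1)
    if totals.sum() == 0:
        raise ValueError("all-zero ADT matrix")
    target = totals.mean()
    factors = np.divide(target, totals, out=np.zeros_like(totals), where=totals > 0)
    out = adata.copy()
    out.X = X * factors[:, None]
    out.uns["adt_normalization"] = "depth_scaled"
    return out


def clr_normalize(adata: ad.AnnData, scale: bool = True) -> ad.AnnData:
    """Centered log-ratio transform within each cell, then per-antibody scaling.

    value_i -> ln((value_i + 1) / geometric mean over the panel of (value + 1));
    the +1 pseudocount makes zero counts well defined. With ``scale`` each
    antibody is centered and unit-scaled across cells (zero-variance channels
    are left centered).
    """
    X = np.asarray(adata.X, dtype=float)
    if (X < 0).any():
        raise ValueError("ADT values must be non-negative")
    logx = np.log(X + 1.0)
    clr = logx - logx.mean(axis=1, keepdims=True)
    if scale:
        mu = clr.mean(axis=0)
        sd = clr.std(axis=0, ddof=1) if clr.shape[0] > 1 else np.zeros(clr.shape[1])
        clr = (clr - mu) / np.where(sd > 0, sd, 1.0)
    out = adata.copy()
    out.X = clr
    out.uns["adt_normalization"] = "clr_scaled" if scale else "clr"
    return out


def cluster_profiles(adata: ad.AnnData, cluster_labels=None) -> pd.DataFrame:
    """Mean normalized signal per cluster x antibody.

    ``cluster_labels`` defaults to ``adata.obs["cluster"]``; every cell must
    be labeled.
    """
    if cluster_labels is None:
        if "cluster" not in adata.obs:
            raise ValueError("no cluster labels supplied and none in obs")
        cluster_labels = adata.obs["cluster"]
    labels = pd.Series(np.asarray(cluster_labels), index=adata.obs_names)
    if labels.isna().any() or (labels == "").any():
        raise ValueError("every cell must carry a cluster label")
    df = pd.DataFrame(np.asarray(adata.X, dtype=float), index=adata.obs_names,
                      columns=adata.var_names)
    prof = df.groupby(labels, sort=True).mean()
    prof.index.name = "cluster"
    return prof


def link_by_correlation(stim: pd.DataFrame, nonstim: pd.DataFrame,
                        panel_subset=None) -> LinkageMap:
    """Pearson correlation between every (stim, nonstim) cluster profile pair.

    Profiles are correlated over ``panel_subset`` (default: the shared
    antibodies; at least 3 required). Zero-variance profiles yield missing
    correlations. Pairing is the row-wise argmax.
    """
    if panel_subset is None:
        panel_subset = stim.columns.intersection(nonstim.columns)
    panel_subset = list(panel_subset)
    if len(panel_subset) < 3:
        raise ValueError("need a shared antibody subset of size >= 3")
    a = stim[panel_subset].to_numpy(dtype=float)
    b = nonstim[panel_subset].to_numpy(dtype=float)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac ** 2).sum(axis=1))
    sb = np.sqrt((bc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (ac @ bc.T) / np.outer(sa, sb)
    corr[:, sb == 0] = np.nan
    corr[sa == 0, :] = np.nan
    matrix = pd.DataFrame(corr, index=stim.index, columns=nonstim.index)
    pairing = matrix.idxmax(axis=1, skipna=True)
    return LinkageMap(matrix=matrix, pairing=pairing)


def link_by_gsea(stim_expression_means: pd.DataFrame,
                 nonstim_marker_sets: dict[str, list[str]],
                 params: EnrichmentParams | None = None) -> LinkageMap:
    """Link stimulated clusters to nonstimulated marker sets by enrichment.

    For each stimulated cluster, genes are ranked by mean expression and each
    nonstimulated cluster's marker set is scored; the NES matrix and its
    row-argmax pairing are returned. ``stim_expression_means`` is genes x
    stimulated clusters.
    """
    params = params or EnrichmentParams(n_perm=1000)
    genes = stim_expression_means.index.to_numpy(dtype=object)
    base_masks = {}
    for name, members in nonstim_marker_sets.items():
        if not list(members):
            raise ValueError(f"marker set {name!r} is empty")
        mask = np.isin(genes, np.asarray(list(members), dtype=object))
        if mask.sum() == 0:
            raise ValueError(f"marker set {name!r} is disjoint from the universe")
        base_masks[name] = mask
    rows = {}
    seeds = np.random.SeedSequence(params.seed).spawn(stim_expression_means.shape[1])
    for (cluster, col), seed in zip(stim_expression_means.items(), seeds):
        stats_raw = col.to_numpy(dtype=float)
        order = np.lexsort((genes, -stats_raw))
        ranked = RankedGeneList(patient=str(cluster), genes=genes[order],
                                stats=stats_raw[order])
        rng = np.random.default_rng(seed)
        by_size: dict[int, np.ndarray] = {}
        nes_row = {}
        for name, base_mask in base_masks.items():
            mask = base_mask[order]
            k = int(mask.sum())
            es = float(_es_from_masks(ranked.stats, mask[None, :], params.p_w)[0][0])
            if k not in by_size:
                by_size[k] = null_es(ranked.stats, k, params.n_perm, rng, params.p_w)
            _, nes, _ = _p_and_nes(es, by_size[k])
            nes_row[name] = nes
        rows[cluster] = nes_row
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix = matrix.loc[stim_expression_means.columns, list(nonstim_marker_sets)]
    pairing = matrix.idxmax(axis=1)
    return LinkageMap(matrix=matrix, pairing=pairing)
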