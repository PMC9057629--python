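"""Derive gene signatures from single-cell expression and score cells by them.

Two derivations: one-vs-rest Wilcoxon rank-sum cluster markers (with a
minimum difference in expressing-cell fractions, biotype/prefix exclusions,
and p-then-effect ordering), and correlation signatures (top genes most
correlated with a reference gene such as a stemness, exhaustion, or
cytotoxicity marker). Cells are scored by the mean normalized expression of a
signature's genes.

Scoring and correlation use log1p of depth-scaled counts (per-cell total
rescaled to the cohort median); :func:`log_normalize` applies that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps

from . import io as tio


@dataclass(frozen=True)
class SignatureParams:
    min_diff_pct: float = 0.25
    top_n: int = 100
    excluded_prefixes: tuple[str, ...] = ("AP-",)
    excluded_biotypes: tuple[str, ...] = ("lincRNA", "miRNA")
    effect: str = "mean_diff"  # or "logfc"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_diff_pct <= 1.0):
            raise ValueError("min_diff_pct must lie in [0, 1]")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.effect not in ("mean_diff", "logfc"):
            raise ValueError("effect must be 'mean_diff' or 'logfc'")


@dataclass
class GeneSignature:
    """Ordered gene list with its derivation statistics and provenance."""

    name: str
    genes: list[str]
    stats: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")


def _dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)


def log_normalize(adata: ad.AnnData, target: float | None = None) -> ad.AnnData:
    """log1p of depth-scaled counts; per-cell total rescaled to the cohort median."""
    X = _dense(adata)
    totals = X.sum(axis=1)
    if target is None:
        target = float(np.median(totals[totals > 0])) if (totals > 0).any() else 1.0
    factors = np.divide(target, totals, out=np.zeros_like(totals), where=totals > 0)
    out = adata.copy()
    out.X = np.log1p(X * factors[:, None])
    out.uns["normalization"] = {"method": "log1p_depth_scaled", "target": target}
    return out


# ---------------------------------------------------------------------------
# Cluster markers (one-vs-rest Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

def marker_statistics(adata: ad.AnnData, cluster: str,
                      cluster_labels=None,
                      effect: str = "mean_diff") -> pd.DataFrame:
    """Per-gene one-vs-rest rank-sum statistics for one cluster.

    Two-sided Wilcoxon rank-sum (normal approximation with tie correction;
    exact enumeration when both groups have <= 8 cells), effect = difference
    in mean normalized expression (or log2 fold change), and the fraction of
    expressing (> 0) cells inside and outside the cluster.
    """
    labels = np.asarray(adata.obs["cluster"] if cluster_labels is None else cluster_labels)
    in_mask = labels == cluster
    if in_mask.sum() == 0:
        raise ValueError(f"cluster {cluster!r} not present")
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise ValueError("need >= 2 cells inside and outside the cluster")
    X = _dense(adata)
    x_in, x_out = X[in_mask], X[~in_mask]
    method = "exact" if max(len(x_in), len(x_out)) <= 8 else "asymptotic"
    res = sps.mannwhitneyu(x_in, x_out, axis=0, alternative="two-sided", method=method)
    mean_in, mean_out = x_in.mean(axis=0), x_out.mean(axis=0)
    if effect == "mean_diff":
        eff = mean_in - mean_out
    else:
        eff = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
    # rank-based direction: AUC = U1 / (n_in * n_out), > 0.5 means shifted up
    auc = np.atleast_1d(res.statistic) / (len(x_in) * len(x_out))
    return pd.DataFrame({
        "p": np.atleast_1d(res.pvalue),
        "effect": eff,
        "auc": auc,
        "pct_in": (x_in > 0).mean(axis=0),
        "pct_out": (x_out > 0).mean(axis=0),
    }, index=adata.var_names.copy())


def rank_sum_markers(adata: ad.AnnData, cluster: str,
                     params: SignatureParams | None = None,
                     cluster_labels=None) -> GeneSignature:
    """Marker signature of one cluster vs the rest.

    Keeps genes with (pct_in - pct_out) > min_diff_pct (strict) and a positive
    rank-based direction (AUC > 0.5, so membership is invariant under
    rank-preserving transforms), drops excluded biotypes
    (``adata.var['biotype']`` if present) and name prefixes, orders by
    ascending p then descending effect (gene id breaks remaining ties), and
    truncates to ``top_n``.
    """
    params = params or SignatureParams()
    st = marker_statistics(adata, cluster, cluster_labels, params.effect)
    keep = ((st["pct_in"] - st["pct_out"]) > params.min_diff_pct) & (st["auc"] > 0.5)
    names = st.index.astype(str)
    for prefix in params.excluded_prefixes:
        keep &= ~names.str.startswith(prefix)
    if "biotype" in adata.var:
        keep &= ~adata.var["biotype"].astype(str).isin(params.excluded_biotypes).to_numpy()
    st = st[keep.to_numpy() if hasattr(keep, "to_numpy") else keep]
    order = np.lexsort((st.index.to_numpy(dtype=object),
                        -st["effect"].to_numpy(), st["p"].to_numpy()))
    st = st.iloc[order[:params.top_n]]
    return GeneSignature(
        name=f"{cluster}_markers", genes=list(st.index), stats=st,
        meta={"derivation": "rank_sum_markers", "cluster": cluster,
              "min_diff_pct": params.min_diff_pct, "top_n": params.top_n},
    )


# ---------------------------------------------------------------------------
# Correlation signatures
# ---------------------------------------------------------------------------

def correlation_signature(adata: ad.AnnData, reference_gene: str, k: int = 25,
                          variable_genes=None, cells=None,
                          name: str | None = None) -> GeneSignature:
    """Top-k genes most Pearson-correlated with a reference gene.

    ``variable_genes`` restricts the candidate universe (the reference is
    always included and listed first); ``cells`` optionally restricts the
    cell subset. Ties in r are broken by gene id.
    """
    if not (1 <= k):
        raise ValueError("k must be >= 1")
    if reference_gene not in adata.var_names:
        raise ValueError(f"reference gene {reference_gene!r} absent from matrix")
    sub = adata[cells] if cells is not None else adata
    X = _dense(sub)
    genes = sub.var_names.to_numpy(dtype=object)
    if variable_genes is not None:
        universe = set(map(str, variable_genes)) | {reference_gene}
        keep = np.isin(genes, np.asarray(sorted(universe), dtype=object))
        X, genes = X[:, keep], genes[keep]
    ref = X[:, genes == reference_gene].ravel()
    if ref.std(ddof=1) == 0:
        raise ValueError("reference gene has zero variance on the chosen cells")
    xc = X - X.mean(axis=0)
    rc = ref - ref.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0)) * np.sqrt((rc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ rc) / denom
    valid = np.isfinite(r) & (genes != reference_gene)
    cand_genes, cand_r = genes[valid], r[valid]
    order = np.lexsort((cand_genes, -cand_r))
    chosen = [reference_gene, *cand_genes[order][: k - 1]]
    r_map = dict(zip(cand_genes, cand_r))
    stats = pd.DataFrame({"r": [1.0] + [r_map[g] for g in chosen[1:]]},
                         index=pd.Index(chosen, name="gene"))
    return GeneSignature(
        name=name or f"{reference_gene}_correlated", genes=chosen, stats=stats,
        meta={"derivation": "correlation_signature", "reference": reference_gene,
              "k": k},
    )


# ---------------------------------------------------------------------------
# Scoring and export
# ---------------------------------------------------------------------------

def score_cells(adata: ad.AnnData, signature: GeneSignature) -> pd.Series:
    """Per-cell mean normalized expression over the signature genes present.

    The number of signature genes missing from the matrix is reported in
    ``result.attrs["n_missing"]``; no overlap at all is an error.
    """
    present = [g for g in signature.genes if g in adata.var_names]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    X = _dense(adata[:, present])
    scores = pd.Series(X.mean(axis=1), index=adata.obs_names, name=signature.name)
    scores.attrs["n_missing"] = len(signature.genes) - len(present)
    return scores


def export_signatures(signatures, path: str) -> str:
    """Write signatures as GMT, one line per signature, order preserved."""
    signatures = list(signatures)
    if not signatures:
        raise ValueError("no signatures to export")
    return tio.write_gmt(signatures, path)
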