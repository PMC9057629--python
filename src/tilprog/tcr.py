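"""TCR clonotypes, clone frequencies, clonal composition, and inter-cluster sharing.

Clonotypes are keyed on the TRB CDR3 nucleotide sequence within each patient
(identical sequences in different patients are distinct clones); cells without
a productive TRB contig are unassigned ("NA"). Clone frequencies are relative
to each patient x tissue group, tumor-infiltrating cells separated from
normal-tissue cells. Sharing between two clusters is the count of distinct
clonotypes seen in both, tested against a within-patient label-permutation
null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "NA"


@dataclass
class ClonotypeSummary:
    n_cells: int
    n_assigned: int
    n_paired: int
    n_skipped_contigs: int = 0

    @property
    def assigned_pct(self) -> int:
        """Percent of cells with any TCR, rounded to integer percent."""
        return int(np.rint(100.0 * self.n_assigned / self.n_cells)) if self.n_cells else 0

    @property
    def paired_pct(self) -> int:
        """Percent of assigned cells with paired TRA+TRB, rounded to integer percent."""
        return int(np.rint(100.0 * self.n_paired / self.n_assigned)) if self.n_assigned else 0


@dataclass
class SharingResult:
    cluster_a: str
    cluster_b: str
    shared: int
    n_clones_a: int
    n_clones_b: int
    p: float
    n_perm: int
    seed: int
    test: str = "within_patient_label_permutation"


def build_clonotypes(contigs: pd.DataFrame, cell_meta: pd.DataFrame,
                     key: str = "trb") -> pd.DataFrame:
    """Assign a clonotype id per cell from a 10x-style contig table.

    ``contigs`` needs columns barcode, chain, cdr3, cdr3_nt, productive;
    malformed rows are skipped (count logged and recorded in
    ``result.attrs``). ``cell_meta`` is indexed by barcode with patient and
    tissue columns; barcodes absent from it are ignored. ``key`` is ``"trb"``
    (default, TRB CDR3 nt within patient) or ``"paired"`` (TRA+TRB).

    Returns one row per cell in ``cell_meta``: patient, tissue, trb_nt,
    tra_nt, paired flag, and clonotype_id ("NA" when unassigned).
    """
    required = {"barcode", "chain", "cdr3_nt", "productive"}
    if not required.issubset(contigs.columns):
        raise ValueError(f"contig table must have columns {sorted(required)}")
    ok = (contigs["barcode"].notna() & contigs["chain"].isin(["TRA", "TRB"])
          & contigs["cdr3_nt"].notna() & (contigs["cdr3_nt"].astype(str) != ""))
    productive = contigs["productive"].astype(str).str.lower().isin(["true", "1"])
    skipped = int((~ok).sum())
    if skipped:
        logger.info("skipping %d malformed contig rows", skipped)
    good = contigs[ok & productive]
    first = good.drop_duplicates(["barcode", "chain"]).pivot(
        index="barcode", columns="chain", values="cdr3_nt")

    table = cell_meta[["patient", "tissue"]].copy()
    table.index.name = "barcode"
    table["trb_nt"] = first["TRB"].reindex(table.index) if "TRB" in first else pd.NA
    table["tra_nt"] = first["TRA"].reindex(table.index) if "TRA" in first else pd.NA
    table["paired"] = table["trb_nt"].notna() & table["tra_nt"].notna()

    if key == "trb":
        has_key = table["trb_nt"].notna()
        key_vals = list(zip(table["patient"], table["trb_nt"]))
    elif key == "paired":
        has_key = table["trb_nt"].notna() & table["tra_nt"].notna()
        key_vals = list(zip(table["patient"], table["trb_nt"], table["tra_nt"]))
    else:
        raise ValueError("key must be 'trb' or 'paired'")
    codes = pd.Series(
        pd.factorize(pd.Series(key_vals, index=table.index)[has_key])[0],
        index=table.index[has_key])
    table["clonotype_id"] = UNASSIGNED
    table.loc[has_key, "clonotype_id"] = [
        f"{p}_ct{c:05d}" for p, c in zip(table.loc[has_key, "patient"], codes)]
    table.attrs["n_skipped_contigs"] = skipped
    return table


def summarize_clonotypes(table: pd.DataFrame) -> ClonotypeSummary:
    """Assigned-any and paired-of-assigned counts with integer-percent fractions."""
    assigned_any = table["trb_nt"].notna() | table["tra_nt"].notna()
    return ClonotypeSummary(
        n_cells=len(table),
        n_assigned=int(assigned_any.sum()),
        n_paired=int(table["paired"].sum()),
        n_skipped_contigs=int(table.attrs.get("n_skipped_contigs", 0)),
    )


def clone_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell clone frequency relative to its patient x tissue group.

    frequency = (cells in the group sharing the clonotype) / (group size);
    unassigned cells are excluded from both numerator and denominator.
    """
    assigned = table[table["clonotype_id"] != UNASSIGNED].copy()
    if assigned.empty:
        return assigned.assign(group=pd.Series(dtype=str),
                               clone_size=pd.Series(dtype=int),
                               frequency=pd.Series(dtype=float))
    assigned["group"] = assigned["patient"].astype(str) + "|" + assigned["tissue"].astype(str)
    group_size = assigned.groupby("group")["clonotype_id"].transform("size")
    clone_size = assigned.groupby(["group", "clonotype_id"])["clonotype_id"].transform("size")
    assigned["clone_size"] = clone_size.astype(int)
    assigned["frequency"] = clone_size / group_size
    return assigned[["patient", "tissue", "clonotype_id", "group", "clone_size", "frequency"]]


def clonal_composition(table: pd.DataFrame, cluster_labels: pd.Series,
                       bins: tuple = ((1, 1), (2, 5), (6, np.inf))) -> pd.DataFrame:
    """Per-cluster proportion of cells by clone-size expansion bin.

    ``bins`` are inclusive (lo, hi) clone-size intervals; they must not
    overlap. Proportions are over assigned cells and sum to 1 per cluster.
    """
    edges = sorted(bins)
    for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
        if hi1 >= lo2:
            raise ValueError("expansion bins overlap")
    freq = clone_frequencies(table)
    labels = pd.Series(cluster_labels).reindex(freq.index)
    names = [f"{int(lo)}" if lo == hi else
             (f"{int(lo)}+" if np.isinf(hi) else f"{int(lo)}-{int(hi)}")
             for lo, hi in bins]
    rows = {}
    for cluster, idx in freq.groupby(labels).groups.items():
        sizes = freq.loc[idx, "clone_size"]
        rows[cluster] = [((sizes >= lo) & (sizes <= hi)).mean() for lo, hi in bins]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    out.index.name = "cluster"
    return out


def tcr_sharing_test(table: pd.DataFrame, cluster_labels: pd.Series,
                     cluster_a: str, cluster_b: str,
                     n_perm: int = 10_000, seed: int = 0) -> SharingResult:
    """Count clonotypes shared by two clusters and test by label permutation.

    Observed statistic: number of distinct clonotypes (within patient, TRB
    keyed) present in both clusters. Null: cluster labels permuted among the
    two clusters' assigned cells within each patient. p uses the add-one
    estimator (1 + #null >= observed) / (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p", stacklevel=2)
    labels = pd.Series(cluster_labels).reindex(table.index)
    in_ab = labels.isin([cluster_a, cluster_b]) & (table["clonotype_id"] != UNASSIGNED)
    if not (labels == cluster_a).any() or not (labels == cluster_b).any():
        raise ValueError("both clusters must be non-empty")
    sub = table[in_ab]
    if sub.empty:
        return SharingResult(cluster_a=cluster_a, cluster_b=cluster_b, shared=0,
                             n_clones_a=0, n_clones_b=0, p=1.0, n_perm=n_perm,
                             seed=seed)
    sub_labels = labels[in_ab].to_numpy()
    clones, _ = pd.factorize(sub["clonotype_id"])
    patients, _ = pd.factorize(sub["patient"])
    is_a = sub_labels == cluster_a

    def _shared(a_mask: np.ndarray) -> int:
        in_a = np.zeros(clones.max() + 1, dtype=bool)
        in_b = np.zeros(clones.max() + 1, dtype=bool)
        in_a[clones[a_mask]] = True
        in_b[clones[~a_mask]] = True
        return int((in_a & in_b).sum())

    observed = _shared(is_a)
    rng = np.random.default_rng(seed)
    order_by_patient = [np.flatnonzero(patients == p) for p in np.unique(patients)]
    exceed = 0
    perm_mask = is_a.copy()
    for _ in range(n_perm):
        for idx in order_by_patient:
            perm_mask[idx] = is_a[idx][rng.permutation(len(idx))]
        if _shared(perm_mask) >= observed:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    n_a = len(set(clones[is_a]))
    n_b = len(set(clones[~is_a]))
    return SharingResult(cluster_a=cluster_a, cluster_b=cluster_b, shared=observed,
                         n_clones_a=n_a, n_clones_b=n_b, p=p, n_perm=n_perm,
                         seed=seed)
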