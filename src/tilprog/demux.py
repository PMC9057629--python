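"""Hashtag (HTO) demultiplexing: assign each barcode to a sample, negative, or doublet.

Each barcode's HTO counts are rescaled to a fixed total (100 by default);
identity goes to the most highly expressed tag, with operational thresholds
for calling negatives (weak top tag or too few raw UMIs) and doublets
(strong second tag, or a tie at the top).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NEGATIVE = "negative"
DOUBLET = "doublet"


@dataclass(frozen=True)
class DemuxParams:
    """Thresholds on the normalized (0..normalized_total) scale."""

    normalized_total: float = 100.0
    singlet_min: float = 60.0
    doublet_second_min: float = 30.0
    min_total_raw: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.doublet_second_min < self.singlet_min <= self.normalized_total):
            raise ValueError(
                "require 0 < doublet_second_min < singlet_min <= normalized_total")


def normalize_tags(raw: pd.DataFrame, params: DemuxParams | None = None) -> pd.DataFrame:
    """Rescale each barcode's tag counts to sum to ``normalized_total``.

    ``raw`` is tags x barcodes. Zero-total barcodes are left all-zero (they
    are labeled negative downstream). Raw totals are kept in
    ``result.attrs["raw_totals"]`` for the min-UMI rule.
    """
    params = params or DemuxParams()
    if raw.shape[0] < 1:
        raise ValueError("need at least one tag")
    if raw.index.duplicated().any() or raw.columns.duplicated().any():
        raise ValueError("duplicate tag or barcode identifiers")
    values = raw.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValueError("counts must be finite and non-negative")
    totals = values.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    normalized = values / safe * params.normalized_total
    out = pd.DataFrame(normalized, index=raw.index, columns=raw.columns)
    out.attrs["raw_totals"] = pd.Series(totals, index=raw.columns)
    out.attrs["normalized_total"] = params.normalized_total
    return out


def assign_barcodes(normalized: pd.DataFrame,
                    params: DemuxParams | None = None,
                    raw_totals: pd.Series | None = None) -> pd.DataFrame:
    """Label every barcode as a tag id, ``negative``, or ``doublet``.

    Rules on the normalized scale: argmax tag if top >= singlet_min and
    second < doublet_second_min; doublet if second >= doublet_second_min
    (a tie at the top is a doublet); negative if top < singlet_min or the
    raw total is below min_total_raw.
    """
    params = params or DemuxParams()
    if raw_totals is None:
        raw_totals = normalized.attrs.get("raw_totals")
    values = normalized.to_numpy(dtype=float)
    n_tags, n_bc = values.shape
    top_idx = values.argmax(axis=0)
    top = values[top_idx, np.arange(n_bc)]
    if n_tags > 1:
        part = np.partition(values, n_tags - 2, axis=0)
        second = part[n_tags - 2, :]
    else:
        second = np.zeros(n_bc)
    labels = np.array([normalized.index[i] for i in top_idx], dtype=object)
    labels[top < params.singlet_min] = NEGATIVE
    labels[second >= params.doublet_second_min] = DOUBLET
    if raw_totals is not None:
        low = np.asarray(raw_totals.reindex(normalized.columns)) < params.min_total_raw
        labels[low] = NEGATIVE
    result = pd.DataFrame({
        "label": labels,
        "top_tag": [normalized.index[i] for i in top_idx],
        "top_value": top,
        "second_value": second,
    }, index=normalized.columns.copy())
    result.index.name = "barcode"
    return result


def demux(raw: pd.DataFrame, params: DemuxParams | None = None) -> pd.DataFrame:
    """Normalize then assign in one step."""
    params = params or DemuxParams()
    normalized = normalize_tags(raw, params)
    return assign_barcodes(normalized, params)


def demux_summary(result: pd.DataFrame) -> pd.Series:
    """Counts per label; sums to the number of barcodes."""
    if len(result) == 0:
        return pd.Series(dtype=int)
    return result["label"].value_counts()
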