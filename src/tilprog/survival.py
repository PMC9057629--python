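"""Kaplan-Meier estimation and log-rank comparison between enrichment classes.

Product-limit curves and the two-group log-rank test are delegated to
lifelines; this module adds the cohort-facing conveniences: stratifying the
enriched-vs-depleted comparison to a stage subset, stage-composition
summaries per class, and overlap between two classifications. Ties between
an event and a censoring at the same time follow the standard convention
(events first).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .enrichment import DEPLETED, ENRICHED

_STAGE_NUM = {"I": 1, "II": 2, "III": 3, "IV": 4}
_STAGE_RE = re.compile(r"(IV|III|II|I)")


@dataclass
class KMCurve:
    """Step values of the product-limit estimator at the distinct event times."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass
class LogRankResult:
    chisq: float
    df: int
    p: float
    flagged: bool = False


@dataclass
class StratifiedResult:
    curves: dict
    test: LogRankResult | None
    stages: list[str]
    flagged: bool = False


@dataclass
class OverlapResult:
    n_both: int
    n_a: int
    n_b: int
    percent: int
    crosstab: pd.DataFrame = field(repr=False, default=None)


def parse_stage(value: str) -> str | None:
    """Reduce an AJCC-like string ("Stage IIA") to its I-IV stage group."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    m = _STAGE_RE.search(str(value).upper())
    return m.group(1) if m else None


def km_estimate(times, events, group: str = "all") -> KMCurve:
    """Product-limit survival estimate for one group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("group is empty")
    if (times < 0).any() or not np.isfinite(times).all():
        raise ValueError("times must be finite and non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    # number at risk just before each event time
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return KMCurve(group=group, times=event_times, survival=surv,
                   at_risk=at_risk, n=len(times))


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test (chi-square, df=1).

    Degenerate inputs (no events, or zero variance throughout) are flagged
    with chi-square 0 and p = 1 rather than raising.
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return LogRankResult(chisq=0.0, df=1, p=1.0, flagged=True)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    chisq = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chisq):
        return LogRankResult(chisq=0.0, df=1, p=1.0, flagged=True)
    return LogRankResult(chisq=chisq, df=1, p=p)


def stratified_survival(clinical: pd.DataFrame, classification: pd.Series,
                        stages_subset=None) -> StratifiedResult:
    """Enriched-vs-depleted survival comparison within a stage subset.

    ``clinical`` carries os_months / os_event / stage indexed by patient;
    ``classification`` maps patients to enriched/depleted/neither ("neither"
    is excluded from the test). An empty class after stage restriction is
    flagged and no test is run.
    """
    df = clinical.copy()
    df["label"] = classification.reindex(df.index)
    df["stage_group"] = df["stage"].map(parse_stage)
    if stages_subset is None:
        stages = sorted(set(df["stage_group"].dropna()), key=_STAGE_NUM.get)
    else:
        stages = [parse_stage(s) for s in stages_subset]
        df = df[df["stage_group"].isin(stages)]
    enriched = df[df["label"] == ENRICHED]
    depleted = df[df["label"] == DEPLETED]
    if len(enriched) == 0 or len(depleted) == 0:
        return StratifiedResult(curves={}, test=None, stages=stages, flagged=True)
    curves = {
        ENRICHED: km_estimate(enriched["os_months"], enriched["os_event"], ENRICHED),
        DEPLETED: km_estimate(depleted["os_months"], depleted["os_event"], DEPLETED),
    }
    test = logrank_test(enriched["os_months"], enriched["os_event"],
                        depleted["os_months"], depleted["os_event"])
    return StratifiedResult(curves=curves, test=test, stages=stages)


def stage_composition(classification: pd.Series, stages: pd.Series):
    """Per-class stage proportions (each class sums to 1) and mean numeric stage.

    Patients with unparseable stage are excluded (count logged).
    """
    groups = pd.Series(stages).map(parse_stage)
    dropped = groups.isna().sum()
    if dropped:
        import logging

        logging.getLogger(__name__).info("excluding %d patients without stage", dropped)
    df = pd.DataFrame({"label": pd.Series(classification), "stage": groups}).dropna()
    levels = ["I", "II", "III", "IV"]
    prop = (df.groupby("label")["stage"].value_counts(normalize=True)
            .unstack(fill_value=0.0).reindex(columns=levels, fill_value=0.0))
    mean_stage = df.groupby("label")["stage"].apply(
        lambda s: s.map(_STAGE_NUM).mean())
    return prop, mean_stage


def classification_overlap(class_a: pd.Series, class_b: pd.Series) -> OverlapResult:
    """Overlap of the enriched patients of two classifications.

    percent = round(100 * |A and B| / |A|) where A, B are the enriched sets.
    Both classifications must cover the same patient universe.
    """
    a, b = pd.Series(class_a), pd.Series(class_b)
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("classifications cover different patient universes")
    set_a = set(a.index[a == ENRICHED])
    set_b = set(b.index[b == ENRICHED])
    n_both = len(set_a & set_b)
    percent = int(np.rint(100.0 * n_both / len(set_a))) if set_a else 0
    crosstab = pd.crosstab(a, b.reindex(a.index))
    return OverlapResult(n_both=n_both, n_a=len(set_a), n_b=len(set_b),
                         percent=percent, crosstab=crosstab)
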