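import numpy as np
import pytest

import tilprog as tp


@pytest.fixture(scope="session")
def mux_run():
    """One simulated hashed run shared across tests (defaults, seed 11)."""
    cfg = tp.MultiplexSimConfig(n_cells=800, seed=11)
    return cfg, tp.simulate_multiplexed_run(cfg)


@pytest.fixture(scope="session")
def cohort_sim():
    """One simulated bulk cohort with planted signal (seed 7)."""
    cfg = tp.CohortSimConfig(n_patients=150, n_genes=500, seed=7)
    return cfg, tp.simulate_bulk_cohort(cfg)


def binom_bounds(n: int, p: float, level: float = 0.99):
    """Exact central binomial interval for a count at confidence ``level``."""
    from scipy.stats import binom

    lo = binom.ppf((1 - level) / 2, n, p)
    hi = binom.ppf(1 - (1 - level) / 2, n, p)
    return lo, hi


def ks_running_oracle(n: int, hits, weights=None):
    """Brute-force KS running sum: independent oracle for the enrichment score.

    ``hits`` are 0-based positions; uniform hit weights unless ``weights``
    (aligned with hits) are given. Returns the signed extremum.
    """
    hitset = set(int(h) for h in hits)
    k = len(hitset)
    if weights is None:
        w = {h: 1.0 / k for h in hitset}
    else:
        tot = float(np.sum(weights))
        w = {h: float(wi) / tot for h, wi in zip(hits, weights)}
    run, vals = 0.0, []
    for i in range(n):
        run += w[i] if i in hitset else -1.0 / (n - k)
        vals.append(run)
    vals = np.array(vals)
    return float(vals[np.argmax(np.abs(vals))])


def logrank_oracle(ta, ea, tb, eb):
    """Observed-minus-expected log-rank chi-square with hypergeometric variance."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, int)
    tb, eb = np.asarray(tb, float), np.asarray(eb, int)
    pooled = np.concatenate([ta[ea == 1], tb[eb == 1]])
    o1 = e1 = v = 0.0
    for t in np.unique(pooled):
        n1, n2 = (ta >= t).sum(), (tb >= t).sum()
        n = n1 + n2
        d1 = ((ta == t) & (ea == 1)).sum()
        d = d1 + ((tb == t) & (eb == 1)).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj
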