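"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own algorithms: full enumeration for
the exact rank-sum test, exhaustive threshold scans for separation metrics
and cutoffs, and direct pairwise counting for the AUC.
"""

import itertools

import numpy as np
from scipy.stats import rankdata


def mw_exact_oracle(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all label assignments."""
    vals = list(x) + list(y)
    n1 = len(x)
    ranks = rankdata(vals)
    mu = n1 * (len(vals) + 1) / 2.0
    dev = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(vals)), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def threshold_scan_oracle(values, labels):
    """Exhaustive scan over all thresholds and both orientations.

    Returns (sens at 100% spec, spec at 100% sens, complete flag,
    best Youden threshold, best Youden score) with percentages in [0, 100].
    """
    values = [float(v) for v in values]
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    distinct = sorted(set(values))
    mids = [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
    cands = [distinct[0] - 1] + mids + [distinct[-1] + 1]
    best_sens = best_spec = 0.0
    complete = False
    best_youden = (-1.0, None)
    for orient in ("high", "low"):
        for t in cands:
            if orient == "high":
                sens = np.mean([v >= t for v in pos])
                spec = np.mean([v < t for v in neg])
            else:
                sens = np.mean([v <= t for v in pos])
                spec = np.mean([v > t for v in neg])
            if spec == 1.0:
                best_sens = max(best_sens, sens)
            if sens == 1.0:
                best_spec = max(best_spec, spec)
            if sens == 1.0 and spec == 1.0:
                complete = True
            if sens + spec > best_youden[0] + 1e-12:
                best_youden = (sens + spec, t)
    return 100 * best_sens, 100 * best_spec, complete, best_youden[1], best_youden[0]


def auc_pairwise_oracle(scores, labels) -> float:
    """AUC by direct pairwise comparison with ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else 0.5 if a == b else 0.0
    return total / (len(pos) * len(neg))
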