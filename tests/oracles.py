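"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — exhaustive enumeration and plain
Python loops — and shares no code path with the package implementation.
"""

import numpy as np


def brute_force_stump(X, y, w):
    """Exhaustively enumerate every (feature, midpoint) stump.

    Returns (loss, feature, threshold, left_value, right_value) of the
    minimum-weighted-squared-error stump, ties broken by lowest feature then
    lowest threshold.  Leaf values are weighted label means.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    best = None
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (a + b)
            mask = X[:, f] <= thr
            lw, rw = w[mask].sum(), w[~mask].sum()
            lv = float(np.dot(w[mask], y[mask]) / lw) if lw > 0 else 0.0
            rv = float(np.dot(w[~mask], y[~mask]) / rw) if rw > 0 else 0.0
            pred = np.where(mask, lv, rv)
            loss = float(np.dot(w, (y - pred) ** 2))
            key = (loss, f, thr)
            if best is None or key < (best[0], best[1], best[2]):
                best = (loss, f, thr, lv, rv)
    if best is None:  # all columns constant
        mean = float(np.dot(w, y) / w.sum())
        loss = float(np.dot(w, (y - mean) ** 2))
        best = (loss, 0, 0.0, mean, mean)
    return best


def pairwise_auroc(labels, scores):
    """AUROC as the explicit average over all positive-negative pairs."""
    labels = np.asarray(labels, float)
    scores = np.asarray(scores, float)
    pos = scores[labels > 0]
    neg = scores[labels < 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def loop_predict_raw(stumps, x):
    """Ensemble total recomputed stump by stump from the serialised fields."""
    out = 0.0
    for s in stumps:
        out += s.left_value if x[s.feature] <= s.threshold else s.right_value
    return out


def stump_loss(stump, X, y, w):
    """Naive weighted squared error achieved by a fitted stump."""
    pred = np.where(np.asarray(X, float)[:, stump.feature] <= stump.threshold,
                    stump.left_value, stump.right_value)
    return float(np.dot(w, (np.asarray(y, float) - pred) ** 2))
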