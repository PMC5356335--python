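"""Weighted regression stumps — the weak learning algorithm inside Gentle Boost.

A stump is a depth-1 regression tree: one feature, one threshold, two real
leaf values.  Fitting minimises the weighted squared error
``sum_i w_i (y_i - f(x_i))**2`` over every (feature, threshold) pair, with
leaf values the weighted label means on each side — the weighted-least-squares
optimum.  For ±1 labels under probability weights both leaves therefore lie in
[−1, 1], giving the real-valued "confidence" predictions boosting relies on.

Thresholds are scanned at midpoints between consecutive distinct sorted
feature values; an instance sitting exactly on the threshold goes left.  Ties
in loss break deterministically by (lowest feature index, lowest threshold) so
training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import LabeledDataset

__all__ = ["Stump", "fit_stump", "stump_predict"]

# Relative slack for the vectorised split screen.  Candidate splits whose
# screened loss is within this slack of the screened minimum are re-evaluated
# with the naive loss formula, so the selected stump attains the exact minimum
# of the naive enumeration despite cumulative-sum rounding.
_SCREEN_RTOL = 1e-9


@dataclass(frozen=True)
class Stump:
    feature: int
    threshold: float
    left_value: float   # response where x[feature] <= threshold
    right_value: float  # response where x[feature] >  threshold
    degenerate: bool = False

    def to_record(self) -> dict:
        return {
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "left_value": float(self.left_value),
            "right_value": float(self.right_value),
        }

    @staticmethod
    def from_record(rec: dict) -> "Stump":
        return Stump(
            int(rec["feature"]), float(rec["threshold"]),
            float(rec["left_value"]), float(rec["right_value"]),
            bool(rec.get("degenerate", False)),
        )


def _exact_split_loss(col, y, w, threshold):
    """Naive weighted squared error of the best stump at a given threshold."""
    mask = col <= threshold
    lw, rw = w[mask].sum(), w[~mask].sum()
    lv = float(np.dot(w[mask], y[mask]) / lw) if lw > 0 else 0.0
    rv = float(np.dot(w[~mask], y[~mask]) / rw) if rw > 0 else 0.0
    pred = np.where(mask, lv, rv)
    return float(np.dot(w, (y - pred) ** 2)), lv, rv


def fit_stump(data: LabeledDataset, w) -> Stump:
    """Fit the weighted-least-squares optimal regression stump.

    Returns the loss-minimising stump; if every feature column is constant the
    stump is degenerate with both leaves equal to the weighted mean of ``y``.
    """
    X, y = data.features, data.labels
    w = np.asarray(w, dtype=float)
    if w.shape != (data.n,):
        raise ValueError("weight vector length must match N")
    base = float(np.dot(w, y * y))
    wy = w * y

    per_feature: list[tuple[int, np.ndarray, np.ndarray]] = []
    lo = np.inf
    for f in range(data.d):
        col = X[:, f]
        order = np.argsort(col, kind="stable")
        xs = col[order]
        cw = np.cumsum(w[order])
        cwy = np.cumsum(wy[order])
        cut = np.flatnonzero(xs[:-1] < xs[1:])
        if cut.size == 0:
            continue
        lw, lwy = cw[cut], cwy[cut]
        rw, rwy = cw[-1] - lw, cwy[-1] - lwy
        gain = np.zeros(cut.size)
        np.divide(lwy**2, lw, out=gain, where=lw > 0)
        gain += np.where(rw > 0, rwy**2 / np.where(rw > 0, rw, 1.0), 0.0)
        loss = base - gain
        thrs = 0.5 * (xs[cut] + xs[cut + 1])
        per_feature.append((f, thrs, loss))
        lo = min(lo, float(loss.min()))

    if not per_feature:
        mean = float(np.dot(w, y) / w.sum())
        return Stump(0, 0.0, mean, mean, degenerate=True)

    tol = _SCREEN_RTOL * (1.0 + abs(lo) + base)
    best = None  # (loss, feature, threshold, lv, rv)
    for f, thrs, loss in per_feature:
        for k in np.flatnonzero(loss <= lo + tol):
            thr = float(thrs[k])
            exact, lv, rv = _exact_split_loss(X[:, f], y, w, thr)
            key = (exact, f, thr)
            if best is None or key < (best[0], best[1], best[2]):
                best = (exact, f, thr, lv, rv)
    _, f, thr, lv, rv = best
    return Stump(f, thr, lv, rv)


def stump_predict(stump: Stump, x):
    """Real-valued stump response for a single vector or an (N, d) matrix."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return stump.left_value if x[stump.feature] <= stump.threshold \
            else stump.right_value
    col = x[:, stump.feature]
    return np.where(col <= stump.threshold, stump.left_value, stump.right_value)
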