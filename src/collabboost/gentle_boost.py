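"""Gentle Boost: additive stump ensembles with multiplicative weight updates.

Each round fits a regression stump by weighted least squares and reweights the
data by ``w_i <- w_i * exp(-y_i f_t(x_i))`` (renormalised to a probability
distribution), so instances the latest stump gets wrong gain relative weight.
The ensemble output ``F(x)`` is the plain sum of the T stump responses; a
probability comes from the sigmoid ``g(z) = 1 / (1 + exp(-z))`` and the hard
label from ``sign``.  No shrinkage or per-round reweighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledDataset
from .weak_learner import Stump, fit_stump, stump_predict

__all__ = [
    "GentleBoostModel",
    "init_weights",
    "boost_round",
    "train",
    "predict_raw",
    "predict_proba",
    "sigmoid",
    "empirical_exp_loss",
]

# floor applied to weights before renormalisation; keeps the probability
# distribution invariant in float arithmetic on long runs
_WEIGHT_FLOOR = 1e-300


@dataclass
class GentleBoostModel:
    """An ordered list of fitted stumps plus training bookkeeping."""

    stumps: list = field(default_factory=list)
    training_ids: np.ndarray = None  # type: ignore[assignment]
    weight_trace: list = None  # type: ignore[assignment]

    @property
    def T(self) -> int:
        return len(self.stumps)

    def to_record(self) -> dict:
        return {
            "T": self.T,
            "stumps": [s.to_record() for s in self.stumps],
            "training_ids": [int(i) for i in (
                self.training_ids if self.training_ids is not None else []
            )],
        }

    @staticmethod
    def from_record(rec: dict) -> "GentleBoostModel":
        return GentleBoostModel(
            [Stump.from_record(r) for r in rec["stumps"]],
            np.asarray(rec.get("training_ids", []), dtype=int),
        )


def init_weights(N: int) -> np.ndarray:
    """Uniform probability weights 1/N."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return np.full(N, 1.0 / N)


def boost_round(
    model: GentleBoostModel, data: LabeledDataset, w: np.ndarray
) -> tuple[GentleBoostModel, np.ndarray]:
    """One boosting iteration: fit a stump, append it, reweight the data."""
    stump = fit_stump(data, w)
    model.stumps.append(stump)
    pred = stump_predict(stump, data.features)
    w_new = w * np.exp(-data.labels * pred)
    w_new = np.maximum(w_new, _WEIGHT_FLOOR)
    w_new /= w_new.sum()
    return model, w_new


def train(
    data: LabeledDataset, T: int, record_weights: bool = False
) -> GentleBoostModel:
    """Train a T-round Gentle Boost ensemble; deterministic for fixed data."""
    if T < 1:
        raise ValueError("T must be >= 1")
    data.require_both_classes()
    model = GentleBoostModel([], np.asarray(data.ids).copy(),
                             [] if record_weights else None)
    w = init_weights(data.n)
    for _ in range(T):
        if record_weights:
            model.weight_trace.append(w.copy())
        model, w = boost_round(model, data, w)
    if record_weights:
        model.weight_trace.append(w.copy())
    return model


def predict_raw(model: GentleBoostModel, x):
    """Raw ensemble output F(x) = sum_t f_t(x); scalar or per-row vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return float(sum(stump_predict(s, x) for s in model.stumps))
    out = np.zeros(x.shape[0])
    for s in model.stumps:
        out += stump_predict(s, x)
    return out


def sigmoid(z):
    """Overflow-safe logistic function g(z) = 1 / (1 + exp(-z))."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def predict_proba(model: GentleBoostModel, x):
    """Class-probability view of F(x); the label is positive iff > 0.5."""
    return sigmoid(predict_raw(model, x))


def empirical_exp_loss(model: GentleBoostModel, data: LabeledDataset) -> float:
    """Mean exponential loss (1/N) sum_i exp(-y_i F(x_i))."""
    F = predict_raw(model, data.features)
    return float(np.mean(np.exp(-data.labels * F)))
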