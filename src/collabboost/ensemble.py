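"""The bi-level multi-model: S subbagged Gentle Boost ensembles, averaged.

``L = S*T`` weak learners are grouped into S boosting ensembles of T stumps,
each trained on a stratified subsample.  The multi-model output averages the
per-ensemble totals, ``Φ(x) = (1/S) Σ_j F^(j)(x)``, mimicking majority voting
with real-valued votes; ``sign(Φ)`` is the predicted label (sign(0) := +1)
and ``g(Φ)`` the probability view.  Collaboration is dispatched by mode:
``none`` trains the ensembles independently, ``wclb`` trains them in
lock-step with per-round exchanges, and ``sclb`` trains independently and
then runs the pairwise exchange-retrain-revert session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gentle_boost, sclb, wclb
from .datasets import LabeledDataset, SubsamplePlan, stratified_subsample
from .gentle_boost import GentleBoostModel, predict_raw, sigmoid

__all__ = [
    "SubbaggedModel",
    "train_multimodel",
    "predict_multimodel",
    "predict_phi",
    "model_to_dict",
    "model_from_dict",
]

MODES = ("none", "wclb", "sclb")


@dataclass
class SubbaggedModel:
    """S trained Gentle Boost ensembles plus their sampling plan and config."""

    ensembles: list
    plan: SubsamplePlan
    mode: str
    config: dict = field(default_factory=dict)
    feature_names: list = field(default_factory=list)

    @property
    def S(self) -> int:
        return len(self.ensembles)

    @property
    def T(self) -> int:
        return self.ensembles[0].T if self.ensembles else 0


def predict_phi(ensembles, X) -> np.ndarray | float:
    """Averaged raw output Φ over a list of Gentle Boost models."""
    scalar = np.asarray(X).ndim == 1
    outs = [predict_raw(m, X) for m in ensembles]
    phi = sum(outs) / len(outs)
    return float(phi) if scalar else phi


def train_multimodel(
    data: LabeledDataset,
    S: int,
    T: int,
    eta: float,
    mode: str = "none",
    *,
    p_c: float = 0.0,
    n_exc: int = 1,
    seed: int = 0,
    wclb_transfer: str = "copy",
    sclb_passes: int = 1,
    sclb_strict: bool = False,
    sclb_metric: str = "zero_one",
) -> tuple[SubbaggedModel, wclb.CollaborationLog]:
    """Train the full multi-model; deterministic for a fixed seed."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode != "none" and S < 2:
        raise ValueError("collaboration requires S >= 2 ensembles")
    if S < 1:
        raise ValueError("S must be >= 1")
    plan = stratified_subsample(data, S, eta, seed)
    config = {
        "S": S, "T": T, "eta": eta, "mode": mode,
        "p_c": p_c, "n_exc": n_exc, "seed": seed,
    }
    if mode == "wclb":
        cfg = wclb.WclbConfig(p_c=p_c, n_exc=n_exc, rng_seed=seed,
                              transfer=wclb_transfer)
        boosters, log = wclb.train_wclb(data, plan, T, cfg)
        ensembles = [b.model for b in boosters]
    else:
        ensembles = [gentle_boost.train(data.take(idx), T)
                     for idx in plan.subsets]
        if mode == "sclb":
            subsets = [data.take(idx) for idx in plan.subsets]
            ensembles, _, log = sclb.sclb_run(
                ensembles, data, subsets, n_exc, T,
                passes=sclb_passes, strict=sclb_strict, metric=sclb_metric,
            )
        else:
            log = wclb.CollaborationLog(mode="none")
    model = SubbaggedModel(ensembles, plan, mode, config,
                           list(data.feature_names))
    return model, log


def predict_multimodel(model: SubbaggedModel, x):
    """Return (phi, label, proba) for one instance or arrays for a matrix."""
    phi = predict_phi(model.ensembles, x)
    if np.isscalar(phi):
        label = 1.0 if phi >= 0 else -1.0
        return phi, label, sigmoid(phi)
    labels = np.where(np.asarray(phi) >= 0, 1.0, -1.0)
    return phi, labels, sigmoid(phi)


def model_to_dict(model: SubbaggedModel) -> dict:
    return {
        "S": model.S,
        "T": model.T,
        "eta": model.plan.eta,
        "mode": model.mode,
        "seed": model.plan.seed,
        "config": model.config,
        "feature_names": list(model.feature_names),
        "ensembles": [m.to_record() for m in model.ensembles],
        "plan": [[int(i) for i in idx] for idx in model.plan.subsets],
    }


def model_from_dict(d: dict) -> SubbaggedModel:
    plan = SubsamplePlan(
        tuple(np.asarray(idx, dtype=int) for idx in d["plan"]),
        float(d["eta"]), int(d["seed"]),
    )
    ensembles = [GentleBoostModel.from_record(r) for r in d["ensembles"]]
    return SubbaggedModel(ensembles, plan, d["mode"], dict(d.get("config", {})),
                          list(d.get("feature_names", [])))
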