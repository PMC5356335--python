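"""Strong-learner collaboration (S-CLB): exchange-retrain-revert between boosters.

S-CLB runs after all S ensembles are fully trained.  Pairs are visited in
sequence order — initiator j against each of its predecessors k < j, for
S(S−1)/2 pairs in one pass — and each pair goes through three steps:

1. the initiator selects its ``n_exc`` weakest-conviction correctly classified
   instances, the predecessor its ``n_exc`` strongest-conviction correct ones;
2. the two selections are swapped between the subsets;
3. both ensembles are retrained from scratch on the modified subsets.

The exchange is kept only if the multi-model's empirical error on the full
training set does not increase; otherwise subsets and models revert to the
pre-pair state.  This accept-on-non-increase rule makes the empirical-error
trace over the pair counter τ non-increasing by construction.  Ties (equal
error) are accepted by default, which admits margin-improving neutral moves;
a ``strict`` switch requires a strict decrease.  The error may alternatively
be measured with the exponential loss of the averaged output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledDataset
from .gentle_boost import GentleBoostModel, train
from .wclb import (CollaborationLog, ExchangeEvent, select_strongest_correct,
                   select_weakest_correct)

__all__ = ["SclbState", "sclb_pair", "sclb_run"]

logger = logging.getLogger(__name__)


@dataclass
class SclbState:
    """Progress of an S-CLB session."""

    tau: int = 0
    pair: tuple | None = None
    accepted: bool = False
    emp_error_trace: list = field(default_factory=list)


def _multimodel_error(models, data: LabeledDataset, metric: str) -> float:
    """Empirical error of the averaged output Φ on ``data``.

    metric 'zero_one': misclassification rate with sign(0) = +1;
    metric 'exponential': mean exp(-y Φ(x)).
    """
    from .ensemble import predict_phi  # local import: avoids import cycle

    phi = predict_phi(models, data.features)
    if metric == "exponential":
        return float(np.mean(np.exp(-data.labels * phi)))
    pred = np.where(phi >= 0, 1.0, -1.0)
    return float(np.mean(pred != data.labels))


def _swap_instances(sub_a: LabeledDataset, ids_a, sub_b: LabeledDataset, ids_b):
    """Swap the listed instances between two subsets, returning new subsets."""
    pos_a = [int(np.flatnonzero(sub_a.ids == i)[0]) for i in ids_a]
    pos_b = [int(np.flatnonzero(sub_b.ids == i)[0]) for i in ids_b]
    fa, la, ia = sub_a.features.copy(), sub_a.labels.copy(), sub_a.ids.copy()
    fb, lb, ib = sub_b.features.copy(), sub_b.labels.copy(), sub_b.ids.copy()
    for pa, pb in zip(pos_a, pos_b):
        fa[pa], fb[pb] = sub_b.features[pb].copy(), sub_a.features[pa].copy()
        la[pa], lb[pb] = sub_b.labels[pb], sub_a.labels[pa]
        ia[pa], ib[pb] = sub_b.ids[pb], sub_a.ids[pa]
    names = list(sub_a.feature_names)
    return (LabeledDataset(fa, la, ia, feature_names=names),
            LabeledDataset(fb, lb, ib, feature_names=names))


def sclb_pair(
    initiator: tuple,
    predecessor: tuple,
    n_exc: int,
    models: list,
    data: LabeledDataset,
    j: int,
    k: int,
    T: int,
    *,
    strict: bool = False,
    metric: str = "zero_one",
):
    """Run one collaboration pair; returns (new subsets, new models, accepted,
    error after the pair, events).

    ``initiator`` and ``predecessor`` are (model, subset) tuples at positions
    j and k of ``models``.  The caller's state is never mutated; on rejection
    the returned subsets/models are the originals.
    """
    model_j, sub_j = initiator
    model_k, sub_k = predecessor
    base_err = _multimodel_error(models, data, metric)
    weak = select_weakest_correct(model_j, sub_j, n_exc)
    strong = select_strongest_correct(model_k, sub_k, n_exc)
    m = min(len(weak), len(strong))
    events = []
    if m == 0:
        return sub_j, sub_k, model_j, model_k, False, base_err, events
    weak, strong = weak[:m], strong[:m]
    # ids moving in must not duplicate ids already present on the other side
    if (set(strong) - set(weak)) & set(int(i) for i in sub_j.ids):
        return sub_j, sub_k, model_j, model_k, False, base_err, events
    if (set(weak) - set(strong)) & set(int(i) for i in sub_k.ids):
        return sub_j, sub_k, model_j, model_k, False, base_err, events
    new_j, new_k = _swap_instances(sub_j, weak, sub_k, strong)
    re_j = train(new_j, T)
    re_k = train(new_k, T)
    trial = list(models)
    trial[j], trial[k] = re_j, re_k
    new_err = _multimodel_error(trial, data, metric)
    accepted = new_err < base_err if strict else new_err <= base_err
    for w_id, s_id in zip(weak, strong):
        events.append(ExchangeEvent(
            round=T, ensemble=j, removed_id=int(w_id), added_id=int(s_id),
            tentative=True, successful=accepted, accepted=accepted,
        ))
    if accepted:
        return new_j, new_k, re_j, re_k, True, new_err, events
    return sub_j, sub_k, model_j, model_k, False, base_err, events


def sclb_run(
    models: list,
    data: LabeledDataset,
    subsets: list,
    n_exc: int,
    T: int,
    *,
    passes: int = 1,
    strict: bool = False,
    metric: str = "zero_one",
) -> tuple[list, list, CollaborationLog]:
    """Full S-CLB session over all ordered pairs (j, k), k < j.

    Returns (models, subsets, log); ``log.emp_error_trace`` holds the
    empirical error after every pair (τ = 1 .. S(S−1)/2 per pass) and is
    non-increasing by construction.
    """
    S = len(models)
    if S < 2:
        raise ValueError("S-CLB needs S >= 2 ensembles")
    models = list(models)
    subsets = list(subsets)
    log = CollaborationLog(mode="sclb",
                           prospective=S * (S - 1) * n_exc / 2 * passes)
    state = SclbState()
    log.emp_error_trace.append(_multimodel_error(models, data, metric))
    for _ in range(passes):
        for j in range(1, S):
            for k in range(j):
                state.tau += 1
                state.pair = (j, k)
                sub_j, sub_k, mod_j, mod_k, accepted, err, events = sclb_pair(
                    (models[j], subsets[j]), (models[k], subsets[k]),
                    n_exc, models, data, j, k, T,
                    strict=strict, metric=metric,
                )
                subsets[j], subsets[k] = sub_j, sub_k
                models[j], models[k] = mod_j, mod_k
                state.accepted = accepted
                log.tentative += 1
                if accepted:
                    log.successful += 1
                for ev in events:
                    ev.tau = state.tau
                    log.events.append(ev)
                log.emp_error_trace.append(err)
    return models, subsets, log
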