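"""Weak-learner collaboration (W-CLB): per-round instance exchange.

The S boosting ensembles are trained in lock-step.  After every boosting
round, the exchange schedule makes ``n_exc`` independent Bernoulli(``p_c``)
draws; each draw that fires triggers one *tentative collaboration*: a
simultaneous ring exchange in which every ensemble j drops its
weakest-conviction correctly classified instance and receives the
strongest-conviction correct instance of ensemble ``(j+1) mod S``.  Conviction
is the margin ``y * F(x)`` under the partial ensemble built so far, so only
instances currently classified correctly (margin > 0) are ever removed.

One tentative collaboration therefore touches all S ensembles at once, which
is what makes the prospective collaboration count per training run equal to
``T * p_c * n_exc`` in expectation.  Donated instances are copies by default
(the donor keeps its instance); the incoming instance inherits the removed
instance's boosting weight so every weight vector stays a probability
distribution, and subset sizes are conserved.  An exchange that would create
a duplicate id inside a subset is skipped (sampling is without replacement).
A swap variant (donor loses the donated instance and takes the receiver's
removed one) is available via :class:`WclbConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import LabeledDataset, SubsamplePlan
from .gentle_boost import GentleBoostModel, boost_round, init_weights, predict_raw

__all__ = [
    "WclbConfig",
    "ExchangeEvent",
    "CollaborationLog",
    "margin",
    "select_weakest_correct",
    "select_strongest_correct",
    "wclb_round",
    "train_wclb",
]

logger = logging.getLogger(__name__)

_EVENT_COLUMNS = [
    "round", "ensemble", "removed_id", "added_id",
    "removed_margin", "added_margin", "tentative", "successful",
    "tau", "accepted",
]


@dataclass(frozen=True)
class WclbConfig:
    """W-CLB knobs: exchange probability, count per round, RNG seed."""

    p_c: float
    n_exc: int
    rng_seed: int = 0
    transfer: str = "copy"  # "copy" (donor keeps its instance) or "swap"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_c <= 1.0):
            raise ValueError("p_c must lie in [0, 1]")
        if self.n_exc < 1:
            raise ValueError("n_exc must be >= 1")
        if self.transfer not in ("copy", "swap"):
            raise ValueError("transfer must be 'copy' or 'swap'")


@dataclass
class ExchangeEvent:
    """One attempted instance replacement in one ensemble's subset."""

    round: int
    ensemble: int
    removed_id: int = -1
    added_id: int = -1
    removed_margin: float = np.nan
    added_margin: float = np.nan
    tentative: bool = True
    successful: bool = False
    tau: int | None = None
    accepted: bool | None = None


@dataclass
class CollaborationLog:
    """Record of tentative and successful exchange events."""

    mode: str
    events: list = field(default_factory=list)
    tentative: int = 0       # collaborations attempted (schedule fired / pair visited)
    successful: int = 0      # collaborations that changed state everywhere
    prospective: float = 0.0  # T*p_c*n_exc (W-CLB) or S(S-1)*n_exc/2 (S-CLB)
    emp_error_trace: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{c: getattr(e, c) for c in _EVENT_COLUMNS} for e in self.events]
        return pd.DataFrame(rows, columns=_EVENT_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def margin(model: GentleBoostModel, z) -> float:
    """Margin y * F(x) of an instance-label pair under a (partial) ensemble."""
    x, y = z
    return float(y) * predict_raw(model, np.asarray(x, dtype=float))


def _margins(model: GentleBoostModel, subset: LabeledDataset) -> np.ndarray:
    return subset.labels * predict_raw(model, subset.features)


def _select_correct(model, subset, k, weakest: bool):
    if k < 1:
        raise ValueError("k must be >= 1")
    m = _margins(model, subset)
    correct = np.flatnonzero(m > 0)
    if correct.size == 0:
        return []
    order = sorted(correct, key=lambda i: (m[i], subset.ids[i]))
    if not weakest:
        order = sorted(correct, key=lambda i: (-m[i], subset.ids[i]))
    return [int(subset.ids[i]) for i in order[:k]]


def select_weakest_correct(model, subset: LabeledDataset, k: int):
    """Ids of the k correctly classified instances with smallest margins."""
    return _select_correct(model, subset, k, weakest=True)


def select_strongest_correct(model, subset: LabeledDataset, k: int):
    """Ids of the k correctly classified instances with largest margins."""
    return _select_correct(model, subset, k, weakest=False)


class _Booster:
    """Mutable per-ensemble training state for lock-step W-CLB training."""

    def __init__(self, subset: LabeledDataset):
        self.data = subset
        self.model = GentleBoostModel([], np.asarray(subset.ids).copy())
        self.w = init_weights(subset.n)

    def margins(self) -> np.ndarray:
        return _margins(self.model, self.data)


def _ring_attempt(boosters, t, cfg, log) -> None:
    """One tentative collaboration: simultaneous ring exchange over all S.

    Selections are computed on the pre-exchange state of every ensemble, then
    applied at once.  In swap mode the donor's donated slot additionally takes
    the receiver's removed instance; donor-slot writes are applied last so the
    (degenerate) case where an ensemble's weakest and strongest correct
    instance coincide resolves deterministically.
    """
    S = len(boosters)
    log.tentative += 1
    margins = [b.margins() for b in boosters]
    plans = []  # (event, removed_idx | None, donor_index, donated_idx | None)
    for j, b in enumerate(boosters):
        dj = (j + 1) % S
        donor = boosters[dj]
        m_j, m_d = margins[j], margins[dj]
        ev = ExchangeEvent(round=t, ensemble=j)
        corr_j = np.flatnonzero(m_j > 0)
        corr_d = np.flatnonzero(m_d > 0)
        if corr_j.size == 0 or corr_d.size == 0:
            plans.append((ev, None, dj, None))
            continue
        rm = int(min(corr_j, key=lambda i: (m_j[i], b.data.ids[i])))
        add = int(max(corr_d, key=lambda i: (m_d[i], -donor.data.ids[i])))
        ev.removed_id = int(b.data.ids[rm])
        ev.added_id = int(donor.data.ids[add])
        ev.removed_margin = float(m_j[rm])
        ev.added_margin = float(m_d[add])
        # duplicate guard: sampling is without replacement inside a subset;
        # a self-replacement (same id in and out) changes no state and is
        # likewise logged unsuccessful
        if ev.added_id == ev.removed_id or \
                ev.added_id in np.delete(b.data.ids, rm):
            plans.append((ev, None, dj, None))
            continue
        if cfg.transfer == "swap" and \
                ev.removed_id in np.delete(donor.data.ids, add):
            plans.append((ev, None, dj, None))
            continue
        plans.append((ev, rm, dj, add))
    # snapshot every row that moves before mutating anything
    incoming, removed_rows = [], []
    for j, (ev, rm, dj, add) in enumerate(plans):
        if rm is None:
            incoming.append(None)
            removed_rows.append(None)
            continue
        donor, b = boosters[dj], boosters[j]
        incoming.append((donor.data.features[add].copy(),
                         float(donor.data.labels[add]),
                         int(donor.data.ids[add])))
        removed_rows.append((b.data.features[rm].copy(),
                             float(b.data.labels[rm]),
                             int(b.data.ids[rm])))
    for j, (ev, rm, dj, add) in enumerate(plans):
        log.events.append(ev)
        if rm is None:
            continue
        b = boosters[j]
        x_new, y_new, id_new = incoming[j]
        # the incoming instance inherits the removed instance's weight, so
        # b.w is untouched and stays a probability distribution
        b.data.features[rm] = x_new
        b.data.labels[rm] = y_new
        b.data.ids[rm] = id_new
        ev.successful = True
    if cfg.transfer == "swap":
        for j, (ev, rm, dj, add) in enumerate(plans):
            if rm is None:
                continue
            donor = boosters[dj]
            x_old, y_old, id_old = removed_rows[j]
            donor.data.features[add] = x_old
            donor.data.labels[add] = y_old
            donor.data.ids[add] = id_old
    if all(p[1] is not None for p in plans):
        log.successful += 1


def wclb_round(boosters, t: int, cfg: WclbConfig, rng,
               log: CollaborationLog) -> None:
    """Run the per-round exchange schedule: n_exc Bernoulli(p_c) draws."""
    S = len(boosters)
    if S < 2:
        return
    for _ in range(cfg.n_exc):
        if rng.random() < cfg.p_c:
            _ring_attempt(boosters, t, cfg, log)


def train_wclb(
    data: LabeledDataset, plan: SubsamplePlan, T: int, cfg: WclbConfig
) -> tuple[list, CollaborationLog]:
    """Lock-step training of S ensembles with W-CLB exchanges.

    Returns the list of trained :class:`GentleBoostModel` and the exchange
    log.  With ``p_c = 0`` the result is bitwise identical to independent
    (non-collaborative) subbagged training on the same plan.
    """
    if plan.S < 2:
        raise ValueError("W-CLB needs S >= 2 ensembles")
    boosters = [_Booster(data.take(idx)) for idx in plan.subsets]
    rng = np.random.default_rng([cfg.rng_seed, 1_000_003])
    log = CollaborationLog(mode="wclb",
                           prospective=T * cfg.p_c * cfg.n_exc)
    for t in range(1, T + 1):
        for b in boosters:
            b.model, b.w = boost_round(b.model, b.data, b.w)
        wclb_round(boosters, t, cfg, rng, log)
    for b in boosters:
        b.model.training_ids = np.asarray(b.data.ids).copy()
    return boosters, log
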