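"""Measurement protocol: error rate, AUROC, stratified k-fold CV, paired runs.

AUROC uses the rank-statistic (Mann–Whitney) definition: the probability that
a random positive instance outranks a random negative one, with ties credited
half.  Cross-validation reports per-fold values plus the fold mean with a 95%
t-interval half-width, the "(mean ± half-width)" style.  Paired comparison
trains two configurations on identical synthetic datasets and seeds and
summarises the per-seed test-error deltas with a one-sided sign test and a
paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledDataset, train_test_split
from .ensemble import predict_multimodel, train_multimodel

__all__ = [
    "EvalReport",
    "PairedComparison",
    "error_rate",
    "auroc",
    "kfold_cv",
    "paired_compare",
]


@dataclass
class EvalReport:
    """Per-fold CV results with mean ± 95% half-width summaries."""

    error_rate: float
    auroc: float
    per_fold: dict = field(default_factory=dict)
    mean_ci: tuple = (np.nan, np.nan)        # AUROC (mean, half-width)
    error_mean_ci: tuple = (np.nan, np.nan)  # error rate (mean, half-width)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fold": np.arange(1, len(self.per_fold["error"]) + 1),
            "error": self.per_fold["error"],
            "auroc": self.per_fold["auroc"],
        })


def error_rate(labels, predictions) -> float:
    """Misclassification fraction."""
    labels = np.asarray(labels, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if labels.shape != predictions.shape or labels.size < 1:
        raise ValueError("labels and predictions must have equal length >= 1")
    return float(np.mean(labels != predictions))


def auroc(labels, scores) -> float:
    """Rank-statistic AUROC; ties credited 0.5."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    pos = labels > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _mean_halfwidth(values, confidence: float = 0.95) -> tuple[float, float]:
    """Fold mean and 95% t-interval half-width (0 half-width for one fold)."""
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    if v.size < 2:
        return mean, 0.0
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=v.size - 1))
    return mean, tcrit * sem


def kfold_cv(data: LabeledDataset, k: int, trainer_config: dict,
             seed: int) -> EvalReport:
    """Stratified k-fold CV of a multi-model configuration.

    ``trainer_config`` holds keyword arguments for
    :func:`collabboost.ensemble.train_multimodel` (S, T, eta, mode, p_c,
    n_exc, ...); the training seed is derived from ``seed`` per fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = [int((data.labels == c).sum()) for c in (-1.0, 1.0)]
    if min(counts) < k:
        raise ValueError("stratified folds infeasible: a class has fewer "
                         "instances than folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    errs, aucs, fold_ids = [], [], []
    cfg = dict(trainer_config)
    S, T, eta = cfg.pop("S"), cfg.pop("T"), cfg.pop("eta")
    mode = cfg.pop("mode", "none")
    for f, (tr, te) in enumerate(splitter.split(data.features,
                                                data.labels > 0)):
        train_ds, test_ds = data.take(tr), data.take(te)
        model, _ = train_multimodel(train_ds, S, T, eta, mode,
                                    seed=seed + f, **cfg)
        phi, pred, _ = predict_multimodel(model, test_ds.features)
        errs.append(error_rate(test_ds.labels, pred))
        aucs.append(auroc(test_ds.labels, phi))
        fold_ids.append(test_ds.ids.copy())
    auroc_ci = _mean_halfwidth(aucs)
    err_ci = _mean_halfwidth(errs)
    return EvalReport(
        error_rate=err_ci[0],
        auroc=auroc_ci[0],
        per_fold={"error": errs, "auroc": aucs, "test_ids": fold_ids},
        mean_ci=auroc_ci,
        error_mean_ci=err_ci,
    )


@dataclass
class PairedComparison:
    """Per-seed test-error deltas (config_a − config_b) and test summaries."""

    deltas: np.ndarray
    errors_a: np.ndarray
    errors_b: np.ndarray
    mean_delta: float
    sign_test_p: float  # one-sided: H1 median delta > 0 (b beats a)
    t_test_p: float     # one-sided paired t, same direction
    wins_b: int
    wins_a: int
    ties: int


def paired_compare(config_a: dict, config_b: dict, make_dataset, n_seeds: int,
                   *, base_seed: int = 0,
                   test_fraction: float = 0.3) -> PairedComparison:
    """Paired evaluation of two configurations on shared synthetic data.

    ``make_dataset(seed)`` must return a fresh :class:`LabeledDataset`; both
    configurations see the identical dataset, split and training seed in
    every replicate, so the deltas isolate the configuration difference.
    """
    deltas, ea, eb = [], [], []
    for r in range(n_seeds):
        seed = base_seed + r
        ds = make_dataset(seed)
        train_ds, test_ds = train_test_split(ds, test_fraction, seed)
        errs = []
        for cfg in (config_a, config_b):
            c = dict(cfg)
            S, T, eta = c.pop("S"), c.pop("T"), c.pop("eta")
            mode = c.pop("mode", "none")
            model, _ = train_multimodel(train_ds, S, T, eta, mode,
                                        seed=seed, **c)
            _, pred, _ = predict_multimodel(model, test_ds.features)
            errs.append(error_rate(test_ds.labels, pred))
        ea.append(errs[0])
        eb.append(errs[1])
        deltas.append(errs[0] - errs[1])
    deltas = np.asarray(deltas)
    wins_b = int((deltas > 0).sum())
    wins_a = int((deltas < 0).sum())
    ties = int((deltas == 0).sum())
    n_eff = wins_a + wins_b
    if n_eff > 0:
        sign_p = float(stats.binomtest(wins_b, n_eff, 0.5,
                                       alternative="greater").pvalue)
    else:
        sign_p = 1.0
    if np.allclose(deltas, deltas[0]) and deltas.std() == 0:
        t_p = 1.0 if deltas[0] <= 0 else 0.0
    else:
        t_p = float(stats.ttest_1samp(deltas, 0.0,
                                      alternative="greater").pvalue)
    return PairedComparison(
        deltas=deltas, errors_a=np.asarray(ea), errors_b=np.asarray(eb),
        mean_delta=float(deltas.mean()), sign_test_p=sign_p, t_test_p=t_p,
        wins_b=wins_b, wins_a=wins_a, ties=ties,
    )
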