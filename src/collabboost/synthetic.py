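"""Synthetic data with known Bayes error, plus deterministic edge fixtures.

Two spherical unit-variance Gaussian classes are placed at ``±overlap/2``
along the first feature axis (remaining axes are pure noise), so the optimal
error rate has a closed form: for a balanced problem it is
``Phi(-overlap/2)`` with ``Phi`` the standard normal CDF.  ``overlap`` is the
distance between class means in pooled-standard-deviation units — e.g.
``overlap = 2.56`` gives a Bayes error of about 10%.  This gives quantitative
targets for classifier tests without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import LabeledDataset

__all__ = ["SynthSpec", "gaussian_blobs", "bayes_error", "edge_fixtures"]


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings: size, dimension, class overlap, imbalance, seed."""

    n: int = 200
    d: int = 2
    overlap: float = 2.0   # distance between class means, in pooled-sigma units
    imbalance: float = 0.5  # positive-class fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if not (0 < self.imbalance < 1):
            raise ValueError("imbalance must lie in (0, 1)")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")


def bayes_error(spec: SynthSpec) -> float:
    """Closed-form error of the optimal rule for the two-Gaussian mixture.

    The log-likelihood ratio is linear in the first coordinate, so the optimal
    rule thresholds x_0 at ``t* = log((1-pi)/pi) / overlap`` and the error is
    ``pi * Phi(t* - overlap/2) + (1-pi) * Phi(-t* - overlap/2)``.
    """
    pi = spec.imbalance
    if spec.overlap == 0:
        return float(min(pi, 1 - pi))
    half = spec.overlap / 2.0
    t = float(np.log((1 - pi) / pi)) / spec.overlap
    return float(pi * stats.norm.cdf(t - half)
                 + (1 - pi) * stats.norm.cdf(-t - half))


def gaussian_blobs(spec: SynthSpec) -> LabeledDataset:
    """Sample a dataset from the two-Gaussian mixture; deterministic per seed.

    Class counts are exact: ``round(imbalance * n)`` positives.  Rows are
    shuffled so class labels are not position-coded.
    """
    rng = np.random.default_rng([spec.seed, 97])
    n_pos = int(round(spec.imbalance * spec.n))
    n_neg = spec.n - n_pos
    if n_pos < 1 or n_neg < 1:
        raise ValueError("imbalance leaves a class empty")
    half = spec.overlap / 2.0
    X = rng.standard_normal((spec.n, spec.d))
    y = np.concatenate([np.ones(n_pos), -np.ones(n_neg)])
    X[:, 0] += half * y
    perm = rng.permutation(spec.n)
    return LabeledDataset(X[perm], y[perm], np.arange(spec.n))


def edge_fixtures() -> dict:
    """Deterministic pathological datasets keyed by the behaviour they force.

    - ``constant_features``: every column constant → stump fitting degenerates.
    - ``duplicated_instances``: subsets will collide on ids → the W-CLB
      duplicate guard path is exercised (ids stay unique; feature rows repeat).
    - ``single_positive``: one positive among many → small-eta stratified
      subsampling must reject.
    - ``interleaved_1d``: d=1 with alternating labels → no single stump
      separates the data.
    """
    fixtures = {}
    fixtures["constant_features"] = LabeledDataset(
        np.full((6, 2), 3.0),
        np.array([1, 1, 1, -1, -1, -1], dtype=float),
    )
    base = np.array([[0.0, 1.0], [0.0, 1.0], [2.0, -1.0], [2.0, -1.0],
                     [0.1, 0.9], [1.9, -0.9], [0.1, 0.9], [1.9, -0.9]])
    fixtures["duplicated_instances"] = LabeledDataset(
        base, np.array([1, 1, -1, -1, 1, -1, 1, -1], dtype=float),
    )
    rng = np.random.default_rng(12345)
    X = rng.standard_normal((12, 3))
    y = -np.ones(12)
    y[0] = 1.0
    fixtures["single_positive"] = LabeledDataset(X, y)
    fixtures["interleaved_1d"] = LabeledDataset(
        np.arange(8, dtype=float).reshape(-1, 1),
        np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float),
    )
    return fixtures
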