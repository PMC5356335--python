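"""Dataset container, tabular I/O, stratified subsampling and train/test splitting.

The container is deliberately minimal: an ``N x d`` real feature matrix, labels
in ``{-1, +1}`` and stable integer instance ids.  Ids survive subsampling and
the collaborative instance exchanges, which lets the exchange logs refer to
instances of the *parent* dataset unambiguously.

Subsampling is stratified and without replacement (subbagging): each of the
``S`` subsets has size ``p = round(eta * N)`` with per-class counts reconciled
largest-remainder style, and the ``S`` draws are independent of one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "SubsamplePlan",
    "load_csv",
    "write_csv",
    "stratified_subsample",
    "train_test_split",
]


@dataclass
class LabeledDataset:
    """Binary-labelled tabular data.

    Parameters
    ----------
    features : ndarray of shape (N, d)
        Real-valued feature matrix; no missing values allowed.
    labels : ndarray of shape (N,)
        Class labels, each −1 or +1; training sets must contain both.
    ids : ndarray of shape (N,)
        Unique, stable instance identifiers (default: 0-based row index).
    feature_names : list of str
        Column names, used to validate schema compatibility at predict time.
    """

    features: np.ndarray
    labels: np.ndarray
    ids: np.ndarray = None  # type: ignore[assignment]
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=float)
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise ValueError("need at least one instance and one feature")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of rows")
        if not np.isin(self.labels, (-1.0, 1.0)).all():
            raise ValueError("labels must be -1 or +1")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain missing or non-finite values")
        if self.ids is None:
            self.ids = np.arange(n)
        self.ids = np.asarray(self.ids)
        if self.ids.shape != (n,):
            raise ValueError("ids length must match number of rows")
        if len(np.unique(self.ids)) != n:
            raise ValueError("ids must be unique within a dataset")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(d)]

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def take(self, indices) -> "LabeledDataset":
        """Row subset by positional indices; ids are carried along."""
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            self.features[idx], self.labels[idx], self.ids[idx],
            feature_names=list(self.feature_names),
        )

    def require_both_classes(self) -> None:
        if (self.labels > 0).all() or (self.labels < 0).all():
            raise ValueError("dataset must contain both classes")


@dataclass(frozen=True)
class SubsamplePlan:
    """``S`` index lists into a parent dataset, drawn without replacement.

    Each subset has size ``round(eta * N)`` and class proportions matching the
    parent's within one instance per class.
    """

    subsets: tuple
    eta: float
    seed: int

    @property
    def S(self) -> int:
        return len(self.subsets)


def load_csv(path, label_column: str, positive_label) -> LabeledDataset:
    """Load a headered CSV into a :class:`LabeledDataset`.

    The label column must hold exactly two distinct values; rows matching
    ``positive_label`` (compared as-is, then by string form) map to +1, the
    rest to −1.  Row order is preserved and ids are 0-based row indices.
    """
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: file has no data rows")
    if label_column not in df.columns:
        raise ValueError(f"{path}: label column {label_column!r} not found")
    raw = df[label_column]
    uniq = raw.unique()
    if len(uniq) != 2:
        raise ValueError(
            f"{path}: label column not binary — column {label_column!r} has "
            f"{len(uniq)} distinct values"
        )
    pos_mask = raw == positive_label
    if not pos_mask.any():
        pos_mask = raw.astype(str) == str(positive_label)
    if not pos_mask.any():
        raise ValueError(
            f"{path}: positive label {positive_label!r} not present in "
            f"column {label_column!r}"
        )
    feats = df.drop(columns=[label_column])
    for col in feats.columns:
        vals = pd.to_numeric(feats[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric or missing feature value in column "
                f"{col!r}, row {row}"
            )
        feats[col] = vals
    labels = np.where(pos_mask.to_numpy(), 1.0, -1.0)
    return LabeledDataset(
        feats.to_numpy(dtype=float), labels, np.arange(len(df)),
        feature_names=[str(c) for c in feats.columns],
    )


def write_csv(data: LabeledDataset, path, label_column: str = "label") -> None:
    """Write a dataset to CSV; labels are written as the integers −1 / 1."""
    df = pd.DataFrame(data.features, columns=data.feature_names)
    df[label_column] = data.labels.astype(int)
    df.to_csv(path, index=False)


def _per_class_counts(class_sizes: dict, eta: float, p: int) -> dict:
    """Largest-remainder apportionment of the subset size p across classes."""
    raw = {c: eta * m for c, m in class_sizes.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = p - sum(counts.values())
    # distribute the remainder by descending fractional part; break ties by label
    order = sorted(raw, key=lambda c: (-(raw[c] - np.floor(raw[c])), c))
    for c in order[:short]:
        counts[c] += 1
    return counts


def stratified_subsample(
    data: LabeledDataset, S: int, eta: float, seed: int
) -> SubsamplePlan:
    """Draw ``S`` independent stratified subsets of size ``round(eta*N)``.

    Sampling is without replacement within a subset; different subsets may
    overlap.  Per-subset RNG streams are derived from ``(seed, j)`` so earlier
    subsets are unchanged when ``S`` grows.
    """
    if not (0 < eta <= 1):
        raise ValueError("eta must lie in (0, 1]")
    if S < 1:
        raise ValueError("S must be >= 1")
    data.require_both_classes()
    p = int(round(eta * data.n))
    class_idx = {
        c: np.flatnonzero(data.labels == c) for c in (-1.0, 1.0)
    }
    counts = _per_class_counts({c: len(v) for c, v in class_idx.items()}, eta, p)
    for c, k in counts.items():
        if k < 1:
            raise ValueError(
                f"eta={eta} leaves class {int(c):+d} empty in subsets"
            )
        if k > len(class_idx[c]):
            raise ValueError("per-class subset count exceeds class size")
    subsets = []
    for j in range(S):
        rng = np.random.default_rng([seed, j])
        parts = [
            rng.choice(class_idx[c], size=counts[c], replace=False)
            for c in (-1.0, 1.0)
        ]
        subsets.append(np.sort(np.concatenate(parts)))
    return SubsamplePlan(tuple(subsets), eta, seed)


def train_test_split(
    data: LabeledDataset, test_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Uniform random split into disjoint train/test sets.

    ``test_fraction`` is the held-out share (the reference protocol used 20–40%).
    Both resulting sets must contain both classes.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    n_test = int(round(test_fraction * data.n))
    if n_test < 1 or n_test >= data.n:
        raise ValueError("split would leave an empty set")
    rng = np.random.default_rng([seed, 0])
    perm = rng.permutation(data.n)
    test = data.take(np.sort(perm[:n_test]))
    train = data.take(np.sort(perm[n_test:]))
    train.require_both_classes()
    test.require_both_classes()
    return train, test
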