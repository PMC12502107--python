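"""Deterministic Kennard-Stone partitioning into training and test sets.

KS picks a representative, boundary-spanning training set: start from the
two mutually farthest samples, then repeatedly add the sample whose minimum
distance to the already-selected set is largest (max-min criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .dataset import LabeledSpectraSet


@dataclass
class SplitConfig:
    train_fraction: float = 0.70
    per_class: bool = True
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.distance != "euclidean":
            raise ValueError("only euclidean distance is supported")


@dataclass
class SplitResult:
    train_indices: np.ndarray
    test_indices: np.ndarray
    per_class_counts: dict

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        overlap = np.intersect1d(self.train_indices, self.test_indices)
        if overlap.size:
            raise ValueError("train and test indices overlap")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def kennard_stone(X: np.ndarray, k: int) -> np.ndarray:
    """Select ``k`` row indices by the Kennard-Stone max-min procedure.

    Deterministic: ties are broken by the lowest index (numpy argmax keeps
    the first maximal entry).  Returned in selection order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    D = cdist(X, X)
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -np.inf
    return np.asarray(selected, dtype=int)


def _select_one(X: np.ndarray) -> int:
    """Degenerate k=1 case: the sample farthest from the centroid."""
    d = np.linalg.norm(X - X.mean(axis=0), axis=1)
    return int(np.argmax(d))


def split(spectra: LabeledSpectraSet, config: SplitConfig | None = None
          ) -> SplitResult:
    """Partition samples into train/test with KS-selected training sets.

    Per class (default), the training count is the nearest integer (half
    away from zero) to ``train_fraction`` x class size, clipped so both
    partitions stay non-empty.
    """
    cfg = config if config is not None else SplitConfig()
    n = spectra.n_samples
    if cfg.per_class:
        train_parts, per_class = [], {}
        for label, idx in spectra.class_indices().items():
            nc = idx.size
            if nc < 2:
                raise ValueError(
                    f"class {label!r} has a single sample; per-class KS needs >= 2"
                )
            k = min(max(_round_half_away(cfg.train_fraction * nc), 1), nc - 1)
            Xc = spectra.X[idx]
            if k == 1:
                local = np.asarray([_select_one(Xc)])
            else:
                local = kennard_stone(Xc, k)
            train_parts.append(idx[local])
            per_class[label] = (k, nc - k)
        train = np.sort(np.concatenate(train_parts))
    else:
        k = min(max(_round_half_away(cfg.train_fraction * n), 2), n - 1)
        train = np.sort(kennard_stone(spectra.X, k))
        per_class = {}
        for label, idx in spectra.class_indices().items():
            kt = int(np.isin(idx, train).sum())
            per_class[label] = (kt, idx.size - kt)
    test = np.setdiff1d(np.arange(n), train)
    return SplitResult(train_indices=train, test_indices=test,
                       per_class_counts=per_class)
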