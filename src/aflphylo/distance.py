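"""Pairwise distances for dominant (presence/absence) marker profiles.

The similarity between two banding profiles is F = 2*n_xy / (n_x + n_y),
the fraction of shared bands. The default distance transform is d = 1 - F,
which is bounded in [0, 1] and defined for disjoint profiles; d = -ln(F)
is available for users wanting an unbounded transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BinaryCharacterMatrix
from .errors import AflPhyloError, UndefinedDistanceError

__all__ = ["DistanceMatrix", "nei_li_similarity", "nei_li_distance", "distance_matrix"]

TRANSFORMS = ("one-minus-f", "neg-log-f")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.labels = [str(s) for s in self.labels]
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise AflPhyloError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise AflPhyloError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise AflPhyloError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise AflPhyloError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)


def nei_li_similarity(profile_x, profile_y) -> float:
    """Shared-band similarity F = 2*n_xy / (n_x + n_y)."""
    x = np.asarray(profile_x)
    y = np.asarray(profile_y)
    if x.shape != y.shape or x.ndim != 1:
        raise AflPhyloError("profiles must be 1-D and of equal length")
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise AflPhyloError("profiles must be binary")
    n_x = int(x.sum())
    n_y = int(y.sum())
    if n_x + n_y == 0:
        raise UndefinedDistanceError("both profiles are bandless; F undefined")
    n_xy = int((x & y).sum()) if x.dtype != float else int(np.sum((x > 0) & (y > 0)))
    return 2.0 * n_xy / (n_x + n_y)


def nei_li_distance(profile_x, profile_y, transform: str = "one-minus-f") -> float:
    """Distance from shared-band similarity under the chosen transform."""
    f = nei_li_similarity(profile_x, profile_y)
    return _apply_transform(f, transform)


def _apply_transform(f, transform: str):
    if transform == "one-minus-f":
        return 1.0 - f
    if transform == "neg-log-f":
        if np.any(np.asarray(f) <= 0):
            raise UndefinedDistanceError("F = 0: -ln(F) transform undefined for disjoint profiles")
        return -np.log(f)
    raise AflPhyloError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")


def _pairwise_f(calls: np.ndarray) -> np.ndarray:
    """All-pairs similarity; raises naming the first undefined pair."""
    b = calls.astype(np.float64)
    counts = b.sum(axis=1)
    shared = b @ b.T
    denom = counts[:, None] + counts[None, :]
    bad = np.argwhere(denom == 0)
    if bad.size:
        i, j = bad[0]
        raise UndefinedDistanceError(f"similarity undefined for pair (row {i}, row {j}): no bands")
    f = 2.0 * shared / denom
    np.fill_diagonal(f, 1.0)
    return f


def distance_matrix(
    matrix: BinaryCharacterMatrix,
    level: str = "sample",
    transform: str = "one-minus-f",
) -> DistanceMatrix:
    """All pairwise distances at sample or species-consensus level.

    Sample level is the default: published AFLP trees typically show
    individual profiles rather than species consensi.
    """
    if level == "sample":
        calls = matrix.calls
        labels = list(matrix.sample_ids)
    elif level == "species":
        species = matrix.species()
        calls = np.stack([matrix.species_consensus(sp) for sp in species])
        labels = species
    else:
        raise AflPhyloError(f"unknown level {level!r}; choose 'sample' or 'species'")
    if len(labels) < 3:
        raise AflPhyloError("need at least 3 rows at the chosen level")
    try:
        f = _pairwise_f(calls)
    except UndefinedDistanceError as exc:
        raise UndefinedDistanceError(str(exc)) from None
    if transform == "neg-log-f":
        off = ~np.eye(len(labels), dtype=bool)
        if np.any(f[off] <= 0):
            i, j = np.argwhere((f <= 0) & off)[0]
            raise UndefinedDistanceError(
                f"F = 0 for pair ({labels[i]}, {labels[j]}): -ln(F) undefined"
            )
    d = _apply_transform(f, transform)
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)  # guard tiny negative rounding
    return DistanceMatrix(labels, (d + d.T) / 2.0)
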