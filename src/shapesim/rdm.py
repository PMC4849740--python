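"""Representational dissimilarity matrices and the statistics built on them.

The central object of the pipeline is the RDM: a symmetric stimulus-by-stimulus
matrix of pairwise dissimilarities with an *undefined* diagonal.  Dissimilarity
is either one minus the Pearson correlation between feature rows (the
``correlation`` metric, bounded in [0, 2]) or the Euclidean distance between
unit-norm feature rows (``normalized_euclidean``).  All downstream statistics
(RDM-to-RDM correlation, bootstrap resampling, noise ceilings) operate on the
strictly-upper triangle only; the diagonal is stored as NaN and never enters
any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import FeatureMatrix

__all__ = [
    "RDM",
    "AccuracyVector",
    "compute_rdm",
    "rdm_correlation",
    "consistency",
    "mds_embed",
]

METRICS = ("correlation", "normalized_euclidean")


@dataclass
class RDM:
    """Symmetric dissimilarity matrix with an undefined (NaN) diagonal.

    Parameters
    ----------
    values
        ``(n, n)`` array; symmetric off the diagonal, NaN on it.
    stimulus_ids
        Ordered stimulus labels, one per row/column.
    metric
        Name of the dissimilarity metric the matrix was built with.
    strata
        Optional map ``stimulus_id -> stratum label`` used by stratified
        bootstrap resampling (e.g. the perceived-shape class of each stimulus).
    """

    values: np.ndarray
    stimulus_ids: list[str]
    metric: str = "correlation"
    strata: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).copy()
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"RDM values must be square, got shape {v.shape}")
        if len(self.stimulus_ids) != v.shape[0]:
            raise ValueError(
                f"{len(self.stimulus_ids)} stimulus ids for {v.shape[0]} rows"
            )
        np.fill_diagonal(v, np.nan)
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.allclose(v[off], v.T[off], atol=1e-9, equal_nan=True):
            raise ValueError("RDM is not symmetric")
        if np.any(v[off] < -1e-12):
            raise ValueError("RDM contains negative dissimilarities")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Strictly-upper-triangle values as a flat vector (diagonal excluded)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def strata_labels(self) -> np.ndarray:
        """Per-stimulus stratum labels in stimulus order."""
        if self.strata is None:
            raise ValueError("RDM carries no strata")
        return np.array([self.strata[s] for s in self.stimulus_ids])


@dataclass
class AccuracyVector:
    """Per-item accuracies in [0, 1]: binary for one rater, means for a group."""

    values: np.ndarray
    item_ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("accuracy vector must be one-dimensional")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        if self.item_ids is not None and len(self.item_ids) != v.size:
            raise ValueError("item_ids length does not match values")
        self.values = v

    def __len__(self) -> int:
        return self.values.size


def compute_rdm(features: FeatureMatrix, metric: str = "correlation") -> RDM:
    """Pairwise dissimilarity matrix of the rows of a feature matrix.

    ``correlation``: d(i, j) = 1 - Pearson r between feature rows i and j.
    ``normalized_euclidean``: rows are scaled to unit L2 norm first, then the
    plain Euclidean distance is taken, so overall activation magnitude cancels.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    x = np.asarray(features.values, dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 stimuli and 2 features")
    if metric == "correlation":
        sd = x.std(axis=1)
        if np.any(sd == 0):
            bad = features.stimulus_ids[int(np.argmax(sd == 0))]
            raise ValueError(
                f"constant feature row for stimulus {bad!r}: "
                "correlation distance is undefined"
            )
        d = 1.0 - np.corrcoef(x)
        d = np.clip(d, 0.0, 2.0)  # guard rounding just outside [0, 2]
    else:
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        if np.any(norms == 0):
            bad = features.stimulus_ids[int(np.argmax(norms.ravel() == 0))]
            raise ValueError(f"all-zero feature row for stimulus {bad!r}")
        xn = x / norms
        sq = np.sum((xn[:, None, :] - xn[None, :, :]) ** 2, axis=-1)
        d = np.sqrt(np.maximum(sq, 0.0))
    d = (d + d.T) / 2.0
    return RDM(values=d, stimulus_ids=list(features.stimulus_ids), metric=metric)


def rdm_correlation(a: RDM, b: RDM) -> float:
    """Pearson correlation of two RDMs' strictly-upper-triangle vectors."""
    if a.n != b.n:
        raise ValueError(f"RDM sizes differ: {a.n} vs {b.n}")
    if a.stimulus_ids != b.stimulus_ids:
        raise ValueError("RDMs are defined on different stimulus orders")
    x, y = a.upper_triangle(), b.upper_triangle()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in an RDM upper triangle")
    return float(np.corrcoef(x, y)[0, 1])


def consistency(x: AccuracyVector | np.ndarray, y: AccuracyVector | np.ndarray) -> float:
    """Response-pattern consistency: one minus the normalized squared
    Euclidean distance between two accuracy vectors.

    ``1 - sum((x_i - y_i)^2) / n`` — equal to 1 minus the Matching distance
    on binary inputs.  1.0 means identical response patterns; 0.5 means about
    half of the responses (correct or not) agree.
    """
    xv = x.values if isinstance(x, AccuracyVector) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, AccuracyVector) else np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {xv.shape} vs {yv.shape}")
    if np.any((xv < 0) | (xv > 1)) or np.any((yv < 0) | (yv > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    return float(1.0 - np.sum((xv - yv) ** 2) / xv.size)


def mds_embed(rdm: RDM, n_dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of an RDM.

    Double-centers the squared dissimilarities and takes the top eigenvectors.
    Deterministic: each axis is flipped so that its first nonzero loading is
    positive.  Returns an ``(n, n_dims)`` coordinate array.
    """
    if n_dims >= rdm.n:
        raise ValueError(f"n_dims={n_dims} must be < number of stimuli ({rdm.n})")
    d = rdm.values.copy()
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_dims]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    return coords
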