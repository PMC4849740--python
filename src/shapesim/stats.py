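"""Bootstrap inference and noise-ceiling estimation for RDM analyses.

All confidence intervals are percentile bootstrap intervals (2.5th / 97.5th
percentiles of the replicate distribution, 1000 iterations by default).  RDM
bootstraps resample *stimuli* with replacement; when a stimulus is drawn more
than once, every cell pairing a stimulus with itself is undefined — exactly
like the diagonal — and is dropped from the correlated upper triangle.
Stratified resampling draws each stimulus only from its own stratum (e.g. its
shape class), preserving the design's class composition in every replicate.

The paired-samples group test compares two groups of models whose bootstrap
replicates were computed on the *same* stimulus draws: per replicate, model
correlations are averaged within each group and differenced; the p-value is
the fraction of difference replicates below zero, floored at ``1 / n_iter``.

Noise ceilings bound the correlation any model can reach given
inter-participant variability: each participant's upper-triangle vector is
z-scored, the upper bound is the mean correlation with the grand mean
(including the participant), the lower bound the mean correlation with the
leave-one-out mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rdm import RDM, AccuracyVector, rdm_correlation

__all__ = [
    "BootstrapResult",
    "CeilingBand",
    "BehaviorRDMStack",
    "bootstrap_accuracy_ci",
    "bootstrap_rdm_correlation",
    "shared_bootstrap_correlations",
    "paired_group_test",
    "noise_ceiling",
]

DEFAULT_N_ITER = 1000


@dataclass
class BootstrapResult:
    """Point estimate, percentile CI and the full replicate distribution."""

    point: float
    ci_low: float
    ci_high: float
    n_iter: int
    seed: int
    distribution: np.ndarray
    index_draws: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class CeilingBand:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper + 1e-12:
            raise ValueError("ceiling lower bound exceeds upper bound")


@dataclass
class BehaviorRDMStack:
    """Per-participant RDMs from a similarity task, sharing one stimulus order."""

    rdms: list[RDM]

    def __post_init__(self) -> None:
        if not self.rdms:
            raise ValueError("empty RDM stack")
        ids = self.rdms[0].stimulus_ids
        for i, r in enumerate(self.rdms):
            if r.stimulus_ids != ids:
                raise ValueError(f"participant {i} has a different stimulus order")

    @property
    def n_participants(self) -> int:
        return len(self.rdms)

    @property
    def stimulus_ids(self) -> list[str]:
        return self.rdms[0].stimulus_ids

    def triangle_matrix(self) -> np.ndarray:
        """(participants, pairs) matrix of upper-triangle vectors."""
        return np.vstack([r.upper_triangle() for r in self.rdms])

    def mean_rdm(self) -> RDM:
        """Simple mean across participants, cell by cell."""
        vals = np.mean([r.values for r in self.rdms], axis=0)
        first = self.rdms[0]
        return RDM(
            values=vals,
            stimulus_ids=list(first.stimulus_ids),
            metric=first.metric,
            strata=first.strata,
        )


def _percentile_ci(distribution: np.ndarray) -> tuple[float, float]:
    return (
        float(np.percentile(distribution, 2.5)),
        float(np.percentile(distribution, 97.5)),
    )


def bootstrap_accuracy_ci(
    responses: AccuracyVector | np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile CI for a mean accuracy by resampling items with replacement."""
    x = responses.values if isinstance(responses, AccuracyVector) else np.asarray(
        responses, dtype=float
    )
    if x.size == 0:
        raise ValueError("empty response vector")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, x.size, size=(n_iter, x.size))
    dist = x[draws].mean(axis=1)
    lo, hi = _percentile_ci(dist)
    return BootstrapResult(
        point=float(x.mean()),
        ci_low=lo,
        ci_high=hi,
        n_iter=n_iter,
        seed=seed,
        distribution=dist,
        index_draws=draws,
    )


def _stratified_draws(
    n: int, strata: np.ndarray | None, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_iter, n) stimulus index draws, within-stratum when strata given."""
    if strata is None:
        return rng.integers(0, n, size=(n_iter, n))
    draws = np.empty((n_iter, n), dtype=int)
    for label in np.unique(strata):
        members = np.flatnonzero(strata == label)
        if members.size < 2:
            raise ValueError(f"stratum {label!r} has fewer than 2 stimuli")
        draws[:, members] = members[
            rng.integers(0, members.size, size=(n_iter, members.size))
        ]
    return draws


def _replicate_correlation(
    a_vals: np.ndarray, b_vals: np.ndarray, idx: np.ndarray
) -> float:
    """Upper-triangle correlation of index-resampled RDMs.

    Cells where the resampled row and column refer to the same original
    stimulus are undefined (like the diagonal) and dropped.
    """
    sub_a = a_vals[np.ix_(idx, idx)]
    sub_b = b_vals[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    keep = idx[iu[0]] != idx[iu[1]]
    x, y = sub_a[iu][keep], sub_b[iu][keep]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def bootstrap_rdm_correlation(
    a: RDM,
    b: RDM,
    stratified: bool = False,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap the upper-triangle correlation of two RDMs over stimuli."""
    point = rdm_correlation(a, b)
    strata = a.strata_labels() if stratified else None
    rng = np.random.default_rng(seed)
    draws = _stratified_draws(a.n, strata, n_iter, rng)
    dist = np.array(
        [_replicate_correlation(a.values, b.values, draws[i]) for i in range(n_iter)]
    )
    valid = dist[~np.isnan(dist)]
    if valid.size == 0:
        raise ValueError("all bootstrap replicates degenerate")
    lo, hi = _percentile_ci(valid)
    return BootstrapResult(
        point=point,
        ci_low=lo,
        ci_high=hi,
        n_iter=n_iter,
        seed=seed,
        distribution=dist,
        index_draws=draws,
    )


def shared_bootstrap_correlations(
    model_rdms: list[RDM],
    reference: RDM,
    stratified: bool = False,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> np.ndarray:
    """Replicate correlations for several models on *shared* stimulus draws.

    Returns an ``(n_iter, n_models)`` array whose rows are paired: every model
    in the group sees the same resampled stimulus multiset in each replicate,
    as required by the paired-samples group test.
    """
    strata = reference.strata_labels() if stratified else None
    rng = np.random.default_rng(seed)
    draws = _stratified_draws(reference.n, strata, n_iter, rng)
    out = np.empty((n_iter, len(model_rdms)))
    for j, m in enumerate(model_rdms):
        if m.n != reference.n:
            raise ValueError("model RDM size differs from reference")
        for i in range(n_iter):
            out[i, j] = _replicate_correlation(m.values, reference.values, draws[i])
    return out


def paired_group_test(
    replicates_group1: np.ndarray,
    replicates_group2: np.ndarray,
    tail: str = "one",
) -> float:
    """Bootstrapped paired-samples test between two groups of models.

    Per replicate, correlations are averaged within each group and the
    difference (group1 - group2) taken; the one-tailed p-value is the fraction
    of difference replicates below zero, floored at ``1 / n_iter``.  Two-tailed
    doubles it, capped at 1.  All-zero differences return p = 1 (tie
    convention).
    """
    g1 = np.atleast_2d(np.asarray(replicates_group1, dtype=float).T).T
    g2 = np.atleast_2d(np.asarray(replicates_group2, dtype=float).T).T
    if g1.shape[0] != g2.shape[0]:
        raise ValueError(
            f"unpaired replicate counts: {g1.shape[0]} vs {g2.shape[0]}"
        )
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN replicates
        diff = np.nanmean(g1, axis=1) - np.nanmean(g2, axis=1)
    diff = diff[~np.isnan(diff)]
    if diff.size == 0:
        raise ValueError("no valid difference replicates")
    if np.all(diff == 0):
        return 1.0
    n = diff.size
    p = max(float(np.mean(diff < 0)), 1.0 / n)
    if tail == "two":
        p = min(1.0, 2.0 * p)
    return p


def noise_ceiling(stack: BehaviorRDMStack) -> CeilingBand:
    """Upper/lower bounds on any model's achievable correlation with behavior.

    Upper-triangle vectors are z-scored per participant; the upper bound
    correlates each participant with the grand mean (self included), the lower
    bound with the leave-one-out mean; both are averaged over participants.
    """
    if stack.n_participants < 2:
        raise ValueError("noise ceiling needs at least 2 participants")
    tri = stack.triangle_matrix()
    sd = tri.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"participant {bad} has zero upper-triangle variance")
    z = (tri - tri.mean(axis=1, keepdims=True)) / sd[:, None]
    n_p = z.shape[0]
    grand = z.mean(axis=0)
    upper_rs, lower_rs = [], []
    for i in range(n_p):
        upper_rs.append(np.corrcoef(z[i], grand)[0, 1])
        loo = (grand * n_p - z[i]) / (n_p - 1)
        lower_rs.append(np.corrcoef(z[i], loo)[0, 1])
    return CeilingBand(lower=float(np.mean(lower_rs)), upper=float(np.mean(upper_rs)))
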