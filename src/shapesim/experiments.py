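"""Experiment drivers composing the pipeline stages into full analyses.

Four analyses are supported, each mirroring a classic dissociation between
physical image structure and perceived shape:

* :func:`score_naming` / :func:`naming_slope_test` — object-naming accuracy,
  human-model response consistency with a between-human ceiling band, and the
  logistic-regression test of whether model correctness tracks per-item human
  accuracy.
* :func:`physical_vs_perceived` — layer-by-layer correlation of model RDMs
  with physical-form and perceived-shape reference RDMs (the layer profile in
  which perceived shape emerges in upper layers).
* :func:`nap_evaluate` — non-accidental-property triplet discrimination: a
  model is correct on a triplet when its representation places the NAP variant
  farther from the base than the metric variant; chance is 50%.
* :func:`shape_vs_category` — correlations with orthogonal shape and category
  reference RDMs, each bootstrapped with its own stratification.

Each driver returns a result object that serializes to plain dictionaries /
DataFrames, sufficient to re-render its figure analog without recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .models import FeatureMatrix
from .rdm import RDM, AccuracyVector, compute_rdm, consistency, rdm_correlation
from .stats import (
    DEFAULT_N_ITER,
    BehaviorRDMStack,
    BootstrapResult,
    CeilingBand,
    bootstrap_accuracy_ci,
    bootstrap_rdm_correlation,
    paired_group_test,
    shared_bootstrap_correlations,
)
from .synth import TripletSet

__all__ = [
    "NamingDataset",
    "NamingResult",
    "SlopeTest",
    "LayerProfile",
    "NapResult",
    "score_naming",
    "score_correctness",
    "naming_slope_test",
    "physical_vs_perceived",
    "nap_evaluate",
    "shape_vs_category",
    "compare_model_groups",
]


# ---------------------------------------------------------------------------
# Naming (recognition-from-shape) analysis
# ---------------------------------------------------------------------------

@dataclass
class NamingDataset:
    """Closed-list naming responses for humans and models.

    ``synonyms`` maps each item id to the set of acceptable names (including
    the true label); synonym sets may overlap across items.  Responses must
    come from the closed response list (the union of all acceptable names).
    """

    item_ids: list[str]
    true_labels: dict[str, str]
    synonyms: dict[str, set[str]]
    human_responses: dict[str, list[str]]  # participant -> response per item
    model_responses: dict[str, list[str]]  # model -> response per item

    def __post_init__(self) -> None:
        closed = set()
        for item in self.item_ids:
            self.synonyms.setdefault(item, set()).add(self.true_labels[item])
            closed |= self.synonyms[item]
        for agent, resp in {**self.human_responses, **self.model_responses}.items():
            if len(resp) != len(self.item_ids):
                raise ValueError(f"agent {agent!r} has {len(resp)} responses "
                                 f"for {len(self.item_ids)} items")
            for r in resp:
                if r not in closed:
                    raise ValueError(
                        f"response {r!r} by {agent!r} is outside the closed list"
                    )

    def correctness(self, responses: list[str]) -> np.ndarray:
        return np.array(
            [
                1.0 if r in self.synonyms[item] else 0.0
                for item, r in zip(self.item_ids, responses)
            ]
        )


@dataclass
class NamingResult:
    human_item_accuracy: AccuracyVector
    human_accuracy: float
    human_accuracy_ci: BootstrapResult | None
    model_accuracy: dict[str, float]
    model_accuracy_ci: dict[str, BootstrapResult]
    model_item_correct: dict[str, np.ndarray]
    human_model_consistency: dict[str, float]
    model_model_consistency: dict[tuple[str, str], float]
    ceiling: CeilingBand | None

    def to_dict(self) -> dict:
        return {
            "human_accuracy": self.human_accuracy,
            "model_accuracy": self.model_accuracy,
            "human_model_consistency": self.human_model_consistency,
            "model_model_consistency": {
                f"{a}|{b}": v for (a, b), v in self.model_model_consistency.items()
            },
            "ceiling": None
            if self.ceiling is None
            else {"lower": self.ceiling.lower, "upper": self.ceiling.upper},
        }


def _consistency_ceiling(human_correct: np.ndarray) -> CeilingBand | None:
    """Between-human consistency band, analogous to the RDM noise ceiling but
    using the consistency statistic on accuracy vectors."""
    n_p = human_correct.shape[0]
    if n_p < 2:
        return None
    grand = human_correct.mean(axis=0)
    upper, lower = [], []
    for i in range(n_p):
        upper.append(consistency(human_correct[i], grand))
        loo = (grand * n_p - human_correct[i]) / (n_p - 1)
        lower.append(consistency(human_correct[i], loo))
    return CeilingBand(lower=float(np.mean(lower)), upper=float(np.mean(upper)))


def score_correctness(
    human_correct: np.ndarray,
    model_correct: dict[str, np.ndarray],
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> NamingResult:
    """Accuracies, consistencies and ceiling from 0/1 correctness tables.

    ``human_correct`` is (participants, items); model vectors are per-item 0/1.
    Human-model consistency compares each model vector with the *mean-human*
    accuracy vector.
    """
    human_correct = np.atleast_2d(np.asarray(human_correct, dtype=float))
    mean_human = human_correct.mean(axis=0)
    model_names = sorted(model_correct)
    acc_ci = {
        m: bootstrap_accuracy_ci(model_correct[m], n_iter=n_iter, seed=seed + j)
        for j, m in enumerate(model_names)
    }
    mm = {}
    for i, a in enumerate(model_names):
        for b in model_names[i + 1 :]:
            mm[(a, b)] = consistency(model_correct[a], model_correct[b])
    return NamingResult(
        human_item_accuracy=AccuracyVector(mean_human),
        human_accuracy=float(mean_human.mean()),
        human_accuracy_ci=bootstrap_accuracy_ci(
            human_correct.mean(axis=0), n_iter=n_iter, seed=seed
        )
        if human_correct.shape[0] >= 1
        else None,
        model_accuracy={m: float(model_correct[m].mean()) for m in model_names},
        model_accuracy_ci=acc_ci,
        model_item_correct={m: np.asarray(model_correct[m], float) for m in model_names},
        human_model_consistency={
            m: consistency(model_correct[m], mean_human) for m in model_names
        },
        model_model_consistency=mm,
        ceiling=_consistency_ceiling(human_correct),
    )


def score_naming(
    dataset: NamingDataset, n_iter: int = DEFAULT_N_ITER, seed: int = 0
) -> NamingResult:
    """Resolve closed-list responses against synonym sets, then score."""
    human = np.vstack(
        [dataset.correctness(r) for r in dataset.human_responses.values()]
    )
    models = {m: dataset.correctness(r) for m, r in dataset.model_responses.items()}
    return score_correctness(human, models, n_iter=n_iter, seed=seed)


@dataclass(frozen=True)
class SlopeTest:
    slope: float
    z: float
    p: float
    method: str  # "wald" | "lrt-ridge" | "degenerate"


def naming_slope_test(
    human_item_accuracy: AccuracyVector | np.ndarray,
    model_item_correct: np.ndarray,
) -> SlopeTest:
    """Logistic regression of model correctness on per-item human accuracy.

    Reports the Wald z-test on the slope.  Under complete separation the Wald
    statistic is undefined; the fallback is a likelihood-ratio test against the
    intercept-only model using a lightly ridge-regularized fit, reported with
    the slope sign.  A constant model vector is a documented degenerate case
    (slope undefined, p = NaN).
    """
    x = (
        human_item_accuracy.values
        if isinstance(human_item_accuracy, AccuracyVector)
        else np.asarray(human_item_accuracy, dtype=float)
    )
    y = np.asarray(model_item_correct, dtype=float)
    if x.shape != y.shape:
        raise ValueError("item vectors differ in length")
    if np.all(y == y[0]):
        return SlopeTest(slope=np.nan, z=np.nan, p=np.nan, method="degenerate")
    exog = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        slope, bse = fit.params[1], fit.bse[1]
        if np.isfinite(slope) and np.isfinite(bse) and bse < 1e3:
            z = slope / bse
            return SlopeTest(
                slope=float(slope),
                z=float(z),
                p=float(2 * sps.norm.sf(abs(z))),
                method="wald",
            )
    except Exception:
        pass
    # separation fallback: ridge fit + likelihood-ratio bound
    with np.errstate(all="ignore"):
        ridge = sm.Logit(y, exog).fit_regularized(
            alpha=np.array([0.0, 1e-2]), L1_wt=0.0, disp=0
        )
        null = sm.Logit(y, np.ones_like(y)[:, None]).fit(disp=0)
    lr = 2 * (ridge.llf - null.llf)
    p = float(sps.chi2.sf(max(lr, 0.0), df=1))
    slope = float(ridge.params[1])
    return SlopeTest(slope=slope, z=np.sign(slope) * np.sqrt(max(lr, 0.0)), p=p,
                     method="lrt-ridge")


# ---------------------------------------------------------------------------
# Layer profiles: physical vs perceived, shape vs category
# ---------------------------------------------------------------------------

@dataclass
class LayerProfile:
    """Per-layer bootstrap correlations with each reference RDM."""

    layer_names: list[str]
    references: dict[str, list[BootstrapResult]]
    metric: str = "correlation"
    mds_coords: dict[str, np.ndarray] = field(default_factory=dict)

    def correlations(self, reference: str) -> np.ndarray:
        return np.array([r.point for r in self.references[reference]])

    def to_records(self) -> list[dict]:
        rows = []
        for ref, results in self.references.items():
            for layer, res in zip(self.layer_names, results):
                rows.append({"layer": layer, "reference": ref, **res.to_dict()})
        return rows


def _layer_profile(
    layers: list[FeatureMatrix],
    references: dict[str, RDM],
    metric: str,
    n_iter: int,
    seed: int,
    stratified: dict[str, bool],
) -> LayerProfile:
    ids = references[next(iter(references))].stimulus_ids
    for name, ref in references.items():
        if ref.stimulus_ids != ids:
            raise ValueError(f"reference {name!r} has a mismatched stimulus order")
    out: dict[str, list[BootstrapResult]] = {name: [] for name in references}
    for li, layer in enumerate(layers):
        if layer.stimulus_ids != ids:
            raise ValueError(
                f"layer {layer.layer_name!r} stimuli do not match the references"
            )
        layer_rdm = compute_rdm(layer, metric=metric)
        for name, ref in references.items():
            layer_rdm_s = RDM(
                values=layer_rdm.values,
                stimulus_ids=layer_rdm.stimulus_ids,
                metric=layer_rdm.metric,
                strata=ref.strata,
            )
            out[name].append(
                bootstrap_rdm_correlation(
                    layer_rdm_s,
                    ref,
                    stratified=stratified[name],
                    n_iter=n_iter,
                    seed=seed + li,
                )
            )
    return LayerProfile(
        layer_names=[l.layer_name for l in layers], references=out, metric=metric
    )


def physical_vs_perceived(
    layers: list[FeatureMatrix],
    rdm_physical: RDM,
    rdm_perceived: RDM,
    metric: str = "correlation",
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    stratified: bool = False,
) -> LayerProfile:
    """Correlate each layer's RDM with physical-form and perceived-shape RDMs."""
    return _layer_profile(
        layers,
        {"physical": rdm_physical, "perceived": rdm_perceived},
        metric=metric,
        n_iter=n_iter,
        seed=seed,
        stratified={"physical": stratified, "perceived": stratified},
    )


def shape_vs_category(
    layers: list[FeatureMatrix],
    rdm_shape: RDM,
    rdm_category: RDM,
    metric: str = "correlation",
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    stratified: bool = True,
) -> LayerProfile:
    """Correlate layers with orthogonal shape and category reference RDMs.

    When stratified, each reference is resampled within its *own* strata
    (shape classes for the shape RDM, categories for the category RDM), which
    must be carried on the reference RDMs.
    """
    if stratified:
        for name, ref in (("shape", rdm_shape), ("category", rdm_category)):
            if ref.strata is None:
                raise ValueError(f"stratified resampling requested but the "
                                 f"{name} RDM carries no strata")
    return _layer_profile(
        layers,
        {"shape": rdm_shape, "category": rdm_category},
        metric=metric,
        n_iter=n_iter,
        seed=seed,
        stratified={"shape": stratified, "category": stratified},
    )


def compare_model_groups(
    group1_rdms: list[RDM],
    group2_rdms: list[RDM],
    reference: RDM,
    tail: str = "one",
    stratified: bool = False,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> dict:
    """Paired-samples bootstrap test between two groups of model RDMs.

    Both groups' replicate correlations with the reference are computed on the
    same stimulus draws (paired), averaged within group and differenced.
    """
    reps = shared_bootstrap_correlations(
        list(group1_rdms) + list(group2_rdms),
        reference,
        stratified=stratified,
        n_iter=n_iter,
        seed=seed,
    )
    k1 = len(group1_rdms)
    p = paired_group_test(reps[:, :k1], reps[:, k1:], tail=tail)
    return {
        "p": p,
        "tail": tail,
        "group1_mean": float(
            np.mean([rdm_correlation(m, reference) for m in group1_rdms])
        ),
        "group2_mean": float(
            np.mean([rdm_correlation(m, reference) for m in group2_rdms])
        ),
        "n_iter": n_iter,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# Non-accidental-property triplet evaluation
# ---------------------------------------------------------------------------

@dataclass
class NapResult:
    accuracy: float
    ci: BootstrapResult
    outcomes: np.ndarray  # per-triplet 0/1
    n_ties: int
    metric: str

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "ci_low": self.ci.ci_low,
            "ci_high": self.ci.ci_high,
            "n_triplets": int(self.outcomes.size),
            "n_ties": self.n_ties,
            "metric": self.metric,
            "chance": 0.5,
        }


def _pair_distance(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    """Row-wise distance between matched rows of two matrices."""
    if metric == "euclidean":
        return np.linalg.norm(a - b, axis=1)
    if metric == "normalized_euclidean":
        an = a / np.linalg.norm(a, axis=1, keepdims=True)
        bn = b / np.linalg.norm(b, axis=1, keepdims=True)
        return np.linalg.norm(an - bn, axis=1)
    if metric == "correlation":
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(ac, axis=1) * np.linalg.norm(bc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.sum(ac * bc, axis=1) / denom
        return 1.0 - r
    raise ValueError(f"unknown metric {metric!r}")


def nap_evaluate(
    triplets: TripletSet,
    metric: str = "euclidean",
    extractor=None,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> NapResult:
    """Score sensitivity to non-accidental properties on a triplet set.

    A triplet counts as correct when the representation places the NAP variant
    *strictly* farther from the base than the metric variant; ties score 0 and
    are tallied separately.  Accuracy is the mean outcome with a bootstrap CI
    over triplets; chance is 50%.  ``extractor`` optionally maps each member
    (e.g. an image) to a feature row before distances are taken.
    """
    if len(triplets) < 1:
        raise ValueError("empty triplet set")
    members = [triplets.bases, triplets.nap_variants, triplets.metric_variants]
    if extractor is not None:
        members = [np.vstack([extractor(row) for row in m]) for m in members]
    base, nap, met = members
    d_nap = _pair_distance(base, nap, metric)
    d_met = _pair_distance(base, met, metric)
    d_nap = np.nan_to_num(d_nap, nan=0.0)  # degenerate constant rows -> tie
    d_met = np.nan_to_num(d_met, nan=0.0)
    outcomes = (d_nap > d_met).astype(float)
    n_ties = int(np.sum(d_nap == d_met))
    ci = bootstrap_accuracy_ci(outcomes, n_iter=n_iter, seed=seed)
    return NapResult(
        accuracy=float(outcomes.mean()),
        ci=ci,
        outcomes=outcomes,
        n_ties=n_ties,
        metric=metric,
    )
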