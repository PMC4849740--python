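"""Synthetic stimuli, observers, layer activations and geon-like triplets.

Every downstream stage of the pipeline (feature models, RDM statistics,
bootstrap inference, experiment drivers) is exercised here on generated data
that carries the statistical structure the real experiments rely on:

* :func:`generate_shape_set` — novel-shape sets in which the *perceived* class
  (spiky / smoothie / cubie contour style) and the *physical* shape envelope
  (bounding-box aspect ratio) are manipulated orthogonally.
* :func:`simulate_observer_rdms` — a panel of participants whose dissimilarity
  judgments are a shared true RDM plus independent symmetric noise.
* :func:`simulate_layer_features` — a stack of model "layers" whose RDMs blend
  physical and perceived reference structure with a per-layer mixing weight,
  emulating the layer-wise crossover from physical to perceived shape.
* :func:`generate_triplet_features` — base / non-accidental / metric-variant
  triplets in which a linear (Euclidean) metric ranks the NAP variant *closer*
  to the base, while amplifying a diagnostic feature subspace reverses the
  ordering — the perceptual signature of non-accidental properties.
* :func:`simulate_naming` — per-participant binary naming-accuracy tables with
  planted per-item difficulties.

All generators are pure functions of their seed: identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _resize

from .models import FeatureMatrix, ImageStimulus
from .rdm import RDM

__all__ = [
    "StimulusDesign",
    "ObserverModel",
    "LayerMixPlan",
    "TripletSet",
    "generate_shape_set",
    "class_block_rdm",
    "simulate_observer_rdms",
    "simulate_layer_features",
    "generate_triplet_features",
    "simulate_naming",
]

CLASS_STYLES = ("spiky", "smoothie", "cubie")
CLASS_TINTS = {  # used by the color variant only
    "spiky": (0.85, 0.25, 0.2),
    "smoothie": (0.2, 0.55, 0.85),
    "cubie": (0.3, 0.7, 0.3),
}


@dataclass(frozen=True)
class StimulusDesign:
    """A balanced perceived-class x shape-envelope stimulus design."""

    n_perceived_classes: int = 3
    n_envelope_levels: int = 3
    image_side: int = 256
    variant: str = "silhouette"  # color | grayscale | silhouette
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perceived_classes < 2:
            raise ValueError("need at least 2 perceived classes")
        if self.n_envelope_levels < 1:
            raise ValueError("need at least 1 envelope level")
        if self.image_side < 64:
            raise ValueError("image_side must be at least 64 px")
        if self.variant not in ("color", "grayscale", "silhouette"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def n_stimuli(self) -> int:
        return self.n_perceived_classes * self.n_envelope_levels


def _aspect_ratio(level: int, n_levels: int) -> float:
    # Geometric spacing around 1 (square): e.g. 3 levels -> 0.5, 1.0, 2.0
    # (vertical, square, horizontal widths relative to height).
    return float(2.0 ** (level - (n_levels - 1) / 2))


def _radial_contour(style: str, rng: np.random.Generator) -> np.ndarray:
    """Boundary polygon (x, y) in [-1, 1]^2 for one contour style."""
    if style == "cubie":
        # Rectilinear blob: a base rectangle with random axis-aligned bumps.
        return None  # rasterized directly in _render_mask
    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    if style == "spiky":
        n_spikes = int(rng.integers(7, 12))
        phase = rng.uniform(0, 2 * np.pi)
        depth = rng.uniform(0.45, 0.6)
        r = 1.0 - depth * (0.5 + 0.5 * np.cos(n_spikes * theta + phase)) ** 0.4
    else:  # smoothie: a few low-frequency radial harmonics
        r = np.full_like(theta, 0.75)
        for harm in (2, 3, 4):
            r += rng.uniform(0.03, 0.12) * np.cos(harm * theta + rng.uniform(0, 2 * np.pi))
        r = np.clip(r, 0.35, 1.0)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _render_mask(style: str, rng: np.random.Generator, res: int = 256) -> np.ndarray:
    """Rasterize one contour style into a boolean foreground mask."""
    if style == "cubie":
        mask = np.zeros((res, res), dtype=bool)
        h0, w0 = int(res * 0.5), int(res * 0.5)
        r0, c0 = (res - h0) // 2, (res - w0) // 2
        mask[r0 : r0 + h0, c0 : c0 + w0] = True
        for _ in range(int(rng.integers(3, 6))):  # attach axis-aligned bumps
            bh = int(rng.integers(res // 10, res // 4))
            bw = int(rng.integers(res // 10, res // 4))
            side = int(rng.integers(0, 4))
            off = int(rng.integers(0, res // 2))
            if side == 0:
                mask[max(r0 - bh, 0) : r0 + 2, c0 + off % w0 : c0 + off % w0 + bw] = True
            elif side == 1:
                mask[r0 + h0 - 2 : min(r0 + h0 + bh, res), c0 + off % w0 : c0 + off % w0 + bw] = True
            elif side == 2:
                mask[r0 + off % h0 : r0 + off % h0 + bh, max(c0 - bw, 0) : c0 + 2] = True
            else:
                mask[r0 + off % h0 : r0 + off % h0 + bh, c0 + w0 - 2 : min(c0 + w0 + bw, res)] = True
        return mask
    from skimage.draw import polygon as _polygon

    pts = _radial_contour(style, rng)
    rr = (pts[:, 1] + 1.0) / 2.0 * (res - 1)
    cc = (pts[:, 0] + 1.0) / 2.0 * (res - 1)
    mask = np.zeros((res, res), dtype=bool)
    fr, fc = _polygon(rr, cc, shape=(res, res))
    mask[fr, fc] = True
    return mask


def _fit_to_envelope(mask: np.ndarray, aspect: float, side: int) -> np.ndarray:
    """Crop to the foreground bbox and rescale it to the target aspect ratio."""
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.argmax(rows), len(rows) - np.argmax(rows[::-1])
    c0, c1 = np.argmax(cols), len(cols) - np.argmax(cols[::-1])
    cropped = mask[r0:r1, c0:c1]
    span = int(0.8 * side)  # long axis occupies 80% of the canvas
    if aspect >= 1.0:
        w, h = span, int(round(span / aspect))
    else:
        w, h = int(round(span * aspect)), span
    if min(w, h) < 16:
        raise ValueError(
            f"image_side {side} too small to render envelope aspect {aspect:g}"
        )
    # order-0 resize: no anti-aliasing, the mask stays binary
    scaled = _resize(cropped.astype(float), (h, w), order=0, anti_aliasing=False) > 0.5
    canvas = np.zeros((side, side), dtype=bool)
    rr, cc = (side - h) // 2, (side - w) // 2
    canvas[rr : rr + h, cc : cc + w] = scaled
    return canvas


def generate_shape_set(design: StimulusDesign) -> list[ImageStimulus]:
    """Render one stimulus per (perceived class, envelope level) cell.

    Contour style is determined by the perceived class (cycling through
    spiky / smoothie / cubie), the foreground bounding-box aspect ratio by the
    envelope level.  Foreground is black (0) on a white (1) background;
    silhouettes are strictly binary.
    """
    stimuli: list[ImageStimulus] = []
    for c in range(design.n_perceived_classes):
        style = CLASS_STYLES[c % len(CLASS_STYLES)]
        for e in range(design.n_envelope_levels):
            rng = np.random.default_rng([design.seed, c, e])
            aspect = _aspect_ratio(e, design.n_envelope_levels)
            mask = _fit_to_envelope(_render_mask(style, rng), aspect, design.image_side)
            if design.variant == "silhouette":
                pixels = np.where(mask, 0.0, 1.0)
            elif design.variant == "grayscale":
                # interior shading, still strictly below the 0.5 threshold
                ramp = np.linspace(0.1, 0.4, design.image_side)[None, :]
                pixels = np.where(mask, np.broadcast_to(ramp, mask.shape), 1.0)
            else:  # color: class-specific tint on white
                tint = np.array(CLASS_TINTS[style])
                pixels = np.where(mask[..., None], tint[None, None, :], 1.0)
            stimuli.append(
                ImageStimulus(
                    pixels=pixels,
                    variant=design.variant,
                    label=f"class{c}_env{e}",
                    class_labels={"perceived": f"class{c}", "envelope": f"env{e}"},
                )
            )
    return stimuli


def class_block_rdm(
    labels: list[str],
    stimulus_ids: list[str],
    within: float = 0.3,
    between: float = 1.0,
    strata_name: bool = True,
) -> RDM:
    """Block-structured reference RDM: small dissimilarity within a class,
    large between classes.  The labels double as bootstrap strata."""
    lab = np.asarray(labels)
    same = lab[:, None] == lab[None, :]
    values = np.where(same, within, between).astype(float)
    strata = dict(zip(stimulus_ids, labels)) if strata_name else None
    return RDM(values=values, stimulus_ids=list(stimulus_ids), strata=strata)


@dataclass(frozen=True)
class ObserverModel:
    """A panel of simulated participants sharing one true RDM."""

    true_rdm: RDM
    noise_sd: float = 0.3
    n_participants: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


def simulate_observer_rdms(model: ObserverModel):
    """Per-participant RDMs: truth plus i.i.d. symmetric Gaussian noise.

    Noise is added to the upper-triangle cells and mirrored, preserving
    symmetry; negative dissimilarities are clipped to zero; the diagonal stays
    undefined.  Returns a :class:`~shapesim.stats.BehaviorRDMStack`.
    """
    from .stats import BehaviorRDMStack

    rng = np.random.default_rng(model.seed)
    n = model.true_rdm.n
    iu = np.triu_indices(n, k=1)
    rdms = []
    for _ in range(model.n_participants):
        vals = model.true_rdm.values.copy()
        noise = rng.normal(0.0, model.noise_sd, size=len(iu[0])) if model.noise_sd else 0.0
        tri = np.maximum(vals[iu] + noise, 0.0)
        vals[iu] = tri
        vals.T[iu] = tri
        rdms.append(
            RDM(
                values=vals,
                stimulus_ids=list(model.true_rdm.stimulus_ids),
                metric=model.true_rdm.metric,
                strata=model.true_rdm.strata,
            )
        )
    return BehaviorRDMStack(rdms=rdms)


@dataclass(frozen=True)
class LayerMixPlan:
    """Per-layer mixing weights between physical and perceived structure.

    Weight ``w`` is the share of perceived-shape structure in that layer's
    RDM; ``1 - w`` is the share of physical structure.  The default plan rises
    monotonically, emulating the emergence of perceived shape in upper layers.
    """

    mix_weights: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    n_features: int = 200
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 or w > 1 for w in self.mix_weights):
            raise ValueError("mix weights must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _nearest_correlation_sqrt(s: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD-projected, unit-diagonal version of s."""
    w, v = np.linalg.eigh((s + s.T) / 2)
    w = np.maximum(w, 1e-10)
    s_psd = (v * w) @ v.T
    d = np.sqrt(np.diag(s_psd))
    s_psd = s_psd / np.outer(d, d)
    w, v = np.linalg.eigh(s_psd)
    return (v * np.sqrt(np.maximum(w, 0.0))) @ v.T


def simulate_layer_features(
    plan: LayerMixPlan, rdm_physical: RDM, rdm_perceived: RDM
) -> list[FeatureMatrix]:
    """Draw per-layer feature matrices whose correlation-distance RDMs follow
    the weighted blend of the physical and perceived reference RDMs.

    For each layer the target similarity matrix ``1 - D_blend`` is projected
    to the nearest correlation matrix and features are drawn with exactly that
    sample row-correlation (noise-free case), so a layer with weight 1
    reproduces the perceived RDM and weight 0 the physical RDM.
    """
    if rdm_physical.n != rdm_perceived.n:
        raise ValueError(
            f"reference RDM sizes differ: {rdm_physical.n} vs {rdm_perceived.n}"
        )
    n = rdm_physical.n
    if plan.n_features < n:
        raise ValueError("n_features must be at least the stimulus count")
    d_phys = np.nan_to_num(rdm_physical.values, nan=0.0)
    d_perc = np.nan_to_num(rdm_perceived.values, nan=0.0)
    rng = np.random.default_rng(plan.seed)
    layers = []
    for li, w in enumerate(plan.mix_weights):
        blend = (1.0 - w) * d_phys + w * d_perc
        a = _nearest_correlation_sqrt(1.0 - blend)
        z = rng.normal(size=(n, plan.n_features))
        z -= z.mean(axis=1, keepdims=True)
        cov = z @ z.T / plan.n_features
        wc, vc = np.linalg.eigh(cov)
        whiten = (vc / np.sqrt(np.maximum(wc, 1e-12))) @ vc.T
        feats = a @ whiten @ z
        if plan.noise_sd:
            feats = feats + rng.normal(0.0, plan.noise_sd, size=feats.shape)
        layers.append(
            FeatureMatrix(
                values=feats,
                model_name="synthetic_net",
                layer_name=f"layer_{li:02d}",
                stimulus_ids=list(rdm_physical.stimulus_ids),
            )
        )
    return layers


@dataclass
class TripletSet:
    """Base / non-accidental / metric-variant feature triplets.

    ``diagnostic_dim`` is the size of the leading feature subspace that
    carries the non-accidental displacement; :meth:`apply_gain` amplifies that
    subspace, modeling the perceptual weighting of non-accidental properties.
    """

    bases: np.ndarray  # (n_triplets, n_features)
    nap_variants: np.ndarray
    metric_variants: np.ndarray
    diagnostic_dim: int
    triplet_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.bases.shape == self.nap_variants.shape == self.metric_variants.shape):
            raise ValueError("triplet members must share shape")
        if not self.triplet_ids:
            self.triplet_ids = [f"triplet_{i:02d}" for i in range(len(self.bases))]

    def __len__(self) -> int:
        return self.bases.shape[0]

    def apply_gain(self, gain: float) -> "TripletSet":
        """Amplify the diagnostic subspace by ``gain`` in all three members."""
        scale = np.ones(self.bases.shape[1])
        scale[: self.diagnostic_dim] = gain
        return TripletSet(
            bases=self.bases * scale,
            nap_variants=self.nap_variants * scale,
            metric_variants=self.metric_variants * scale,
            diagnostic_dim=self.diagnostic_dim,
            triplet_ids=list(self.triplet_ids),
        )


def generate_triplet_features(
    n_triplets: int = 22,
    d_nap_linear: float = 0.8,
    d_metric_linear: float = 1.0,
    perceptual_gain: float = 5.0,
    n_features: int = 100,
    seed: int = 0,
) -> tuple[TripletSet, TripletSet]:
    """Plant triplets with the conservative linear-metric ordering.

    In raw feature space the NAP variant sits at Euclidean distance
    ``d_nap_linear`` from its base and the metric variant at
    ``d_metric_linear >= d_nap_linear``, so a linear metric ranks the NAP
    variant as similar or *closer* — mirroring the design in which
    non-accidental variants are physically no farther from the base than
    metric ones.  The NAP displacement lives entirely in the leading
    ``ceil(n_features / 10)`` "diagnostic" coordinates; amplifying them by
    ``perceptual_gain`` (>= d_metric/d_nap) reverses the ordering.

    Returns ``(linear, perceptual)``: the raw set and the gain-amplified set.
    """
    if d_nap_linear <= 0 or d_metric_linear <= 0:
        raise ValueError("planted distances must be positive")
    if d_nap_linear > d_metric_linear:
        raise ValueError("planted design requires d_nap_linear <= d_metric_linear")
    if perceptual_gain < 1:
        raise ValueError("perceptual_gain must be >= 1")
    k = int(np.ceil(n_features / 10))
    rng = np.random.default_rng(seed)
    bases = rng.normal(size=(n_triplets, n_features))
    u = np.zeros((n_triplets, n_features))
    u[:, :k] = rng.normal(size=(n_triplets, k))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.zeros((n_triplets, n_features))
    v[:, k:] = rng.normal(size=(n_triplets, n_features - k))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    linear = TripletSet(
        bases=bases,
        nap_variants=bases + d_nap_linear * u,
        metric_variants=bases + d_metric_linear * v,
        diagnostic_dim=k,
    )
    return linear, linear.apply_gain(perceptual_gain)


def simulate_naming(
    item_difficulties, n_participants: int, seed: int = 0
) -> np.ndarray:
    """Per-participant binary naming accuracies with planted item difficulties.

    Each (participant, item) response is an independent Bernoulli draw with
    the item's success probability.  Returns an ``(n_participants, n_items)``
    0/1 array.
    """
    p = np.asarray(item_difficulties, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("item difficulties must lie in [0, 1]")
    if n_participants < 1:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(seed)
    return (rng.random((n_participants, p.size)) < p).astype(int)
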