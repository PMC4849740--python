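"""Image preprocessing, silhouettes, and shallow feature models.

The shallow models are single-layer, hand-designed feature extractors that
serve as baselines against which perceptual shape sensitivity is measured:

* ``pixelwise_features`` — the raw intensity values, a pure "physical form"
  baseline.
* ``gaborjet_features`` — a V1-like jet of complex Gabor magnitudes (five
  octave-spaced spatial frequencies x eight orientations) sampled on a regular
  10x10 grid.
* ``hog_features`` — histogram-of-oriented-gradients descriptor (nine
  orientation bins, 8x8 px cells, 3x3-cell block normalization).

Deep-network activations are not computed here; they are consumed as data
through :func:`load_activation_matrix` / :func:`save_activation_matrix`.

Conventions pinned for reproducibility: images are square intensity grids in
[0, 1] with 0 = black and 1 = white, row-major with the origin at the top-left;
grayscale conversion uses Rec.601 luminance weights; all feature orders are
fixed and documented on each extractor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.feature import hog as _skimage_hog
from skimage.filters import gabor_kernel
from skimage.measure import label as _cc_label
from skimage.transform import resize as _resize

__all__ = [
    "ImageStimulus",
    "FeatureMatrix",
    "preprocess_image",
    "make_silhouette",
    "pixelwise_features",
    "gaborjet_features",
    "hog_features",
    "stack_features",
    "save_activation_matrix",
    "load_activation_matrix",
]

REC601 = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageStimulus:
    """A preprocessed stimulus image: intensities in [0, 1] on a square grid."""

    pixels: np.ndarray
    variant: str = "grayscale"  # color | grayscale | silhouette
    label: str = ""
    class_labels: dict[str, str] = field(default_factory=dict)
    constant: bool = False  # set when the raw image had zero dynamic range

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim == 2:
            if p.shape[0] != p.shape[1]:
                raise ValueError(f"image must be square, got {p.shape}")
        elif p.ndim == 3:
            if p.shape[0] != p.shape[1] or p.shape[2] != 3:
                raise ValueError(f"color image must be square RGB, got {p.shape}")
        else:
            raise ValueError(f"bad image ndim {p.ndim}")
        if p.size and (p.min() < -1e-9 or p.max() > 1 + 1e-9):
            raise ValueError("intensities must lie in [0, 1]")
        self.pixels = np.clip(p, 0.0, 1.0)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def is_gray(self) -> bool:
        return self.pixels.ndim == 2


@dataclass
class FeatureMatrix:
    """Stimuli x features activations for one named model layer."""

    values: np.ndarray
    model_name: str
    layer_name: str
    stimulus_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if v.shape[0] != len(self.stimulus_ids):
            raise ValueError(
                f"{v.shape[0]} rows for {len(self.stimulus_ids)} stimulus ids"
            )
        if v.shape[0] < 2:
            raise ValueError("need at least 2 stimuli")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains non-finite entries")
        self.values = v

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def preprocess_image(
    raw: np.ndarray, target_side: int = 256, to_gray: bool = True, **stimulus_kwargs
) -> ImageStimulus:
    """Resample to ``target_side`` square and min-max rescale into [0, 1].

    A zero-dynamic-range input is returned as a constant image with the
    ``constant`` flag set (and a warning), not an error.
    """
    img = np.asarray(raw, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3 and to_gray:
        img = img[..., :3] @ REC601
    if img.shape[:2] != (target_side, target_side):
        out_shape = (target_side, target_side) + img.shape[2:]
        img = _resize(img, out_shape, order=1, anti_aliasing=True, mode="edge")
    lo, hi = img.min(), img.max()
    constant = hi == lo
    if constant:
        warnings.warn("zero-dynamic-range image: returning a constant stimulus")
        img = np.clip(img, 0.0, 1.0)
    else:
        img = (img - lo) / (hi - lo)
    variant = stimulus_kwargs.pop("variant", "grayscale" if img.ndim == 2 else "color")
    return ImageStimulus(pixels=img, variant=variant, constant=constant, **stimulus_kwargs)


def make_silhouette(stimulus: ImageStimulus, threshold: float = 0.5) -> ImageStimulus:
    """Fill the object with black: the silhouette of a donut is a disk.

    Foreground = the largest connected component of sub-threshold (dark)
    pixels, with every interior cavity filled.  Output is binary {0, 1} with
    the object at intensity 0 on a white background.
    """
    if not stimulus.is_gray:
        raise ValueError("silhouette requires a grayscale stimulus")
    dark = stimulus.pixels < threshold
    if not dark.any():
        raise ValueError(f"no foreground below threshold {threshold}")
    labels = _cc_label(dark, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    fg = labels == counts.argmax()
    fg = ndimage.binary_fill_holes(fg)
    out = np.where(fg, 0.0, 1.0)
    return ImageStimulus(
        pixels=out,
        variant="silhouette",
        label=stimulus.label,
        class_labels=dict(stimulus.class_labels),
    )


def pixelwise_features(stimulus: ImageStimulus) -> np.ndarray:
    """Flattened intensity grid in row-major order."""
    return stimulus.pixels.ravel().astype(float)


def _gabor_bank(n_freqs: int, n_orients: int) -> list[tuple[float, float, np.ndarray]]:
    # Lades-style jet: octave-spaced center frequencies descending from
    # 0.25 cycles/px, ~1 octave bandwidth, complex kernels with the DC of the
    # real part removed so constant images give exactly zero magnitude.
    bank = []
    for v in range(n_freqs):
        freq = 0.25 / (2 ** v)
        for o in range(n_orients):
            theta = np.pi * o / n_orients
            k = gabor_kernel(frequency=freq, theta=theta, bandwidth=1.0)
            k = k - k.real.mean()
            bank.append((freq, theta, np.asarray(k)))
    return bank


def _grid_nodes(side: int, grid: int) -> tuple[np.ndarray, np.ndarray]:
    # Regular grid of interior nodes (cell centers), excluding the border.
    step = side / grid
    pos = np.round(step / 2 + step * np.arange(grid)).astype(int)
    return pos, pos


def gaborjet_features(
    stimulus: ImageStimulus, n_freqs: int = 5, n_orients: int = 8, grid: int = 10
) -> np.ndarray:
    """Complex Gabor magnitudes at every (node, frequency, orientation).

    Feature order is node-major (row-major over the grid), then frequency
    (high to low), then orientation; length = grid^2 * n_freqs * n_orients
    (4000 at defaults).
    """
    if not stimulus.is_gray:
        raise ValueError("gaborjet requires a grayscale stimulus")
    if grid > stimulus.side:
        raise ValueError(f"grid {grid} exceeds image side {stimulus.side}")
    img = stimulus.pixels
    rows, cols = _grid_nodes(stimulus.side, grid)
    mags = np.empty((n_freqs, n_orients, grid, grid))
    for i, (_, _, kern) in enumerate(_gabor_bank(n_freqs, n_orients)):
        f, o = divmod(i, n_orients)
        # edge-replication padding so border nodes see no zero-padding artifact
        pr, pc = kern.shape[0] // 2, kern.shape[1] // 2
        padded = np.pad(img, ((pr, pr), (pc, pc)), mode="edge")
        resp = fftconvolve(padded, kern, mode="same")[pr : pr + img.shape[0],
                                                      pc : pc + img.shape[1]]
        mags[f, o] = np.abs(resp)[np.ix_(rows, cols)]
    # (node_row, node_col, freq, orient) -> flat, node-major
    return mags.transpose(2, 3, 0, 1).ravel()


def hog_features(
    stimulus: ImageStimulus,
    n_orientations: int = 9,
    cell_px: int = 8,
    cells_per_block: int = 3,
) -> np.ndarray:
    """Block-normalized histogram-of-oriented-gradients descriptor."""
    if not stimulus.is_gray:
        raise ValueError("hog requires a grayscale stimulus")
    if stimulus.side % cell_px != 0:
        raise ValueError(
            f"image side {stimulus.side} not divisible by cell size {cell_px}"
        )
    return _skimage_hog(
        stimulus.pixels,
        orientations=n_orientations,
        pixels_per_cell=(cell_px, cell_px),
        cells_per_block=(cells_per_block, cells_per_block),
        block_norm="L2-Hys",
        feature_vector=True,
    )


def stack_features(
    stimuli: list[ImageStimulus],
    extractor,
    model_name: str,
    layer_name: str = "output",
    **kwargs,
) -> FeatureMatrix:
    """Apply a row extractor to each stimulus and stack into a FeatureMatrix."""
    rows = [extractor(s, **kwargs) for s in stimuli]
    ids = [s.label or f"stim_{i}" for i, s in enumerate(stimuli)]
    return FeatureMatrix(
        values=np.vstack(rows),
        model_name=model_name,
        layer_name=layer_name,
        stimulus_ids=ids,
    )


def save_activation_matrix(path, matrices: list[FeatureMatrix]) -> None:
    """Write layer activations to an ``.npz`` container with a JSON id sidecar.

    Arrays are keyed by layer name; all layers must share the stimulus order.
    """
    path = Path(path)
    ids = matrices[0].stimulus_ids
    for m in matrices:
        if m.stimulus_ids != ids:
            raise ValueError("all layers must share one stimulus order")
    np.savez(path, **{m.layer_name: m.values for m in matrices})
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"stimulus_ids": ids, "model_name": matrices[0].model_name})
    )


def load_activation_matrix(
    path, layer_name: str, stimulus_ids: list[str] | None = None
) -> FeatureMatrix:
    """Load one layer from an activation container, aligned to a stimulus order.

    If ``stimulus_ids`` is given, rows are permuted to that order; unknown ids
    raise an alignment error.
    """
    path = Path(path)
    with np.load(path) as archive:
        if layer_name not in archive.files:
            raise KeyError(
                f"layer {layer_name!r} not in container; available: {archive.files}"
            )
        values = archive[layer_name]
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    stored_ids = list(meta["stimulus_ids"])
    if stimulus_ids is None:
        order = list(range(len(stored_ids)))
        ids = stored_ids
    else:
        missing = [s for s in stimulus_ids if s not in stored_ids]
        if missing:
            raise ValueError(f"stimulus ids not in container: {missing}")
        order = [stored_ids.index(s) for s in stimulus_ids]
        ids = list(stimulus_ids)
    return FeatureMatrix(
        values=values[order],
        model_name=meta.get("model_name", "external"),
        layer_name=layer_name,
        stimulus_ids=ids,
    )
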