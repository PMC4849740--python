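"""End-to-end synthetic analyses: the glue the CLI and reports run.

Each ``run_*`` function generates its synthetic inputs from a seed, executes
the corresponding experiment driver, writes a result bundle (CSV tables, JSON
statistics, a layer-profile figure where applicable) and returns a compact
summary dictionary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import experiments as exp
from . import synth
from .io import write_result_bundle
from .models import pixelwise_features, stack_features
from .rdm import compute_rdm, mds_embed
from .stats import noise_ceiling

__all__ = [
    "write_stimuli",
    "run_naming",
    "run_shape",
    "run_nap",
    "run_category",
]


def _save_profile_figure(profile: exp.LayerProfile, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(profile.layer_names))
    for ref, results in profile.references.items():
        pts = [r.point for r in results]
        lo = [r.ci_low for r in results]
        hi = [r.ci_high for r in results]
        ax.plot(x, pts, marker="o", label=ref)
        ax.fill_between(x, lo, hi, alpha=0.2)
    ax.set_xticks(x)
    ax.set_xticklabels(profile.layer_names, rotation=45, ha="right")
    ax.set_ylabel("RDM correlation")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def write_stimuli(out_dir: Path, seed: int = 0) -> int:
    """Render the default 3x3 synthetic shape set to PNG files."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = synth.StimulusDesign(seed=seed)
    stimuli = synth.generate_shape_set(design)
    for s in stimuli:
        arr = (s.pixels * 255).astype(np.uint8)
        Image.fromarray(arr).save(out_dir / f"{s.label}.png")
    return len(stimuli)


def _synthetic_references(seed: int):
    """Shape set plus physical (pixelwise) and perceived (class-block) RDMs."""
    design = synth.StimulusDesign(seed=seed)
    stimuli = synth.generate_shape_set(design)
    pix = stack_features(stimuli, pixelwise_features, model_name="pixelwise")
    rdm_physical = compute_rdm(pix, metric="correlation")
    ids = pix.stimulus_ids
    perceived_labels = [s.class_labels["perceived"] for s in stimuli]
    rdm_perceived = synth.class_block_rdm(perceived_labels, ids)
    return stimuli, pix, rdm_physical, rdm_perceived


def run_naming(out_dir: Path, seed: int = 0, n_iter: int = 1000,
               n_items: int = 60, n_participants: int = 10) -> dict:
    """Simulated naming panel: accuracies, consistency, ceiling, slope test."""
    rng = np.random.default_rng(seed)
    difficulties = rng.beta(4, 1.5, size=n_items)  # mostly nameable items
    human = synth.simulate_naming(difficulties, n_participants, seed=seed + 1)
    # model tracks the same item difficulties, slightly less accurate
    model = synth.simulate_naming(
        np.clip(difficulties - 0.15, 0, 1), 1, seed=seed + 2
    )[0]
    result = exp.score_correctness(human, {"synthetic_model": model},
                                   n_iter=n_iter, seed=seed)
    slope = exp.naming_slope_test(result.human_item_accuracy, model)
    summary = {
        **result.to_dict(),
        "slope": slope.slope,
        "slope_z": slope.z,
        "slope_p": slope.p,
        "slope_method": slope.method,
    }
    write_result_bundle(
        {
            "naming_summary": summary,
            "human_item_accuracy": pd.DataFrame(
                {"item": range(n_items),
                 "accuracy": result.human_item_accuracy.values}
            ),
        },
        out_dir,
    )
    return summary


def run_shape(out_dir: Path, seed: int = 0, n_iter: int = 1000,
              metric: str = "correlation") -> dict:
    """Physical-vs-perceived layer profile on the synthetic orthogonal set."""
    _, pix, rdm_physical, rdm_perceived = _synthetic_references(seed)
    plan = synth.LayerMixPlan(noise_sd=0.1, seed=seed)
    layers = synth.simulate_layer_features(plan, rdm_physical, rdm_perceived)
    profile = exp.physical_vs_perceived(
        layers, rdm_physical, rdm_perceived, metric=metric,
        n_iter=n_iter, seed=seed,
    )
    top_rdm = compute_rdm(layers[-1], metric=metric)
    coords = mds_embed(top_rdm, n_dims=2)
    out_dir = Path(out_dir)
    write_result_bundle(
        {
            "layer_profile": pd.DataFrame(profile.to_records()),
            "mds_top_layer": pd.DataFrame(
                coords, columns=["dim_1", "dim_2"]
            ).assign(stimulus_id=top_rdm.stimulus_ids),
        },
        out_dir,
    )
    _save_profile_figure(profile, out_dir / "layer_profile.png")
    perc = profile.correlations("perceived")
    phys = profile.correlations("physical")
    return {
        "perceived_first_layer": float(perc[0]),
        "perceived_top_layer": float(perc[-1]),
        "physical_first_layer": float(phys[0]),
        "physical_top_layer": float(phys[-1]),
        "perceived_rises": bool(perc[-1] > perc[0]),
        "physical_falls": bool(phys[-1] < phys[0]),
    }


def run_nap(out_dir: Path, seed: int = 0, n_iter: int = 1000,
            n_triplets: int = 22) -> dict:
    """Triplet discrimination on planted linear vs perceptually-gained sets."""
    linear, perceptual = synth.generate_triplet_features(
        n_triplets=n_triplets, seed=seed
    )
    res_linear = exp.nap_evaluate(linear, n_iter=n_iter, seed=seed)
    res_gain = exp.nap_evaluate(perceptual, n_iter=n_iter, seed=seed)
    summary = {
        "linear": res_linear.to_dict(),
        "perceptual": res_gain.to_dict(),
    }
    write_result_bundle({"nap_summary": summary}, out_dir)
    return summary


def run_category(out_dir: Path, seed: int = 0, n_iter: int = 1000,
                 metric: str = "correlation", n_categories: int = 6,
                 n_shapes: int = 9) -> dict:
    """Shape-vs-category profile on a balanced orthogonal design.

    Every (category, shape) cell is occupied once, so the shape and category
    block RDMs are uncorrelated by construction; layers blend the two.
    """
    ids = [f"c{c}_s{s}" for c in range(n_categories) for s in range(n_shapes)]
    cat_labels = [i.split("_")[0] for i in ids]
    shape_labels = [i.split("_")[1] for i in ids]
    rdm_category = synth.class_block_rdm(cat_labels, ids)
    rdm_shape = synth.class_block_rdm(shape_labels, ids)
    plan = synth.LayerMixPlan(
        mix_weights=(0.0, 0.25, 0.5, 0.75), n_features=2 * len(ids),
        noise_sd=0.1, seed=seed,
    )
    # weight = share of category structure; shape plays the "physical" role
    layers = synth.simulate_layer_features(plan, rdm_shape, rdm_category)
    profile = exp.shape_vs_category(
        layers, rdm_shape, rdm_category, metric=metric,
        n_iter=n_iter, seed=seed, stratified=True,
    )
    group_test = exp.compare_model_groups(
        [compute_rdm(layers[-1], metric=metric)],
        [compute_rdm(layers[0], metric=metric)],
        rdm_category,
        tail="one",
        stratified=True,
        n_iter=n_iter,
        seed=seed,
    )
    out_dir = Path(out_dir)
    write_result_bundle(
        {
            "layer_profile": pd.DataFrame(profile.to_records()),
            "group_test": group_test,
        },
        out_dir,
    )
    _save_profile_figure(profile, out_dir / "layer_profile.png")
    return {
        "shape_top_layer": float(profile.correlations("shape")[-1]),
        "category_top_layer": float(profile.correlations("category")[-1]),
        "reference_orthogonality": float(
            np.corrcoef(rdm_shape.upper_triangle(), rdm_category.upper_triangle())[0, 1]
        ),
        "top_vs_bottom_category_p": group_test["p"],
    }
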