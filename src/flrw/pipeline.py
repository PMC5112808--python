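"""End-to-end orchestration: train -> probability -> seeds -> walk -> evaluate.

``run_pipeline`` drives the whole chain on a list of cases, optionally
training the model first and writing stage artifacts plus a reproducibility
manifest.  ``beta_sweep`` reruns the segmentation across a list of beta
values and tabulates the five error measures per value.
"""

from __future__ import annotations

import csv
import json
import os
import sys
from dataclasses import dataclass, replace

import numpy as np

from . import __version__
from .boosted_classifier import EnsembleModel, ProbabilityMap, probability_image, save_model, train_flrw_model
from .config import PipelineConfig
from .errors import ConfigError, FlrwError
from .evaluation import MetricsReport, evaluate_masks
from .image_io import ImageGrid, LabelMask, denoise, write_image, write_mask
from .random_walk import segment
from .seed_selection import SeedMask, auto_seeds

__all__ = ["CaseResult", "run_pipeline", "beta_sweep", "train_from_config"]


@dataclass
class CaseResult:
    probability: ProbabilityMap | None
    seeds: SeedMask
    label: LabelMask
    metrics: MetricsReport | None


def _log(msg: str):
    print(f"[flrw] {msg}", file=sys.stderr)


def train_from_config(config: PipelineConfig, train_images, train_masks) -> EnsembleModel:
    c = config.classifier
    prepped = [denoise(img, config.denoise.method, config.denoise.radius) for img in train_images]
    sched = None
    if c.sigma0 is not None:
        sched = [c.sigma0 * c.rho**t for t in range(c.T)]
    return train_flrw_model(
        prepped,
        train_masks,
        spec=config.feature,
        n_per_region=c.n_per_region,
        edge_band=c.edge_band,
        variance_fraction=c.variance_fraction,
        n_components=c.n_components,
        T=c.T,
        rho=c.rho,
        sigma_schedule=sched,
        svm_C=c.svm_C,
        resample_size=c.resample_size,
        seed=config.seed,
    )


def _process_case(config: PipelineConfig, image: ImageGrid, model, gold, mode: str):
    walk = config.walk
    if mode == "rw":
        walk = replace(walk, alpha=0.0)
    # denoising feeds feature extraction only; seeds and the walker use the
    # original intensities
    prepped = denoise(image, config.denoise.method, config.denoise.radius)
    prob = None
    if mode != "rw":
        if model is None:
            raise ConfigError("flrw mode requires a trained model")
        prob = probability_image(model, prepped)
    seeds = auto_seeds(
        image,
        search_range=config.seeds.search_range,
        erosion_radius=config.seeds.erosion_radius,
        below=config.seeds.offset_below,
        above=config.seeds.offset_above,
    )
    label = segment(image, prob, seeds, walk)
    metrics = None
    if gold is not None:
        metrics = evaluate_masks(gold, label, spacing=image.spacing)
    return CaseResult(probability=prob, seeds=seeds, label=label, metrics=metrics)


def run_pipeline(
    config: PipelineConfig,
    images,
    model: EnsembleModel | None = None,
    train_images=None,
    train_masks=None,
    gold_masks=None,
    out_dir: str | None = None,
    mode: str = "flrw",
):
    """Run the full workflow over ``images``; returns a list of CaseResult.

    ``mode="rw"`` forces alpha = 0 and skips the classifier entirely.
    A manifest (config digest, seed, versions) is written alongside the
    artifacts when ``out_dir`` is given.
    """
    if mode not in ("flrw", "rw"):
        raise ConfigError(f"unknown mode {mode!r}")
    if model is None and mode == "flrw":
        if train_images is None or train_masks is None:
            raise ConfigError("provide a trained model or training images + masks")
        _log(f"training model on {len(train_images)} slices")
        model = train_from_config(config, train_images, train_masks)
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)
            save_model(model, os.path.join(out_dir, "model.flrw"))
    gold_masks = gold_masks or [None] * len(images)
    results = []
    for k, (image, gold) in enumerate(zip(images, gold_masks)):
        try:
            res = _process_case(config, image, model, gold, mode)
        except FlrwError as exc:
            raise type(exc)(f"case {k}: {exc}") from exc
        results.append(res)
        if res.metrics is not None:
            _log(
                f"case {k}: VOE {res.metrics.voe:.2f}% ASD {res.metrics.asd:.2f}mm"
            )
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)
            if res.probability is not None:
                write_image(
                    ImageGrid(res.probability.values, res.probability.spacing),
                    os.path.join(out_dir, f"case{k:03d}_prob.mhd"),
                )
            seeds_img = res.seeds.states.astype(np.float64)
            seeds_img[seeds_img == -1] = 255  # unknown marker for inspection
            write_image(
                ImageGrid(seeds_img, image.spacing),
                os.path.join(out_dir, f"case{k:03d}_seeds.mhd"),
            )
            write_mask(res.label, os.path.join(out_dir, f"case{k:03d}_seg.mhd"))
            if res.metrics is not None:
                with open(os.path.join(out_dir, f"case{k:03d}_metrics.json"), "w") as fh:
                    json.dump(res.metrics.as_dict(), fh, indent=2)
    if out_dir:
        manifest = {
            "flrw_version": __version__,
            "numpy_version": np.__version__,
            "config_digest": config.digest(),
            "config": config.to_dict(),
            "mode": mode,
            "n_cases": len(images),
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return results


def beta_sweep(
    config: PipelineConfig,
    image: ImageGrid,
    gold,
    beta_values,
    model: EnsembleModel | None = None,
    mode: str = "flrw",
    out_csv: str | None = None,
):
    """Segment one case at several beta values; rows of the five errors."""
    beta_values = list(beta_values)
    if len(beta_values) < 2:
        raise ConfigError("sweep needs at least two beta values")
    rows = []
    for beta in beta_values:
        cfg = replace(config, walk=replace(config.walk, beta=float(beta)))
        res = _process_case(cfg, image, model, gold, mode)
        m = res.metrics
        rows.append(
            {
                "beta": float(beta),
                "voe": m.voe,
                "rvd": m.rvd,
                "asd": m.asd,
                "rmse": m.rmse,
                "msd": m.msd,
            }
        )
    if out_csv:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
    return rows
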