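"""End-to-end recognition pipeline.

Order of operations: load (or synthesise) grayscale images ->
preprocess to fixed-size [0, 1] crops -> optional curvelet-domain
enhancement of every image -> stratified train/validation/test split ->
train the attention CNN -> evaluate on all three splits.

All randomness (synthesis, crops, split, weight init, batch shuffling,
dropout) is fanned out from one master seed through named sub-streams,
so a run is fully reproducible from its config; enhancement changes
pixel content only and can never perturb the partition.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .enhance import enhance_image
from .fdct import FdctConfig
from .network import Model, NetworkSpec, TrainConfig, build_network, evaluate, train
from .network import binary_cross_entropy
from .synthetic import LabeledImage, SynthConfig, generate_dataset

logger = logging.getLogger("ciea")

__all__ = [
    "PipelineConfig",
    "Metrics",
    "preprocess",
    "load_image",
    "split_dataset",
    "run_pipeline",
]


# named sub-streams of the master seed, in a fixed order
_STREAMS = ("synth", "crop", "split", "init", "train")


def _sub_seeds(master: int) -> Dict[str, int]:
    state = np.random.SeedSequence(master).generate_state(len(_STREAMS))
    return {name: int(s) % (2**31 - 1) for name, s in zip(_STREAMS, state)}


def load_image(path: str) -> np.ndarray:
    """Read an 8- or 16-bit grayscale (or RGB, converted by luminance)
    image file into a float array in [0, 1]."""
    import imageio.v3 as iio

    data = np.asarray(iio.imread(path))
    if data.ndim == 3:  # RGB(A) -> luminance
        data = data[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if np.issubdtype(data.dtype, np.integer):
        divisor = 65535.0 if data.dtype.itemsize > 1 else 255.0
        return data.astype(float) / divisor
    return np.clip(data.astype(float), 0.0, 1.0)


def preprocess(
    image: np.ndarray,
    crop_size: int = 224,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Random-crop (or symmetric-pad) a [0, 1] image to crop_size x crop_size.

    Larger images are randomly cropped with the supplied (seeded)
    generator; smaller ones are symmetrically padded before cropping, so
    the output geometry is always ``crop_size`` square.
    """
    image = np.asarray(image, dtype=float)
    rng = rng or np.random.default_rng(0)
    h, w = image.shape
    if h < crop_size or w < crop_size:
        ph, pw = max(0, crop_size - h), max(0, crop_size - w)
        image = np.pad(
            image,
            ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)),
            mode="symmetric",
        )
        h, w = image.shape
    top = int(rng.integers(0, h - crop_size + 1))
    left = int(rng.integers(0, w - crop_size + 1))
    return image[top : top + crop_size, left : left + crop_size]


def split_dataset(
    images: Sequence[LabeledImage],
    ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Tuple[List[LabeledImage], List[LabeledImage], List[LabeledImage]]:
    """Stratified random train/validation/test partition.

    Within each class, validation and test receive the floor of their
    ratio share; the remainder goes to training.  The three lists are
    disjoint and exhaustive, and identical for identical seeds.
    """
    if len(images) < 10:
        raise ValueError("need at least 10 images to split")
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("split ratios must be positive")
    ratios = ratios / ratios.sum()

    by_class: Dict[int, List[int]] = {0: [], 1: []}
    for i, im in enumerate(images):
        by_class[im.label].append(i)
    if not by_class[0] or not by_class[1]:
        raise ValueError("both classes must be present")

    rng = np.random.default_rng(seed)
    splits: Tuple[List[int], ...] = ([], [], [])
    for label in (0, 1):
        idx = np.array(by_class[label])
        rng.shuffle(idx)
        n = len(idx)
        n_val = int(np.floor(ratios[1] * n))
        n_test = int(np.floor(ratios[2] * n))
        splits[1].extend(idx[:n_val])
        splits[2].extend(idx[n_val : n_val + n_test])
        splits[0].extend(idx[n_val + n_test :])
    return tuple([images[i] for i in sorted(part)] for part in splits)  # type: ignore


@dataclass
class PipelineConfig:
    """Everything one run needs; serialisable to/from JSON."""

    synth: Optional[SynthConfig] = None  # synthetic source (exclusive with input_dir)
    input_dir: Optional[str] = None  # directory with a manifest.csv
    crop_size: int = 64
    split_ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    enhancement: bool = True
    contrast_step: float = 0.1
    tau: Optional[float] = None
    fdct: FdctConfig = field(default_factory=FdctConfig)
    network: Optional[NetworkSpec] = None  # default: NetworkSpec(input_size=crop_size)
    training: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    output_dir: Optional[str] = None

    def resolve_network(self) -> NetworkSpec:
        return self.network or NetworkSpec(input_size=self.crop_size)


@dataclass
class Metrics:
    """Accuracies and losses of one pipeline run."""

    accuracy: Dict[str, float]
    loss: Dict[str, float]
    seed: int
    sub_seeds: Dict[str, int]
    enhancement: bool
    n_images: int
    runtime_s: float

    def as_text(self) -> str:
        lines = [f"seed = {self.seed}", f"enhancement = {self.enhancement}",
                 f"n_images = {self.n_images}", f"runtime_s = {self.runtime_s:.1f}"]
        for split in ("train", "validation", "test"):
            lines.append(f"accuracy_{split} = {self.accuracy[split]:.4f}")
            lines.append(f"loss_{split} = {self.loss[split]:.4f}")
        return "\n".join(lines) + "\n"


def _load_inputs(config: PipelineConfig, seeds: Dict[str, int]) -> List[LabeledImage]:
    if (config.synth is None) == (config.input_dir is None):
        raise ValueError("exactly one of synth / input_dir must be given")
    if config.synth is not None:
        synth = dataclasses.replace(config.synth, seed=seeds["synth"])
        return generate_dataset(synth)

    from .synthetic import read_dataset

    raw = read_dataset(os.path.join(config.input_dir, "manifest.csv"))
    crop_rng = np.random.default_rng(seeds["crop"])
    out = []
    for im in raw:
        try:
            out.append(
                LabeledImage(
                    preprocess(im.pixels, config.crop_size, crop_rng), im.label, im.id
                )
            )
        except Exception as exc:  # unreadable/corrupt entries are skipped
            logger.warning("skipping %s: %s", im.id, exc)
    return out


def run_pipeline(config: PipelineConfig) -> Metrics:
    """Execute the full pipeline and return (and optionally write) metrics."""
    t0 = time.time()
    seeds = _sub_seeds(config.seed)
    logger.info("sub-seeds: %s", seeds)

    images = _load_inputs(config, seeds)
    logger.info("loaded %d images", len(images))

    if config.enhancement:
        t = time.time()
        images = [
            LabeledImage(
                enhance_image(im.pixels, config.fdct, config.contrast_step, config.tau),
                im.label,
                im.id,
            )
            for im in images
        ]
        logger.info("enhanced %d images in %.1fs", len(images), time.time() - t)

    train_set, val_set, test_set = split_dataset(
        images, config.split_ratios, seed=seeds["split"]
    )
    logger.info("split: %d/%d/%d", len(train_set), len(val_set), len(test_set))

    model = build_network(config.resolve_network(), seed=seeds["init"])
    tcfg = dataclasses.replace(config.training, seed=seeds["train"])
    history = train(model, train_set, tcfg, val_set=val_set)

    accuracy, loss = {}, {}
    for name, subset in (("train", train_set), ("validation", val_set), ("test", test_set)):
        p = model.predict_proba(subset)
        y = np.array([im.label for im in subset], dtype=float)
        accuracy[name] = float(np.mean((p >= 0.5) == (y == 1)))
        loss[name] = binary_cross_entropy(y, p)

    metrics = Metrics(
        accuracy=accuracy,
        loss=loss,
        seed=config.seed,
        sub_seeds=seeds,
        enhancement=config.enhancement,
        n_images=len(images),
        runtime_s=time.time() - t0,
    )

    if config.output_dir:
        _write_outputs(config, model, history, metrics)
    return metrics


def _write_outputs(config, model: Model, history, metrics: Metrics) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "metrics.txt"), "w") as fh:
        fh.write(metrics.as_text())
    keys = list(history)
    with open(os.path.join(out, "history.csv"), "w") as fh:
        fh.write(",".join(keys) + "\n")
        for row in zip(*(history[k] for k in keys)):
            fh.write(",".join(str(v) for v in row) + "\n")
    np.savez(os.path.join(out, "checkpoint.npz"), **model.state_dict())
    with open(os.path.join(out, "config.json"), "w") as fh:
        json.dump(_config_to_dict(config), fh, indent=2, default=str)
    logger.info("outputs written to %s", out)


def _config_to_dict(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        return obj

    return enc(config)
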