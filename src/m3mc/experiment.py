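"""Study-design power computation and end-to-end pipeline orchestration.

``required_sample_size`` reproduces the G*Power-style minimum total sample
size for a two-sample t-test (noncentral-t power at a standardized effect
size); ``run_pipeline`` wires the cascaded stages together on a phantom
dataset: segment → signed distance map → localize/crop → classify →
evaluate; ``ablate_channels`` re-trains the classifier per channel subset
with shared seeds and splits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.power import TTestIndPower, TTestPower
from scipy.stats import norm

from . import classification as cls
from . import segmentation as seg
from .evaluation import cls_metrics, seg_metrics
from .localization import assemble_channels
from .phantom import RelationLabel, generate_dataset
from .sdm import BinaryMask, compute_sdm
from .volume_io import LABEL_M3, LABEL_MC

logger = logging.getLogger(__name__)

__all__ = [
    "PowerSpec",
    "required_sample_size",
    "PipelineConfig",
    "run_pipeline",
    "ablate_channels",
]


# ---------------------------------------------------------------------------
# Sample size


@dataclass
class PowerSpec:
    """Standardized effect size d, two-sided alpha, target power, and group
    allocation ratio for a two-sample (or paired) t-test."""

    effect_size: float = 0.50
    alpha: float = 0.05
    power: float = 0.80
    allocation_ratio: float = 1.0
    design: str = "independent"  # or "paired"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")
        if self.design not in {"independent", "paired"}:
            raise ValueError("design must be 'independent' or 'paired'")


_MAX_N = 10_000_000


def required_sample_size(spec: PowerSpec, method: str = "noncentral_t") -> int:
    """Smallest total N reaching the target power.

    ``noncentral_t`` evaluates the exact noncentral-t power of the
    two-sided t-test at integer group sizes (equal groups by default) and
    returns the total across both groups; ``normal`` is the closed-form
    z-approximation ``ceil(2 (z_{1-α/2} + z_{power})² / d²)`` per group
    that the exact computation refines. For the paired design N is the
    number of pairs.
    """
    if method == "normal":
        z = norm.ppf(1 - spec.alpha / 2) + norm.ppf(spec.power)
        per_group = int(np.ceil(2 * z**2 / spec.effect_size**2))
        return 2 * per_group if spec.design == "independent" else per_group

    if method != "noncentral_t":
        raise ValueError("method must be 'noncentral_t' or 'normal'")
    if spec.design == "paired":
        solver = TTestPower()
        for n in range(2, _MAX_N):
            if solver.power(spec.effect_size, nobs=n, alpha=spec.alpha, alternative="two-sided") >= spec.power:
                return n
    else:
        solver = TTestIndPower()
        for n in range(2, _MAX_N):
            p = solver.power(
                spec.effect_size,
                nobs1=n,
                alpha=spec.alpha,
                ratio=spec.allocation_ratio,
                alternative="two-sided",
            )
            if p >= spec.power:
                return n + int(np.ceil(n * spec.allocation_ratio))
    raise RuntimeError("power target unattainable within the iteration cap")


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """One document configuring every stage; explicit seeds everywhere."""

    out_dir: str = "pipeline_out"
    n_cases: int = 10
    class_balance: float = 0.5
    test_fraction: float = 0.3
    data_seed: int = 0
    # segmentation stage
    seg_architecture: str = "plain_unet"
    seg_depth: int = 3
    seg_base_filters: int = 8
    seg_epochs: int = 20
    seg_learning_rate: float = 1e-3
    seg_batch_size: int = 8
    seg_seed: int = 0
    # localization / channels
    channels: tuple[str, ...] = ("image", "sdm")
    crop_shape: tuple[int, int, int] = (32, 32, 16)
    # classification stage
    cls_levels: int = 3
    cls_base_filters: int = 8
    cls_epochs: int = 30
    cls_learning_rate: float = 1e-3
    cls_batch_size: int = 4
    cls_seed: int = 0
    # use ground-truth masks instead of S-Net predictions for the crops
    # (isolates the classifier from segmentation error)
    use_ground_truth_masks: bool = False

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["channels"] = list(d["channels"])
        d["crop_shape"] = list(d["crop_shape"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["channels"] = tuple(d.get("channels", ("image", "sdm")))
        d["crop_shape"] = tuple(d.get("crop_shape", (32, 32, 16)))
        return cls(**d)


def _split(n: int, test_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    return perm[n_test:], perm[:n_test]


def _build_input(volume, mask, channels, crop_shape):
    union = BinaryMask(mask.binary(), mask.spacing)
    s = compute_sdm(union, units="voxel") if "sdm" in channels else None
    return assemble_channels(volume, mask, s, channels, crop_shape=crop_shape)


def prepare_cases(config: PipelineConfig):
    """Generate the phantom dataset and the train/test split."""
    manifest, cases = generate_dataset(
        config.n_cases, config.class_balance, seed=config.data_seed
    )
    train_idx, test_idx = _split(config.n_cases, config.test_fraction, config.data_seed)
    return manifest, cases, train_idx, test_idx


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the cascade end to end on phantoms; returns a results bundle
    and writes artifacts (config, histories, metrics, predictions, hashes)
    under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    bundle: dict = {}

    manifest, cases, train_idx, test_idx = prepare_cases(config)
    manifest.to_csv(out / "manifest.csv", index=False)
    logger.info("stage 1/5: segmentation training on %d cases", len(train_idx))
    try:
        grid = cases[0][0].shape
        seg_cfg = seg.SegModelConfig(
            architecture=config.seg_architecture,
            depth=config.seg_depth,
            base_filters=config.seg_base_filters,
            input_size=grid[:2],
            seed=config.seg_seed,
        )
        seg_model = seg.build_segmentation_model(seg_cfg)
        seg_spec = seg.SegTrainSpec(
            learning_rate=config.seg_learning_rate,
            max_epochs=config.seg_epochs,
            batch_size=config.seg_batch_size,
            seed=config.seg_seed,
        )
        seg_model, seg_history = seg.train_segmentation(
            seg_model, [(cases[i][0], cases[i][1]) for i in train_idx], seg_spec
        )
        seg_history.to_csv(out / "seg_history.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage 'segmentation': {exc}") from exc

    logger.info("stage 2/5: mask prediction + SDM + localization")
    inputs, labels, skipped = [], [], []
    seg_rows = []
    try:
        for i, (volume, gt_mask, label) in enumerate(cases):
            pred_mask = (
                gt_mask
                if config.use_ground_truth_masks
                else seg.predict_mask(seg_model, volume)
            )
            if i in test_idx:
                for structure, name in ((LABEL_M3, "m3"), (LABEL_MC, "mc")):
                    sm = seg_metrics(pred_mask, gt_mask, structure)
                    seg_rows.append({"case": i, "structure": name, **sm.as_dict()})
            present = set(np.unique(pred_mask.labels).tolist())
            if not {LABEL_M3, LABEL_MC} <= present:
                # refuse to guess a center when a structure is missing
                skipped.append(i)
                logger.warning("case %d: predicted mask lacks a structure; skipped", i)
                continue
            inputs.append((i, _build_input(volume, pred_mask, config.channels, config.crop_shape)))
            labels.append(label)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage 'localization': {exc}") from exc

    logger.info("stage 3/5: classifier training")
    index_of = {case_i: k for k, (case_i, _) in enumerate(inputs)}
    train_pairs = [
        (inputs[index_of[i]][1], labels[index_of[i]]) for i in train_idx if i in index_of
    ]
    try:
        cls_cfg = cls.ClsModelConfig(
            levels=config.cls_levels,
            base_filters=config.cls_base_filters,
            input_channels=len(config.channels),
            input_size=config.crop_shape,
            seed=config.cls_seed,
        )
        cnet = cls.build_cnet(cls_cfg)
        cls_spec = cls.ClsTrainSpec(
            learning_rate=config.cls_learning_rate,
            max_epochs=config.cls_epochs,
            batch_size=config.cls_batch_size,
            seed=config.cls_seed,
        )
        cnet, cls_history = cls.train_cnet(cnet, train_pairs, cls_spec)
        cls_history.to_csv(out / "cls_history.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage 'classification': {exc}") from exc

    logger.info("stage 4/5: evaluation")
    pred_rows = []
    for case_i, x in inputs:
        pred = cls.predict_relation(cnet, x)
        p_buccal = pred.probability if pred.value == "buccal" else 1 - pred.probability
        pred_rows.append(
            {
                "case": case_i,
                "split": "test" if case_i in test_idx else "train",
                "true": labels[index_of[case_i]].value,
                "predicted": pred.value,
                "p_buccal": p_buccal,
                "p_lingual": 1 - p_buccal,
            }
        )
    predictions = pd.DataFrame(pred_rows)
    predictions.to_csv(out / "predictions.csv", index=False)
    seg_table = pd.DataFrame(seg_rows)
    seg_table.to_csv(out / "seg_metrics.csv", index=False)
    test_preds = predictions[predictions.split == "test"]
    metrics = cls_metrics(
        test_preds.p_buccal.tolist(),
        test_preds.true.tolist(),
        positive="buccal",
    )

    logger.info("stage 5/5: artifact manifest")
    seg.save_model(seg_model, out / "seg_model.npz")
    cls.save_model(cnet, out / "cls_model.npz")
    hashes = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir())
        if p.is_file() and p.suffix in {".csv", ".yaml", ".json"}
    }
    (out / "artifacts.json").write_text(json.dumps(hashes, indent=2))

    bundle.update(
        {
            "config": config,
            "seg_history": seg_history,
            "seg_metrics": seg_table,
            "cls_history": cls_history,
            "predictions": predictions,
            "cls_metrics": metrics,
            "skipped_cases": skipped,
            "seg_model": seg_model,
            "cls_model": cnet,
            "cases": cases,
            "train_idx": train_idx,
            "test_idx": test_idx,
        }
    )
    return bundle


def ablate_channels(config: PipelineConfig, channel_sets) -> pd.DataFrame:
    """Train/evaluate the classifier once per channel subset with shared
    data, seeds, and splits; ground-truth masks are used for the crops so
    the comparison isolates the input configuration."""
    channel_sets = [tuple(c for c in ("image", "mask", "sdm") if c in s) for s in channel_sets]
    if any(len(s) == 0 for s in channel_sets):
        raise ValueError("each channel set must be a nonempty subset of {image, mask, sdm}")
    manifest, cases, train_idx, test_idx = prepare_cases(config)
    rows = []
    for channels in channel_sets:
        inputs = [
            _build_input(v, m, channels, config.crop_shape) for v, m, _ in cases
        ]
        labels = [label for _, _, label in cases]
        cnet = cls.build_cnet(
            cls.ClsModelConfig(
                levels=config.cls_levels,
                base_filters=config.cls_base_filters,
                input_channels=len(channels),
                input_size=config.crop_shape,
                seed=config.cls_seed,
            )
        )
        spec = cls.ClsTrainSpec(
            learning_rate=config.cls_learning_rate,
            max_epochs=config.cls_epochs,
            batch_size=config.cls_batch_size,
            seed=config.cls_seed,
        )
        cnet, _ = cls.train_cnet(cnet, [(inputs[i], labels[i]) for i in train_idx], spec)
        probs = cls.predict_proba(cnet, [inputs[i] for i in test_idx])
        m = cls_metrics(
            probs[:, 0].tolist(),
            [labels[i].value for i in test_idx],
            positive="buccal",
        )
        rows.append(
            {
                "channels": "+".join(channels),
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "auc": m.auc,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Desk-scale benchmarks (shared by the test suite and the acceptance script)


def segmentation_holdout_benchmark(
    n_train: int = 8,
    n_test: int = 2,
    seed: int = 0,
    epochs: int = 20,
    learning_rate: float = 1e-3,
    architecture: str = "plain_unet",
) -> pd.DataFrame:
    """Train a tiny slice segmenter on ``n_train`` phantoms and evaluate
    per-structure DSC on ``n_test`` held-out phantoms.

    Returns one row per held-out case and structure (columns: case,
    structure, dsc, iou).
    """
    _, cases = generate_dataset(n_train + n_test, 0.5, seed=seed)
    train, test = cases[:n_train], cases[n_train:]
    grid = cases[0][0].shape
    model = seg.build_segmentation_model(
        seg.SegModelConfig(architecture=architecture, input_size=grid[:2], seed=seed)
    )
    spec = seg.SegTrainSpec(
        learning_rate=learning_rate, max_epochs=epochs, batch_size=8, seed=seed
    )
    model, _ = seg.train_segmentation(model, [(v, m) for v, m, _ in train], spec)
    rows = []
    for i, (v, m, _) in enumerate(test):
        pred = seg.predict_mask(model, v)
        for label, name in ((LABEL_M3, "m3"), (LABEL_MC, "mc")):
            sm = seg_metrics(pred, m, label)
            rows.append({"case": i, "structure": name, "dsc": sm.dsc, "iou": sm.iou})
    return pd.DataFrame(rows)


def classification_benchmark(
    n_train: int = 60,
    n_test: int = 40,
    seed: int = 0,
    epochs: int = 25,
    channel_sets=(("image", "sdm"), ("image",)),
    shuffle_control: bool = True,
    crop_shape=(32, 32, 16),
) -> dict:
    """Held-out accuracy of the relationship classifier per channel set,
    plus an optional label-shuffle negative control.

    Crops are taken from the ground-truth masks so the comparison isolates
    the input configuration from segmentation error. All configurations
    share the dataset, split, and seeds. Returns
    ``{"image+sdm": ClsMetrics-dict, ..., "shuffled": accuracy}``.
    """
    n = n_train + n_test
    _, cases = generate_dataset(n, 0.5, seed=seed)
    train_idx = np.arange(n_train)
    test_idx = np.arange(n_train, n)
    results: dict = {}
    spec = cls.ClsTrainSpec(max_epochs=epochs, batch_size=4, seed=seed)
    for channels in channel_sets:
        inputs = [_build_input(v, m, channels, crop_shape) for v, m, _ in cases]
        labels = [label for _, _, label in cases]
        model = cls.build_cnet(
            cls.ClsModelConfig(
                input_channels=len(channels), input_size=tuple(crop_shape), seed=seed
            )
        )
        model, _ = cls.train_cnet(
            model, [(inputs[i], labels[i]) for i in train_idx], spec
        )
        probs = cls.predict_proba(model, [inputs[i] for i in test_idx])
        m = cls_metrics(
            probs[:, 0].tolist(), [labels[i].value for i in test_idx], positive="buccal"
        )
        results["+".join(channels)] = {
            "accuracy": m.accuracy,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "auc": m.auc,
            "model": model,
            "inputs": inputs,
            "labels": labels,
            "test_idx": test_idx,
        }
    if shuffle_control:
        # Class-balanced label permutation: exactly half of each true class
        # gets the opposite label. On a deterministically separable binary
        # task an unconstrained shuffle lets the learner adopt whichever
        # polarity the random assignment happens to favor (bimodal ~0/~1
        # held-out accuracy); balancing nets the polarity signal to zero so
        # the control concentrates at chance, which is what it must verify.
        channels = tuple(channel_sets[0])
        inputs = results["+".join(channels)]["inputs"]
        labels = [label for _, _, label in cases]
        rng = np.random.default_rng(seed + 1)
        shuffled = [RelationLabel(l.value, 1.0) for l in labels[:n_train]]
        for value in ("buccal", "lingual"):
            idx = [i for i in range(n_train) if labels[i].value == value]
            flip = rng.permutation(len(idx))[: len(idx) // 2]
            other = "lingual" if value == "buccal" else "buccal"
            for k in flip:
                shuffled[idx[k]] = RelationLabel(other, 1.0)
        model = cls.build_cnet(
            cls.ClsModelConfig(
                input_channels=len(channels), input_size=tuple(crop_shape), seed=seed
            )
        )
        model, _ = cls.train_cnet(
            model, [(inputs[i], shuffled[i]) for i in train_idx], spec
        )
        probs = cls.predict_proba(model, [inputs[i] for i in test_idx])
        pred = np.where(probs[:, 0] >= 0.5, "buccal", "lingual")
        truth = np.array([labels[i].value for i in test_idx])
        results["shuffled_accuracy"] = float((pred == truth).mean())
    return results
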