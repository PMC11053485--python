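"""Training, evaluation and ablation orchestration.

The trainer wires synthetic or user-supplied plot images through the
BioUMixer encoder and the SCDR objective: every step augments a mini-batch
into two views per image, runs the forward pass, computes
``α·L_reg + β·L_SCDR`` and takes an Adam step under a cosine-annealed
learning rate.  Labels are z-scored internally for the regression loss;
predictions are mapped back to grams for metrics and for the ω-pairing test,
which operates in label units.  A checkpoint (config + weights + label and
image statistics) is kept at the best validation MAE.  Everything is
reproducible from the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import nn
from .autodiff import Tensor, no_grad
from .metrics import MetricsReport, compute_metrics, residuals_frame
from .model import ABLATION_CASES, BioUMixer, ModelConfig, build_model
from .scdr import (AugmentSpec, SCDRConfig, make_augmented_batch, scdr_total_loss,
                   standardize)

logger = logging.getLogger("bioumixer")

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    epochs: int = 80
    batch_size: int = 16
    lr: float = 1e-3
    lr_min: float = 1e-5
    seed: int = 0
    val_fraction: float = 0.2
    device: str = "cpu"            # hint only; this implementation is CPU-native
    model: ModelConfig = field(default_factory=ModelConfig.tiny)
    scdr: SCDRConfig = field(default_factory=SCDRConfig)
    augment: AugmentSpec = field(default_factory=AugmentSpec)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (pairing needs non-sibling views)")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if isinstance(self.model, dict):
            self.model = ModelConfig(**self.model)
        if isinstance(self.scdr, dict):
            self.scdr = SCDRConfig(**self.scdr)
        if isinstance(self.augment, dict):
            self.augment = AugmentSpec(**self.augment)
        self.augment.out_size = self.model.input_size


def config_from_yaml(path) -> TrainConfig:
    """Build a TrainConfig from the documented YAML schema (keys mirror the
    dataclass fields; nested blocks ``model``, ``scdr``, ``augment``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return TrainConfig(**raw)


@dataclass
class Checkpoint:
    model_config: ModelConfig
    scdr_config: SCDRConfig
    state: dict                     # name → ndarray
    label_mean: float
    label_std: float
    image_mean: tuple
    image_std: tuple
    val_mae: float
    seed: int

    def save(self, path):
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "model_config": asdict(self.model_config),
            "scdr_config": asdict(self.scdr_config),
            "label_mean": self.label_mean,
            "label_std": self.label_std,
            "image_mean": list(self.image_mean),
            "image_std": list(self.image_std),
            "val_mae": self.val_mae,
            "seed": self.seed,
        }
        arrays = {f"arr::{k}": v for k, v in self.state.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(f"unsupported checkpoint format {meta.get('format_version')}")
            state = {k[5:]: data[k] for k in data.files if k.startswith("arr::")}
        return cls(
            model_config=ModelConfig(**meta["model_config"]),
            scdr_config=SCDRConfig(**meta["scdr_config"]),
            state=state,
            label_mean=meta["label_mean"],
            label_std=meta["label_std"],
            image_mean=tuple(meta["image_mean"]),
            image_std=tuple(meta["image_std"]),
            val_mae=meta["val_mae"],
            seed=meta["seed"],
        )

    def build(self) -> BioUMixer:
        model = build_model(self.model_config, seed=self.seed)
        model.load_state_dict(self.state)
        return model.eval()

    @property
    def augment_spec(self) -> AugmentSpec:
        return AugmentSpec(out_size=self.model_config.input_size,
                           mean=self.image_mean, std=self.image_std)


@dataclass
class RunLog:
    rows: list = field(default_factory=list)

    def append(self, **row):
        self.rows.append(row)

    def to_jsonl(self, path):
        with open(path, "w") as fh:
            for row in self.rows:
                fh.write(json.dumps(row) + "\n")


def _image_stats(samples) -> tuple:
    """Per-channel mean/std over the training images."""
    acc = np.stack([s.image.reshape(-1, 3).mean(axis=0) for s in samples])
    sq = np.stack([(s.image.reshape(-1, 3) ** 2).mean(axis=0) for s in samples])
    mean = acc.mean(axis=0)
    std = np.sqrt(np.maximum(sq.mean(axis=0) - mean**2, 1e-6))
    return tuple(float(m) for m in mean), tuple(float(s) for s in std)


def predict(model: BioUMixer, samples, spec: AugmentSpec, label_mean: float,
            label_std: float, batch_size: int = 32):
    """Eval-mode predictions in grams plus embeddings for a sample list."""
    model.eval()
    preds, embs = [], []
    with no_grad():
        for lo in range(0, len(samples), batch_size):
            chunk = samples[lo : lo + batch_size]
            x = np.stack([standardize(s.image, spec) for s in chunk])
            v, y = model(Tensor(x))
            preds.append(y.data * label_std + label_mean)
            embs.append(v.data)
    return np.concatenate(preds), np.concatenate(embs)


def train(config: TrainConfig, dataset) -> tuple:
    """Train BioUMixer with the SCDR objective; returns ``(Checkpoint, RunLog)``.

    ``dataset`` is a list of :class:`RegressionSample`.  A ``val_fraction``
    share is held out for best-MAE checkpoint selection; ω and σ_l are set
    from the training-label standard deviation at run start and frozen.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    if len(dataset) < 2 * config.batch_size:
        raise ValueError(
            f"dataset of {len(dataset)} samples is too small for batch_size "
            f"{config.batch_size} (need at least {2 * config.batch_size})"
        )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(config.val_fraction * len(dataset))))
    val_set = [dataset[i] for i in order[:n_val]]
    train_set = [dataset[i] for i in order[n_val:]]

    labels = np.array([s.label for s in train_set])
    label_mean = float(labels.mean())
    label_std = float(labels.std()) or 1.0
    scdr_cfg = config.scdr.resolved(label_std)
    image_mean, image_std = _image_stats(train_set)
    spec = replace(config.augment, mean=image_mean, std=image_std,
                   out_size=config.model.input_size)

    model = build_model(config.model, seed=config.seed)
    optimizer = nn.Adam(model.parameters(), lr=config.lr)
    n_batches = max(1, len(train_set) // config.batch_size)
    total_steps = config.epochs * n_batches
    logger.info("training on %d samples (%d val), %d steps, %d parameters",
                len(train_set), n_val, total_steps, model.n_parameters())

    run_log = RunLog()
    best_state, best_mae = None, np.inf
    step = 0
    for epoch in range(config.epochs):
        model.train()
        perm = rng.permutation(len(train_set))
        ep_reg, ep_scdr, ep_sum, ep_anchor = [], [], [], []
        for b in range(n_batches):
            batch = [train_set[i] for i in perm[b * config.batch_size : (b + 1) * config.batch_size]]
            aug_seed = int(rng.integers(2**31))
            augmented = make_augmented_batch(batch, spec, aug_seed)
            optimizer.lr = nn.cosine_lr(step, total_steps, config.lr, config.lr_min)
            v, y_norm = model(Tensor(augmented.views))
            y_raw = y_norm.data * label_std + label_mean
            labels_norm = (augmented.labels - label_mean) / label_std
            l_sum, breakdown = scdr_total_loss(
                v, y_norm, labels_norm, y_raw, augmented.labels, scdr_cfg)
            if not np.isfinite(breakdown.l_sum):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {step}: {breakdown} "
                    f"(labels {augmented.labels[:4]}...)"
                )
            optimizer.zero_grad()
            l_sum.backward()
            optimizer.step()
            ep_reg.append(breakdown.l_reg)
            ep_scdr.append(breakdown.l_scdr)
            ep_sum.append(breakdown.l_sum)
            ep_anchor.append(breakdown.anchor_fraction)
            step += 1
        val_pred, _ = predict(model, val_set, spec, label_mean, label_std)
        val_metrics = compute_metrics([s.label for s in val_set], val_pred)
        run_log.append(
            epoch=epoch,
            l_reg=float(np.mean(ep_reg)),
            l_scdr=float(np.mean(ep_scdr)),
            l_sum=float(np.mean(ep_sum)),
            anchor_fraction=float(np.mean(ep_anchor)),
            val=val_metrics.to_dict(),
            lr=optimizer.lr,
            time=time.time(),
        )
        logger.info("epoch %d: l_sum=%.4f (reg %.4f, scdr %.4f) val MAE=%.1f",
                    epoch, np.mean(ep_sum), np.mean(ep_reg), np.mean(ep_scdr),
                    val_metrics.mae)
        if val_metrics.mae < best_mae:
            best_mae = val_metrics.mae
            best_state = {k: v.copy() for k, v in model.state_dict().items()}

    checkpoint = Checkpoint(
        model_config=config.model,
        scdr_config=scdr_cfg,
        state=best_state,
        label_mean=label_mean,
        label_std=label_std,
        image_mean=image_mean,
        image_std=image_std,
        val_mae=float(best_mae),
        seed=config.seed,
    )
    return checkpoint, run_log


def evaluate(checkpoint: Checkpoint, dataset, residual_csv=None) -> MetricsReport:
    """Eval-mode metrics of a checkpoint on a dataset; optional residual CSV."""
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    model = checkpoint.build()
    preds, _ = predict(model, dataset, checkpoint.augment_spec,
                       checkpoint.label_mean, checkpoint.label_std)
    labels = [s.label for s in dataset]
    report = compute_metrics(labels, preds)
    if residual_csv is not None:
        residuals_frame(labels, preds, [s.name for s in dataset]).to_csv(
            residual_csv, index=False)
    return report


def ablate(config: TrainConfig, train_set, test_set, cases=None):
    """Run the module-toggle ablation cases end-to-end with a shared seed.

    Returns a pandas table with one row per case: toggles, parameter count
    and test RMSE/MAE/MAPE.
    """
    import pandas as pd

    cases = list(cases or ABLATION_CASES)
    unknown = [c for c in cases if c not in ABLATION_CASES]
    if unknown:
        raise ValueError(f"unknown ablation cases: {unknown}")
    rows = []
    for case in cases:
        toggles = ABLATION_CASES[case]
        cfg = replace(config, model=replace(config.model, toggles=toggles))
        checkpoint, _ = train(cfg, train_set)
        report = evaluate(checkpoint, test_set)
        rows.append({
            "case": case,
            "skips": toggles.skips,
            "feature_block": toggles.feature_block,
            "bio_block": toggles.bio_block,
            "n_params": build_model(cfg.model, cfg.seed).n_parameters(),
            "rmse": report.rmse,
            "mae": report.mae,
            "mape": report.mape,
        })
        logger.info("ablation %s: MAE=%.1f (%d params)", case, report.mae,
                    rows[-1]["n_params"])
    return pd.DataFrame(rows)
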