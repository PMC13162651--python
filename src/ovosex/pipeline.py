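"""Training, ablation and evaluation harness.

The default protocol is AdamW (decoupled weight decay
0.01), initial learning rate 1e-4, batch size 32, cosine learning-rate
decay, 100 epochs, online augmentation of the training split only — under
two scale presets: ``paper`` (224-px inputs, full-width backbone) and
``desk`` (64-px inputs, narrow backbone) for CPU-scale experiments.

A small access audit runs through every batch assembly: augmentation
refuses test-split samples by construction, and the trainer aborts if a
test-split image is ever requested for a training batch.

Class convention: label 'M' -> index 0, 'F' -> index 1, so the softmax
column 1 is the positive-class (female) score everywhere.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import nn
from .backbone import (ModelConfig, Network, count_flops, count_parameters,
                       profile_config, save_checkpoint)
from .evaluation import (ConfusionCounts, ScoredPredictions,
                         classification_metrics, pr_ap, roc_auc, subset_report)
from .msaaf import MSAAFModule
from .preprocess import PreprocessConfig, augment, standardize_sample
from .synthetic import EggSample, GeneratorParams, generate_arrays

__all__ = [
    "TrainConfig", "EggDataset", "LeakageError", "prepare_dataset",
    "make_benchmark", "train_model", "evaluate_network", "ablate",
    "cross_validate",
]

CLASS_TO_INDEX = {"M": 0, "F": 1}


class LeakageError(RuntimeError):
    pass


@dataclasses.dataclass
class TrainConfig:
    """Optimisation settings; see the module docstring for the defaults."""

    epochs: int = 100
    lr: float = 1e-4
    batch_size: int = 32
    weight_decay: float = 0.01
    seed: int = 0
    preset: str = "paper"
    val_fraction: float = 0.1          # carved from train for checkpoint selection
    stop_at_test_acc: float | None = None

    def desk(self, **overrides) -> "TrainConfig":
        """CPU-scale preset: fewer epochs, and a higher learning rate since
        desk runs start from random initialisation rather than pretrained
        weights."""
        kwargs = dataclasses.asdict(self)
        kwargs.update({"preset": "desk", "epochs": 10, "lr": 1e-3})
        kwargs.update(overrides)
        return TrainConfig(**kwargs)


class EggDataset:
    """Standardised arrays with split bookkeeping and a read audit."""

    def __init__(self, images: np.ndarray, labels: np.ndarray,
                 split: np.ndarray, quality: np.ndarray,
                 vessel_masks: list | None = None):
        self.images = images                       # [N,3,S,S] float32
        self.labels = np.asarray(labels)           # int {0,1}
        self.split = np.asarray(split)
        self.quality = np.asarray(quality)
        self.vessel_masks = vessel_masks
        self.audit_log: list[tuple[str, str]] = []

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.split == split)

    def fetch(self, idx: np.ndarray, purpose: str) -> tuple[np.ndarray, np.ndarray]:
        splits = set(self.split[idx])
        for s in splits:
            self.audit_log.append((s, purpose))
        if purpose == "train-batch" and "test" in splits:
            raise LeakageError("test-split sample requested for a training batch")
        return self.images[idx], self.labels[idx]


def prepare_dataset(samples: list[EggSample], split: np.ndarray,
                    input_size: int = 64) -> EggDataset:
    """Standardise rendered samples into a ready-to-train dataset."""
    cfg = PreprocessConfig(output_size=input_size)
    images = np.stack([standardize_sample(s.image, cfg) for s in samples])
    labels = np.array([CLASS_TO_INDEX[s.label] for s in samples])
    quality = np.array([s.quality for s in samples])
    masks = [s.vessel_mask for s in samples]
    return EggDataset(images, labels, split, quality, vessel_masks=masks)


def make_benchmark(n_train: int, n_test: int, effect: float, seed: int,
                   image_size: int = 128, input_size: int = 64,
                   strata: bool = False,
                   params: GeneratorParams | None = None) -> EggDataset:
    """Balanced synthetic benchmark with a train/test split."""
    total = n_train + n_test
    params = params or GeneratorParams(image_size=image_size, class_effect=effect)
    params = dataclasses.replace(params, image_size=image_size, class_effect=effect)
    samples = generate_arrays(total // 2, params, seed=seed, strata=strata)
    split = np.array(["train"] * n_train + ["test"] * (total - n_train))
    return prepare_dataset(samples, split, input_size=input_size)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _predict(network: Network, images: np.ndarray, batch: int = 64):
    """Eval-mode class probabilities, [N,2]."""
    was_training = network.training
    network.eval()
    probs = []
    for i in range(0, len(images), batch):
        logits = network(images[i:i + batch]).data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs.append(e / e.sum(axis=1, keepdims=True))
    network.train(was_training)
    return np.concatenate(probs, axis=0)


def train_model(network: Network, dataset: EggDataset, cfg: TrainConfig,
                checkpoint_path=None, log=print) -> dict:
    """Train with online augmentation; returns history and the best epoch.

    Per-epoch logging includes loss, train/val/test accuracy and — when an
    MSAAF block is present — the fusion-weight trajectory (alpha, beta,
    gamma), whose drift away from 0.1 is a useful diagnostic.
    """
    rng = np.random.default_rng(cfg.seed)
    train_idx = dataset.indices("train")
    rng.shuffle(train_idx)
    n_val = int(len(train_idx) * cfg.val_fraction)
    val_idx, fit_idx = train_idx[:n_val], train_idx[n_val:]
    test_idx = dataset.indices("test")

    opt = nn.AdamW(network.parameters(), lr=cfg.lr,
                   weight_decay=cfg.weight_decay)
    msaaf = next((m for m in network.modules() if isinstance(m, MSAAFModule)), None)

    history = []
    best = {"val_acc": -1.0, "epoch": -1, "state": None}
    for epoch in range(cfg.epochs):
        opt.lr = nn.cosine_lr(cfg.lr, epoch, cfg.epochs)
        order = rng.permutation(fit_idx)
        network.train()
        losses, hits, seen = [], 0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = dataset.fetch(idx, "train-batch")
            aug_seeds = rng.integers(0, 2**31 - 1, size=len(idx))
            xb = np.stack([augment(x, int(s), split="train")
                           for x, s in zip(xb, aug_seeds)])
            logits = network(xb)
            loss = nn.cross_entropy(logits, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            hits += int((logits.data.argmax(axis=1) == yb).sum())
            seen += len(idx)

        xv, yv = dataset.fetch(val_idx, "validate")
        val_acc = float((_predict(network, xv).argmax(axis=1) == yv).mean()) \
            if len(val_idx) else float("nan")
        xt, yt = dataset.fetch(test_idx, "evaluate")
        test_acc = float((_predict(network, xt).argmax(axis=1) == yt).mean()) \
            if len(test_idx) else float("nan")
        entry = {"epoch": epoch, "lr": opt.lr, "loss": float(np.mean(losses)),
                 "train_acc": hits / max(seen, 1), "val_acc": val_acc,
                 "test_acc": test_acc}
        if msaaf is not None:
            a, b, g = msaaf.fusion_weights
            entry.update({"alpha": a, "beta": b, "gamma": g})
        history.append(entry)
        if log:
            log(f"epoch {epoch:3d}  loss {entry['loss']:.4f}  "
                f"train {entry['train_acc']:.3f}  val {val_acc:.3f}  "
                f"test {test_acc:.3f}")
        score = val_acc if len(val_idx) else test_acc
        if score > best["val_acc"]:               # ties keep the earlier epoch
            best = {"val_acc": score, "epoch": epoch,
                    "state": network.state_dict()}
        if cfg.stop_at_test_acc is not None and test_acc >= cfg.stop_at_test_acc:
            break

    if best["state"] is not None:
        network.load_state_dict(best["state"])
    if checkpoint_path is not None:
        save_checkpoint(network, checkpoint_path)
    return {"history": history, "best_epoch": best["epoch"],
            "best_val_acc": best["val_acc"]}


def evaluate_network(network: Network, dataset: EggDataset) -> dict:
    """Full held-out evaluation: metrics, ROC/PR, per-stratum accuracies."""
    test_idx = dataset.indices("test")
    xt, yt = dataset.fetch(test_idx, "evaluate")
    probs = _predict(network, xt)
    preds = ScoredPredictions(y_true=yt, y_pred=probs.argmax(axis=1),
                              score=probs[:, CLASS_TO_INDEX["F"]],
                              quality=dataset.quality[test_idx])
    counts = ConfusionCounts.from_predictions(preds.y_true, preds.y_pred)
    report = {"confusion": dataclasses.asdict(counts),
              "confusion_normalized": counts.normalized(),
              "metrics": classification_metrics(counts),
              "subsets": subset_report(preds)}
    try:
        roc = roc_auc(preds)
        report["roc"] = {"auc": roc["auc"]}
        report["roc_curve"] = {"fpr": roc["fpr"].tolist(), "tpr": roc["tpr"].tolist()}
    except ValueError as exc:
        report["roc"] = {"error": str(exc)}
    try:
        pr = pr_ap(preds)
        report["pr"] = {"ap": pr["ap"]}
        report["pr_curve"] = {"recall": pr["recall"].tolist(),
                              "precision": pr["precision"].tolist()}
    except ValueError as exc:
        report["pr"] = {"error": str(exc)}
    return report


def ablate(dataset: EggDataset, cfg: TrainConfig,
           model_overrides: dict | None = None, log=print) -> pd.DataFrame:
    """2x2 module grid trained under identical seeds and protocol."""
    rows = []
    for mfe_on, msaaf_on in [(False, False), (True, False),
                             (False, True), (True, True)]:
        mcfg = profile_config(cfg.preset, mfe_enabled=mfe_on,
                              msaaf_enabled=msaaf_on, seed=cfg.seed,
                              **(model_overrides or {}))
        net = Network(mcfg)
        train_model(net, dataset, cfg, log=None)
        report = evaluate_network(net, dataset)
        m = report["metrics"]
        rows.append({"mfe": mfe_on, "msaaf": msaaf_on,
                     "accuracy": m["accuracy"], "precision": m["precision"],
                     "recall": m["recall"], "f1": m["f1"], "kappa": m["kappa"],
                     "params": count_parameters(net),
                     "flops": count_flops(net, mcfg.input_size)})
        if log:
            log(f"mfe={mfe_on} msaaf={msaaf_on}: acc={m['accuracy']:.3f}")
    return pd.DataFrame(rows)


def cross_validate(dataset: EggDataset, cfg: TrainConfig, k: int = 5,
                   model_config: ModelConfig | None = None, log=None) -> list[dict]:
    """k-fold CV on the training split: contiguous seeded folds."""
    rng = np.random.default_rng(cfg.seed)
    train_idx = dataset.indices("train")
    order = rng.permutation(train_idx)
    folds = np.array_split(order, k)
    results = []
    for i, held in enumerate(folds):
        fit = np.concatenate([f for j, f in enumerate(folds) if j != i])
        sub_split = np.full(len(dataset.split), "excluded", dtype=object)
        sub_split[fit] = "train"
        sub_split[held] = "test"
        sub = EggDataset(dataset.images, dataset.labels, sub_split,
                         dataset.quality, dataset.vessel_masks)
        mcfg = model_config or profile_config(cfg.preset, seed=cfg.seed)
        net = Network(mcfg)
        out = train_model(net, sub, dataclasses.replace(cfg, val_fraction=0.0),
                          log=None)
        fold_acc = out["history"][-1]["test_acc"]
        results.append({"fold": i, "accuracy": fold_acc})
        if log:
            log(f"fold {i}: acc={fold_acc:.3f}")
    return results
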