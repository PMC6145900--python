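"""Optimization loop: Adam, validation-loss checkpointing, LR decay, early stop.

The schedule: train up to ``max_epochs``; after every epoch compute the loss
on the validation partition; save a checkpoint whenever validation loss
strictly improves on the best so far; halve the learning rate after
``lr_patience`` (default 5) consecutive epochs without improvement; stop
after ``stop_patience`` (default 20) consecutive epochs without improvement.
Both patience counters reset on improvement, and the LR counter also resets
after a decay.  The returned parameters are the best-validation checkpoint,
not the final state.

The schedule logic lives in :class:`LRSchedule`, separable from the gradient
loop so it can be exercised against stubbed validation-loss sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import roc_auc
from .models import ModelSpec, Network, build_model
from .preprocess import NodeSample
from .splits import AugmentPlan, augment_partition, oversample_ene

__all__ = [
    "TrainSpec",
    "TrainHistory",
    "LRSchedule",
    "samples_to_arrays",
    "train",
    "cross_validate",
]


@dataclass(frozen=True)
class TrainSpec:
    """Optimization hyperparameters."""

    lr_init: float = 0.001
    batch_size: int = 20
    max_epochs: int = 100
    lr_decay_factor: float = 0.5
    lr_patience: int = 5
    stop_patience: int = 20
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    oversample_validation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_patience <= 0 or self.stop_patience <= 0:
            raise ValueError("patience values must be positive")
        if self.stop_patience <= self.lr_patience:
            raise ValueError("stop_patience must exceed lr_patience")


@dataclass
class TrainHistory:
    """Per-epoch record of the run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    checkpoint: list[bool] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    stopped_epoch: int | None = None


class LRSchedule:
    """Improvement tracking, LR decay and early stopping.

    ``update(val_loss)`` returns ``(improved, lr, stop)``.  Improvement means
    a strict decrease of the best validation loss seen so far (no minimum
    delta).
    """

    def __init__(self, lr_init: float, decay_factor: float, lr_patience: int, stop_patience: int):
        self.lr = lr_init
        self.decay_factor = decay_factor
        self.lr_patience = lr_patience
        self.stop_patience = stop_patience
        self.best = float("inf")
        self.since_improvement = 0
        self.since_improvement_or_decay = 0

    def update(self, val_loss: float) -> tuple[bool, float, bool]:
        improved = val_loss < self.best
        if improved:
            self.best = val_loss
            self.since_improvement = 0
            self.since_improvement_or_decay = 0
        else:
            self.since_improvement += 1
            self.since_improvement_or_decay += 1
            if self.since_improvement_or_decay >= self.lr_patience:
                self.lr *= self.decay_factor
                self.since_improvement_or_decay = 0
        stop = self.since_improvement >= self.stop_patience
        return improved, self.lr, stop


def samples_to_arrays(samples: list[NodeSample]) -> tuple[dict, np.ndarray]:
    """Stack NodeSamples into the network's input dict and a target matrix."""
    inputs = {
        "box": np.stack([s.box_input for s in samples]).astype(np.float64),
        "small": np.stack([s.small_input for s in samples]).astype(np.float64),
        "hpv": np.array([s.covariates.hpv_p16 for s in samples], dtype=np.float64),
    }
    targets = np.array([s.target for s in samples], dtype=np.float64)
    return inputs, targets


def _take(inputs: dict, idx) -> dict:
    return {k: v[idx] for k, v in inputs.items()}


def train(
    model: Network,
    train_samples,
    val_samples,
    spec: TrainSpec,
) -> tuple[list[np.ndarray], TrainHistory]:
    """Run the optimization loop; returns (best-checkpoint state, history).

    ``train_samples``/``val_samples`` may be NodeSample lists or pre-stacked
    ``(inputs, targets)`` pairs.  The model is left holding the best
    checkpoint on return.
    """
    tr = train_samples if isinstance(train_samples, tuple) else samples_to_arrays(train_samples)
    va = val_samples if isinstance(val_samples, tuple) else samples_to_arrays(val_samples)
    tr_inputs, tr_targets = tr
    va_inputs, va_targets = va
    n = len(tr_targets)
    if n == 0 or len(va_targets) == 0:
        raise ValueError("training and validation partitions must be nonempty")

    rng = np.random.default_rng(spec.seed)
    opt = model.make_optimizer()
    opt.beta1, opt.beta2 = spec.adam_beta1, spec.adam_beta2
    sched = LRSchedule(spec.lr_init, spec.lr_decay_factor, spec.lr_patience, spec.stop_patience)
    history = TrainHistory()
    best_state = model.get_state()

    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            opt.zero_grad()
            loss = model.loss_and_backward(_take(tr_inputs, idx), tr_targets[idx], rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {n_batches} "
                    f"(lr={sched.lr:.2e}); aborting"
                )
            opt.step(sched.lr)
            epoch_loss += loss
            n_batches += 1
        val_loss = model.loss(va_inputs, va_targets, train=False)
        improved, lr_after, stop = sched.update(val_loss)
        history.train_loss.append(epoch_loss / max(n_batches, 1))
        history.val_loss.append(float(val_loss))
        history.lr.append(lr_after)
        history.checkpoint.append(improved)
        if improved:
            history.best_epoch = epoch
            history.best_val_loss = float(val_loss)
            best_state = model.get_state()
        if stop:
            history.stopped_epoch = epoch
            break

    model.set_state(best_state)
    return best_state, history


def _stratified_folds(labels: list[str], k: int, seed: int) -> list[np.ndarray]:
    """Largest-remainder stratified k folds over sample indices."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    folds: list[list[int]] = [[] for _ in range(k)]
    for lab in sorted(by_class):
        idx = np.array(by_class[lab])
        rng.shuffle(idx)
        # Evenly apportion this class across folds (sizes differ by <= 1).
        base, extra = divmod(len(idx), k)
        start = 0
        for f in range(k):
            take = base + (1 if f < extra else 0)
            folds[f].extend(idx[start : start + take].tolist())
            start += take
    return [np.array(sorted(f)) for f in folds]


def cross_validate(
    samples: list[NodeSample],
    model_spec: ModelSpec,
    train_spec: TrainSpec,
    k: int = 5,
    seed: int = 0,
    oversample_factor: int = 2,
    augment_plan: AugmentPlan | None = None,
) -> dict:
    """Stratified k-fold cross-validation of the network.

    Each fold's training side receives ENE oversampling and geometric
    augmentation; the held-out fold is evaluated untouched.  Reports per-fold
    AUCs for both endpoints and their means (the ENE mean is the headline
    robustness figure).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    import warnings

    labels = [("nm_ene" if s.ene else "nm_no_ene" if s.nm else "negative") for s in samples]
    class_sizes: dict[str, int] = {}
    for lab in labels:
        class_sizes[lab] = class_sizes.get(lab, 0) + 1
    if any(n < k for n in class_sizes.values()):
        warnings.warn(f"a class has fewer than k={k} members; folds will be degenerate")

    folds = _stratified_folds(labels, k, seed)
    results = {"fold_auc_ene": [], "fold_auc_nm": []}
    for f, hold in enumerate(folds):
        hold_set = set(hold.tolist())
        tr_samples = [s for i, s in enumerate(samples) if i not in hold_set]
        te_samples = [samples[i] for i in hold]
        tr_samples = oversample_ene(tr_samples, oversample_factor, seed=seed + f)
        plan = augment_plan or AugmentPlan(seed=seed + f)
        tr_samples = augment_partition(tr_samples, plan)
        model = build_model(model_spec, seed=seed + f)
        train(model, tr_samples, te_samples, train_spec)
        inputs, targets = samples_to_arrays(te_samples)
        probs = model.predict_proba(**{k_: inputs[k_] for k_ in ("box", "small", "hpv")})
        for j, key in enumerate(("fold_auc_nm", "fold_auc_ene")):
            if len(np.unique(targets[:, j])) == 2:
                results[key].append(roc_auc(probs[:, j], targets[:, j]))
            else:
                results[key].append(float("nan"))
    results["mean_auc_ene"] = float(np.nanmean(results["fold_auc_ene"]))
    results["mean_auc_nm"] = float(np.nanmean(results["fold_auc_nm"]))
    return results
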