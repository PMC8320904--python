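"""Training loop, optimizer schedule and cross-validation fold protocols.

The published schedule is Adam at an initial learning rate of 1e-5 with a
staircase decay of 0.94 every 2e4 steps, batches of three augmented crops,
1e5 iterations, Xavier-initialized weights, batch-norm momentum 0.9 and
dropout keep probability 0.6. That schedule is hours of GPU work; a named
scaled-down smoke profile (500 steps, 64x64 crops, base width 8, lr 1e-3)
exercises the identical code path at desk scale.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .nn import autodiff as ad
from .preprocess import SMOKE_AUGMENT, AugmentConfig, augment_pair
from .network import (
    SMOKE_NETWORK,
    NetworkConfig,
    PixelBNN,
    save_checkpoint,
)

__all__ = [
    "TrainConfig",
    "SMOKE_TRAIN",
    "FoldSchedule",
    "lr_schedule",
    "make_folds",
    "Adam",
    "train",
    "TrainResult",
    "TrackedDataset",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 3
    total_iterations: int = 100_000
    lr_initial: float = 1e-5
    lr_decay: float = 0.94
    lr_decay_every: int = 20_000
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    checkpoint_every: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.total_iterations, self.lr_decay_every) < 1:
            raise ValueError("batch size, iterations and decay interval must be >= 1")
        if self.lr_initial <= 0 or not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_initial must be > 0 and lr_decay in (0, 1]")


#: desk-scale profile: same loop, small problem (pairs with SMOKE_NETWORK and
#: SMOKE_AUGMENT)
SMOKE_TRAIN = TrainConfig(
    batch_size=4, total_iterations=500, lr_initial=1e-3, checkpoint_every=500
)


def lr_schedule(step: int, cfg: TrainConfig) -> float:
    """Staircase decay: lr_initial * lr_decay ** floor(step / lr_decay_every)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return cfg.lr_initial * cfg.lr_decay ** (step // cfg.lr_decay_every)


@dataclass(frozen=True)
class FoldSchedule:
    """k-fold partition; each fold is (train ids, test ids) over images, with
    optional patient grouping that co-assigns a patient's images."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    group_key: str = "image"

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_folds(
    ids,
    k: int,
    group_key=None,
    seed: int = 0,
) -> FoldSchedule:
    """Deal groups round-robin into k test folds of near-equal size.

    `group_key` maps an id to its group (e.g. patient); all ids of a group
    share a fold. Groups are shuffled by `seed` before dealing, and fold
    sizes (in groups) differ by at most one.
    """
    ids = list(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if group_key is None:
        groups = {i: [i] for i in ids}
    else:
        groups = {}
        for i in ids:
            groups.setdefault(group_key(i), []).append(i)
    names = sorted(groups)
    if len(names) < k:
        raise ValueError(f"cannot split {len(names)} groups into {k} folds")
    rng = np.random.default_rng(seed)
    order = [names[j] for j in rng.permutation(len(names))]
    test_sets: list[list[str]] = [[] for _ in range(k)]
    for idx, name in enumerate(order):
        test_sets[idx % k].extend(groups[name])
    folds = []
    for test in test_sets:
        test_set = set(test)
        train = tuple(i for i in ids if i not in test_set)
        folds.append((train, tuple(sorted(test, key=ids.index))))
    return FoldSchedule(
        folds=tuple(folds), group_key="patient" if group_key else "image"
    )


class Adam:
    """Adam over the model's parameter list; lr supplied per step."""

    def __init__(self, params, cfg: TrainConfig):
        self.params = list(params)
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        cfg = self.cfg
        self.t += 1
        bc1 = 1.0 - cfg.adam_beta1**self.t
        bc2 = 1.0 - cfg.adam_beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= cfg.adam_beta1
            m += (1.0 - cfg.adam_beta1) * p.grad
            v *= cfg.adam_beta2
            v += (1.0 - cfg.adam_beta2) * np.square(p.grad)
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + cfg.adam_eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class TrackedDataset:
    """List-like dataset wrapper that records every index it serves, so fold
    protocols can assert that training never touched a test image."""

    def __init__(self, pairs, ids=None):
        self.pairs = list(pairs)
        self.ids = list(ids) if ids is not None else list(range(len(self.pairs)))
        self.accessed: set = set()

    def __len__(self):
        return len(self.pairs)

    def __getitem__(self, i):
        self.accessed.add(self.ids[i])
        return self.pairs[i]


@dataclass
class TrainResult:
    loss_trace: list[tuple[int, float, float]]  # (step, lr, loss)
    checkpoints: list[Path] = field(default_factory=list)
    final_model: PixelBNN | None = None

    @property
    def losses(self) -> list[float]:
        return [loss for _, _, loss in self.loss_trace]

    def write_trace(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "lr", "loss"])
            writer.writerows(self.loss_trace)


def train(
    model: PixelBNN,
    dataset,
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
    augment: AugmentConfig | None = None,
    out_dir=None,
) -> TrainResult:
    """Run `cfg.total_iterations` Adam steps of cross-entropy training over
    randomly augmented batches. Fully reproducible for a given rng seed.

    `dataset` is a sequence of (FundusImage, VesselMask) pairs — typically a
    :class:`TrackedDataset` so fold hygiene can be asserted afterwards.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    augment = augment or AugmentConfig()
    optimizer = Adam(model.parameters(), cfg)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    result = TrainResult(loss_trace=[])
    for step in range(cfg.total_iterations):
        idx = rng.integers(0, len(dataset), size=cfg.batch_size)
        imgs, masks = [], []
        for i in idx:
            img, mask = dataset[int(i)]
            cont, m = augment_pair(img, mask, augment, rng)
            imgs.append(cont.pixels)
            masks.append(m.pixels)
        batch = np.stack(imgs)
        targets = np.stack(masks).astype(np.float32)

        logits = model.forward_logits(batch, training=True, rng=rng)
        loss = ad.sigmoid_cross_entropy(logits, targets)
        loss_val = loss.item()
        if not math.isfinite(loss_val):
            raise FloatingPointError(
                f"non-finite loss {loss_val} at step {step}; aborting"
            )
        optimizer.zero_grad()
        loss.backward()
        lr = lr_schedule(step, cfg)
        optimizer.step(lr)
        result.loss_trace.append((step, lr, loss_val))

        done = step + 1 == cfg.total_iterations
        if out_dir is not None and ((step + 1) % cfg.checkpoint_every == 0 or done):
            path = out_dir / f"checkpoint_{step + 1:07d}.npz"
            save_checkpoint(model, path, extra={"step": step + 1})
            result.checkpoints.append(path)

    result.final_model = model
    return result


def smoke_profile(seed: int = 0):
    """(NetworkConfig, TrainConfig, AugmentConfig) for the desk-scale run."""
    return SMOKE_NETWORK, replace(SMOKE_TRAIN, seed=seed), SMOKE_AUGMENT
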