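"""Autoencoder training: loss, splits, the average-brain reference and Adam.

Training minimizes the mean absolute error between input and
reconstruction, computed over *all* voxels of the box (background
included; a mask-restricted loss is available behind a flag).  The
trivial reference level is the "average brain": the voxelwise mean of
the training volumes, the best input-independent reconstruction.  A
model that has learned anything about individual differences must sit
below that level on held-out data.

Model selection follows best-validation checkpointing: training always
runs to ``max_iterations`` and the returned weights are the ones with
the lowest validation MAE seen at any evaluation point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .architecture import CAE
from .nn import Adam
from .volume import GreyMatterVolume

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "AverageBrain",
    "LearningCurve",
    "mae_loss",
    "average_brain",
    "split_cohort",
    "train_cae",
]


@dataclass(frozen=True)
class SplitSpec:
    """Subject counts for the train/validation/test partition.

    Defaults are the reference cohort split (172 = 138 + 16 + 18).
    """

    n_train: int = 138
    n_val: int = 16
    n_test: int = 18
    seed: int = 0


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and loop settings (defaults are the reference values)."""

    alpha: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    max_iterations: int = 50_000
    eval_interval: int = 100
    loss_masked: bool = False
    calibrate_init: bool = True
    head_scale: float | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha", "beta1", "beta2", "batch_size",
                     "max_iterations", "eval_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class AverageBrain:
    """Voxelwise mean of the training volumes (the trivial reference)."""

    data: np.ndarray
    n: int

    def mae_against(self, volumes: np.ndarray, mask: np.ndarray | None = None) -> float:
        return mae_loss(volumes, np.broadcast_to(self.data, volumes.shape),
                        mask=mask)


@dataclass
class LearningCurve:
    """Per-evaluation MAE records for every monitored set."""

    records: pd.DataFrame  # columns: iteration, split, mae, reference_mae

    def final(self, split: str) -> float:
        sub = self.records[self.records["split"] == split]
        return float(sub.iloc[-1]["mae"])

    def best(self, split: str) -> float:
        sub = self.records[self.records["split"] == split]
        return float(sub["mae"].min())

    def reference(self, split: str) -> float:
        sub = self.records[self.records["split"] == split]
        return float(sub.iloc[0]["reference_mae"])

    def series(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def mae_loss(batch_in: np.ndarray, batch_out: np.ndarray,
             mask: np.ndarray | None = None) -> float:
    """Mean absolute difference over every voxel (and the batch).

    With ``mask`` given, the mean runs over in-mask voxels only.
    """
    a = np.asarray(batch_in)
    b = np.asarray(batch_out)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    d = np.abs(a.astype(np.float64) - b.astype(np.float64))
    if mask is not None:
        m = np.broadcast_to(mask, d.shape)
        return float(d[m].mean())
    return float(d.mean())


def average_brain(volumes) -> AverageBrain:
    """Exact voxelwise arithmetic mean of the given volumes."""
    arr = _stack(volumes)
    if arr.shape[0] == 0:
        raise ValueError("average_brain requires at least one volume")
    return AverageBrain(data=arr.mean(axis=0, dtype=np.float64).astype(np.float32),
                        n=arr.shape[0])


def split_cohort(cohort, split: SplitSpec):
    """Seeded uniform partition into (train, val, test) lists."""
    cohort = list(cohort)
    total = split.n_train + split.n_val + split.n_test
    if total != len(cohort):
        raise ValueError(
            f"split counts sum to {total} but cohort has {len(cohort)} subjects")
    order = np.random.default_rng(split.seed).permutation(len(cohort))
    train = [cohort[i] for i in order[: split.n_train]]
    val = [cohort[i] for i in order[split.n_train : split.n_train + split.n_val]]
    test = [cohort[i] for i in order[split.n_train + split.n_val :]]
    return train, val, test


def _stack(volumes) -> np.ndarray:
    arrs = []
    for v in volumes:
        arrs.append(v.data if isinstance(v, GreyMatterVolume) else np.asarray(v))
    return np.stack(arrs).astype(np.float32) if arrs else np.empty((0,))


def _check_standardized(volumes, label):
    for v in volumes:
        if isinstance(v, GreyMatterVolume) and not v.standardized:
            raise ValueError(
                f"{label} volume {v.subject_id!r} is not standardized; "
                "run standardize() first")


def train_cae(model: CAE, train, val, test, external=None,
              config: TrainConfig = TrainConfig(),
              eval_subset: int | None = None) -> tuple[CAE, LearningCurve]:
    """Train with Adam on shuffled mini-batches; return best-validation weights.

    ``train``/``val``/``test`` are lists of standardized volumes from
    the primary site; ``external`` is an optional transfer cohort from
    another site, monitored (never trained on) at every evaluation.
    ``eval_subset`` caps the number of training volumes used for the
    train-MAE estimate at evaluation time.

    The average-brain reference MAE of each monitored set — a pure data
    statistic, independent of training — is logged with every record.
    """
    for vols, label in ((train, "train"), (val, "val"), (test, "test"),
                        (external or [], "external")):
        _check_standardized(vols, label)

    Xtr = _stack(train)
    sets = {"train": Xtr if eval_subset is None else Xtr[:eval_subset],
            "val": _stack(val), "test": _stack(test)}
    if external:
        sets["external"] = _stack(external)

    ave = average_brain(train)
    ref = {name: ave.mae_against(arr) for name, arr in sets.items()}

    convs = model.conv_layers()
    opt = Adam(convs, alpha=config.alpha, beta1=config.beta1, beta2=config.beta2)
    rng = np.random.default_rng(config.seed)

    if config.calibrate_init:
        model.calibrate_init(Xtr[: config.batch_size],
                             head_scale=config.head_scale)

    mask_all = None
    if config.loss_masked:
        mask_all = np.stack([v.mask for v in train])

    n = Xtr.shape[0]
    order = rng.permutation(n)
    pos = 0
    records = []
    best_val = np.inf
    best_weights = model.get_weights()

    def evaluate(iteration):
        nonlocal best_val, best_weights
        for name, arr in sets.items():
            maes = []
            bs = config.batch_size
            for i in range(0, arr.shape[0], bs):
                batch = arr[i : i + bs]
                recon = model.forward(batch, keep=False)
                maes.append(mae_loss(batch, recon) * batch.shape[0])
            mae = float(np.sum(maes) / arr.shape[0])
            records.append({"iteration": iteration, "split": name,
                            "mae": mae, "reference_mae": ref[name]})
            if name == "val" and mae < best_val:
                best_val = mae
                best_weights = model.get_weights()

    evaluate(0)
    for it in range(1, config.max_iterations + 1):
        if pos + config.batch_size > n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos : pos + config.batch_size]
        pos += config.batch_size
        batch = Xtr[idx]
        recon = model.forward(batch, keep=True)
        diff = recon - batch
        if config.loss_masked:
            m = mask_all[idx]
            grad = (np.sign(diff) * m / max(int(m.sum()), 1)).astype(np.float32)
            loss = mae_loss(batch, recon, mask=m)
        else:
            grad = (np.sign(diff) / diff.size).astype(np.float32)
            loss = mae_loss(batch, recon)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at iteration {it}; "
                "check input scaling or lower the learning rate")
        model.backward(grad)
        opt.step()
        if it % config.eval_interval == 0 or it == config.max_iterations:
            evaluate(it)

    model.set_weights(best_weights)
    curve = LearningCurve(records=pd.DataFrame.from_records(records))
    return model, curve
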