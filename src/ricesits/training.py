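"""Polygon-group-isolated splitting and the optimisation loop.

The split operates at polygon (field) granularity so that spatially
correlated points sampled inside one field never straddle the train/test
boundary; stratification keeps the label mix balanced at polygon level.
Training uses AdamW (lr 0.001), cross-entropy, batch 32, global gradient
norm clipping at 1.0 and a cosine-annealing schedule over the epoch budget
(reduce-on-plateau available by configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .layers import AdamW, clip_grad_norm
from .model import SITSFormer


class SplitError(ValueError):
    pass


@dataclass
class SplitAssignment:
    train_idx: np.ndarray
    test_idx: np.ndarray
    groups: np.ndarray       # polygon id per sample
    seed: int
    test_fraction: float

    def __post_init__(self):
        overlap = np.intersect1d(self.groups[self.train_idx],
                                 self.groups[self.test_idx])
        if overlap.size:
            raise SplitError(f"polygons straddle the split: {overlap[:5]}")


def group_split(polygon_ids: np.ndarray, labels: np.ndarray,
                test_fraction: float = 0.2, seed: int = 0,
                stratify_by_label: bool = True) -> SplitAssignment:
    """Shuffle polygons (within label strata) and cut at the target
    fraction; all points of a polygon land on one side."""
    polygon_ids = np.asarray(polygon_ids)
    labels = np.asarray(labels)
    if polygon_ids.shape != labels.shape:
        raise SplitError("polygon_ids and labels must align")
    if not 0.0 < test_fraction < 1.0:
        raise SplitError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)

    uniq, first = np.unique(polygon_ids, return_index=True)
    poly_label = labels[first]
    strata = ([poly_label == v for v in np.unique(poly_label)]
              if stratify_by_label else [np.ones(len(uniq), dtype=bool)])
    test_polys = []
    for stratum in strata:
        polys = uniq[stratum]
        if len(polys) < 2:
            raise SplitError(
                "need at least 2 polygons per stratum to split")
        n_test = int(round(test_fraction * len(polys)))
        n_test = min(max(n_test, 1), len(polys) - 1)
        perm = rng.permutation(len(polys))
        test_polys.append(polys[perm[:n_test]])
    test_set = np.concatenate(test_polys)
    is_test = np.isin(polygon_ids, test_set)
    return SplitAssignment(train_idx=np.flatnonzero(~is_test),
                           test_idx=np.flatnonzero(is_test),
                           groups=polygon_ids, seed=seed,
                           test_fraction=test_fraction)


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    grad_clip_norm: float = 1.0
    weight_decay: float = 0.01
    scheduler: str = "cosine"        # or "plateau"
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be positive")
        if self.scheduler not in ("cosine", "plateau"):
            raise ValueError(f"unknown scheduler {self.scheduler!r}")


@dataclass
class Batch:
    """Model-ready arrays for one set of samples."""

    features: np.ndarray   # (N, T, C) standardized
    doys: np.ndarray       # (T,)
    mask: np.ndarray       # (N, T)
    labels: np.ndarray     # (N,)
    patches: np.ndarray | None = None

    def subset(self, idx) -> "Batch":
        return Batch(self.features[idx], self.doys, self.mask[idx],
                     self.labels[idx],
                     None if self.patches is None else self.patches[idx])

    def __len__(self):
        return len(self.features)


def _epoch_eval(model, data: Batch, batch_size: int = 512):
    proba = model.predict_proba(data.features, data.doys, data.mask,
                                data.patches, batch_size=batch_size)
    pred = proba.argmax(axis=1)
    n = len(data)
    nll = -np.log(np.maximum(proba[np.arange(n), data.labels], 1e-12)).mean()
    acc = float((pred == data.labels).mean())
    return float(nll), acc


def train_model(model: SITSFormer, train: Batch, val: Batch | None,
                config: TrainConfig) -> dict:
    """Train in place; returns the per-epoch history.

    History keys: loss, acc, val_loss, val_acc (when a validation batch is
    given), lr, grad_norm (mean pre-clip), clipped (count of clipped steps).
    Aborts with diagnostics if the loss diverges to NaN.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.parameters(), lr=config.lr,
                weight_decay=config.weight_decay)
    history = {k: [] for k in ("loss", "acc", "val_loss", "val_acc", "lr",
                               "grad_norm", "clipped")}
    n = len(train)
    plateau_best, plateau_wait = np.inf, 0
    lr = config.lr
    for epoch in range(config.epochs):
        if config.scheduler == "cosine":
            lr = config.lr * 0.5 * (1.0 + np.cos(
                np.pi * epoch / max(config.epochs - 1, 1)))
        opt.lr = lr
        model.train()
        perm = rng.permutation(n)
        losses, correct, norms, clipped = [], 0, [], 0
        for lo in range(0, n, config.batch_size):
            idx = perm[lo:lo + config.batch_size]
            sub = train.subset(idx)
            logits = model.forward(sub.features, sub.doys, sub.mask,
                                   sub.patches)
            loss = ad.softmax_cross_entropy(logits, sub.labels)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"training diverged: loss={lval} at epoch {epoch}, "
                    f"batch {lo // config.batch_size} (lr={lr:.2e})")
            opt.zero_grad()
            loss.backward()
            gnorm = clip_grad_norm(model.parameters(), config.grad_clip_norm)
            clipped += gnorm > config.grad_clip_norm
            norms.append(gnorm)
            opt.step()
            losses.append(lval)
            correct += int((logits.data.argmax(axis=1) == sub.labels).sum())
        history["loss"].append(float(np.mean(losses)))
        history["acc"].append(correct / n)
        history["lr"].append(float(lr))
        history["grad_norm"].append(float(np.mean(norms)))
        history["clipped"].append(int(clipped))
        monitor = history["loss"][-1]
        if val is not None:
            vl, va = _epoch_eval(model, val)
            history["val_loss"].append(vl)
            history["val_acc"].append(va)
            monitor = vl
        if config.scheduler == "plateau":
            if monitor < plateau_best - 1e-6:
                plateau_best, plateau_wait = monitor, 0
            else:
                plateau_wait += 1
                if plateau_wait > config.plateau_patience:
                    lr *= config.plateau_factor
                    plateau_wait = 0
    model.eval()
    return history
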