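"""Training protocol for the four-chamber segmentation network.

The recipe: frames are resized to 128x128 (bilinear; label maps use
nearest-neighbour so no fractional labels appear) and normalized from
8-bit integers to [0, 1]; the dataset is split 80/10/10 into
train/validation/test; optimization is Adam at a fixed learning rate of
1e-3 with per-pixel multiclass cross-entropy, mini-batches of eight and
reshuffling every epoch, for 50 epochs.  After each training epoch the
validation loss and three validation metrics (macro Dice, macro IoU, mean
pixel accuracy) are recorded.  Final-epoch weights are kept — no early
stopping or best-epoch selection.

Validation/test metrics are macro: computed per image, then averaged.
One integer seed fans out deterministically to the split, the shuffles
and the weight initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import nn
from .metrics import MetricsReport, labelmap_metrics
from .unet import UNet, UNetSpec, build_unet

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "preprocess",
    "split_dataset",
    "fit",
    "evaluate_on_test",
    "run_phantom_experiment",
]


@dataclass(frozen=True)
class TrainConfig:
    split_ratios: tuple = (0.8, 0.1, 0.1)
    batch_size: int = 8
    epochs: int = 50
    learning_rate: float = 1e-3
    shuffle_each_epoch: bool = True
    seed: int = 0
    target_size: tuple = (128, 128)

    def __post_init__(self):
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class TrainHistory:
    """Per-epoch loss/metric curves of one training run."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    val_iou: list = field(default_factory=list)
    val_mpa: list = field(default_factory=list)
    config: TrainConfig | None = None

    def __len__(self):
        return len(self.train_loss)

    def to_csv(self) -> str:
        lines = ["epoch,train_loss,val_loss,val_dice,val_iou,val_mpa"]
        for i in range(len(self)):
            lines.append(
                f"{i + 1},{self.train_loss[i]:.6f},{self.val_loss[i]:.6f},"
                f"{self.val_dice[i]:.6f},{self.val_iou[i]:.6f},{self.val_mpa[i]:.6f}"
            )
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        """Compact text summary of the run."""
        if not len(self):
            return "TrainHistory: empty (0 epochs)"
        lines = [
            "Training summary",
            "================",
            f"epochs run            : {len(self)}",
            f"first/last train loss : {self.train_loss[0]:.4f} / {self.train_loss[-1]:.4f}",
            f"first/last val loss   : {self.val_loss[0]:.4f} / {self.val_loss[-1]:.4f}",
            f"final val Dice        : {self.val_dice[-1]:.4f}",
            f"final val IoU         : {self.val_iou[-1]:.4f}",
            f"final val mean px acc : {self.val_mpa[-1]:.4f}",
        ]
        if self.config is not None:
            c = self.config
            lines += [
                f"batch size / lr       : {c.batch_size} / {c.learning_rate}",
                f"seed                  : {c.seed}",
            ]
        return "\n".join(lines)

    def plot(self, path) -> None:
        """Loss and validation-metric curves side by side (PNG)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        ep = np.arange(1, len(self) + 1)
        ax1.plot(ep, self.train_loss, "r-", label="training")
        ax1.plot(ep, self.val_loss, "b-", label="validation")
        ax1.set_xlabel("epoch"), ax1.set_ylabel("cross-entropy loss")
        ax1.legend(), ax1.set_title("Loss history")
        ax2.plot(ep, self.val_dice, label="dice_coeff")
        ax2.plot(ep, self.val_iou, label="IoU")
        ax2.plot(ep, self.val_mpa, label="mean pixel accuracy")
        ax2.set_xlabel("epoch"), ax2.legend(), ax2.set_title("Validation metrics")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def preprocess(frame, mask=None, target_size=(128, 128)):
    """Resize to the working resolution and normalize intensities to [0, 1].

    Frames are resampled bilinearly; label maps use nearest-neighbour so
    the label set is preserved exactly (no interpolated fractional labels).
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be single-channel (2-D)")
    img = frame.astype(np.float32) / 255.0
    if img.shape != tuple(target_size):
        img = resize(
            img, target_size, order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        ).astype(np.float32)
    img = np.clip(img, 0.0, 1.0)
    if mask is None:
        return img, None
    mask = np.asarray(mask)
    if mask.shape != tuple(target_size):
        mask = resize(
            mask, target_size, order=0, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    return img, mask.astype(np.uint8)


def split_dataset(items, ratios=(0.8, 0.1, 0.1), seed=0):
    """Random disjoint, exhaustive train/val/test split.

    Validation and test sizes are floor allocations; the remainder goes
    to training.  Deterministic per seed.
    """
    items = list(items)
    n = len(items)
    if n < 10:
        raise ValueError("need at least 10 items to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(np.floor(n * ratios[1]))
    n_test = int(np.floor(n * ratios[2]))
    n_train = n - n_val - n_test
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train : n_train + n_val]]
    test = [items[i] for i in order[n_train + n_val :]]
    return train, val, test


def _validation_pass(model: UNet, x_val, y_val, batch_size):
    losses = []
    d, j, m = [], [], []
    for i in range(0, len(x_val), batch_size):
        xb = x_val[i : i + batch_size][..., None]
        yb = y_val[i : i + batch_size]
        logits = model.forward(xb, training=False)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        pred = logits.argmax(axis=-1)
        for p, g in zip(pred, yb):
            met = labelmap_metrics(p, g)
            d.append(met["dice"])
            j.append(met["iou"])
            m.append(met["mean_pixel_accuracy"])
    return (
        float(np.sum(losses) / len(x_val)),
        float(np.mean(d)),
        float(np.mean(j)),
        float(np.mean(m)),
    )


def fit(model: UNet, train_set, val_set, config: TrainConfig | None = None) -> TrainHistory:
    """Optimize the network on (frames, labels) arrays.

    ``train_set``/``val_set`` are (X, Y) pairs with X float32 in [0, 1] of
    shape (n, H, W) and Y integer labels of shape (n, H, W).  Aborts with
    a diagnostic if the loss turns non-finite.
    """
    config = config or TrainConfig()
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("empty training or validation split")
    x_tr = np.asarray(x_tr, dtype=np.float32)
    y_tr = np.asarray(y_tr)
    x_va = np.asarray(x_va, dtype=np.float32)
    y_va = np.asarray(y_va)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory(config=config)
    n = len(x_tr)
    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
        batch_losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = x_tr[idx][..., None]
            yb = y_tr[idx]
            logits = model.forward(xb, training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}, "
                    f"batch {i // config.batch_size + 1}: {loss}"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            batch_losses.append(loss)
        vl, vd, vj, vm = _validation_pass(model, x_va, y_va, config.batch_size)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.val_loss.append(vl)
        history.val_dice.append(vd)
        history.val_iou.append(vj)
        history.val_mpa.append(vm)
    return history


def evaluate_on_test(model: UNet, test_set, batch_size: int = 8) -> MetricsReport:
    """Macro metrics of the trained model on a held-out (X, Y) pair."""
    x_te, y_te = test_set
    if len(x_te) == 0:
        raise ValueError("empty test set")
    x_te = np.asarray(x_te, dtype=np.float32)
    preds = []
    for i in range(0, len(x_te), batch_size):
        preds.extend(model.predict(x_te[i : i + batch_size]))
    return MetricsReport.from_pairs(preds, list(np.asarray(y_te)))


def run_phantom_experiment(
    n_frames: int = 200,
    seed: int = 0,
    config: TrainConfig | None = None,
    phantom_config=None,
    spec: UNetSpec | None = None,
):
    """End-to-end desk-scale experiment on synthetic phantoms.

    Generates ``n_frames`` phantoms, preprocesses them to the working
    resolution, splits 80/10/10, trains with the standard recipe and
    evaluates on the held-out split.  Returns (model, history, report).
    """
    from .phantom import PhantomConfig, generate_scene, render

    config = config or TrainConfig(seed=seed)
    phantom_config = phantom_config or PhantomConfig()
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_frames)
    pairs = []
    for s in scene_seeds:
        frame, labels = render(generate_scene(phantom_config, seed=int(s)))
        pairs.append(preprocess(frame, labels, config.target_size))
    split_seed = int(rng.integers(0, 2**31 - 1))
    init_seed = int(rng.integers(0, 2**31 - 1))
    tr, va, te = split_dataset(pairs, config.split_ratios, seed=split_seed)
    stack = lambda part: (
        np.stack([p[0] for p in part]),
        np.stack([p[1] for p in part]),
    )
    model = build_unet(spec, seed=init_seed)
    history = fit(model, stack(tr), stack(va), config)
    report = evaluate_on_test(model, stack(te), config.batch_size)
    return model, history, report
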