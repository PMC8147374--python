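"""Training protocol, recurrent slice-by-slice inference, and the
ablation harness.

Training minimizes the combo loss with Adam over windows of ``U``
consecutive axial slices (truncated backpropagation through the unroll);
the previous-probability input inside a window is the model's own
prediction, and zeros at the window start, matching test-time behaviour
(no teacher forcing).  Windows containing no foreground are downsampled
to 25% to keep the thin target from being drowned out by background.
An early-stopping rule halts training when the validation loss has not
improved for a fixed number of epochs and restores the best-validation
weights.

Inference sweeps a volume in ascending z feeding ``[slice, previous
probability map]`` into the shared-weight unit; when the network carries
the prior path, the PSFE input is the voxelized mean shape's slice at
the same relative axial depth as the current slice (no per-patient
registration of the prior).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.base import BaseEstimator

from .losses import LossConfig, combo_loss
from .meanshape import MeanShapeModel
from .metrics import evaluate_pair
from .nn import Module, Tensor, no_grad
from .nnarch import NetworkSpec, SASeg, assemble_saseg
from .volio import BinaryMask, Volume, normalize_intensity

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Adam",
    "early_stop_epoch",
    "train",
    "predict_volume",
    "run_ablation",
    "SASegSegmenter",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol.

    The defaults follow the published protocol: Adam with batch size 3,
    50 epochs, learning rate 1e-4, early stopping after 5 epochs without
    validation improvement.  ``slice_size`` is the square in-plane
    resolution slices are resampled to before entering the network
    (must be divisible by 16); ``iterations_per_epoch`` fixes how many
    optimizer steps make up one epoch at desk scale.
    """

    batch_size: int = 3
    epochs: int = 50
    learning_rate: float = 1e-4
    early_stop_patience: int = 5
    unroll: int = 4
    slice_size: int = 64
    iterations_per_epoch: int = 25
    val_windows_per_case: int = 8
    empty_window_keep: float = 0.25
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.unroll, self.iterations_per_epoch) < 1:
            raise ValueError("batch_size, epochs, unroll, iterations_per_epoch must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.slice_size % 16:
            raise ValueError("slice_size must be divisible by 16")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def early_stop_epoch(val_losses: list[float], patience: int) -> int | None:
    """Index (0-based) of the epoch at which training stops, or None.

    Training stops at the first epoch after which ``patience``
    consecutive epochs have failed to improve on the best validation
    loss seen so far.
    """
    best = np.inf
    best_i = -1
    for i, v in enumerate(val_losses):
        if v < best:
            best, best_i = v, i
        elif i - best_i >= patience:
            return i
    return None


# ---------------------------------------------------------------------------
# data preparation

class _Case:
    """One volume/mask pair resampled to network resolution."""

    def __init__(self, v: Volume, m: BinaryMask, size: int):
        norm = normalize_intensity(v)
        d = v.n_slices
        self.slices = np.stack(
            [resize(norm.slice(z), (size, size), order=1, anti_aliasing=True) for z in range(d)]
        ).astype(np.float32)
        self.masks = np.stack(
            [
                resize(m.slice(z).astype(float), (size, size), order=0, anti_aliasing=False)
                for z in range(d)
            ]
        ).astype(np.float32)
        self.depth = d
        self.native_shape = v.data.shape
        self.spacing = v.spacing
        self.origin = v.origin


def _prior_stack(mean: MeanShapeModel, depth: int, size: int) -> np.ndarray:
    """Mean-shape slices resampled to (depth, size, size) by relative z."""
    vox = mean.voxelized.data.astype(np.float32)
    dz = vox.shape[2]
    out = np.empty((depth, size, size), dtype=np.float32)
    for z in range(depth):
        zz = int(round(z / max(depth - 1, 1) * (dz - 1)))
        out[z] = resize(vox[:, :, zz], (size, size), order=1, anti_aliasing=True)
    return out


def _window_batch(rng, cases, priors, cfg) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Sample a (B, U, 1, S, S) window batch with foreground downsampling."""
    xs, ys, ps = [], [], []
    while len(xs) < cfg.batch_size:
        ci = int(rng.integers(len(cases)))
        case = cases[ci]
        z0 = int(rng.integers(0, max(case.depth - cfg.unroll, 0) + 1))
        ymask = case.masks[z0 : z0 + cfg.unroll]
        if ymask.sum() == 0 and rng.random() > cfg.empty_window_keep:
            continue
        xs.append(case.slices[z0 : z0 + cfg.unroll, None])
        ys.append(ymask[:, None])
        if priors is not None:
            ps.append(priors[ci][z0 : z0 + cfg.unroll, None])
    return (
        np.stack(xs),
        np.stack(ys),
        np.stack(ps) if priors is not None else None,
    )


def _window_loss(net: SASeg, x, y, prior, cfg) -> Tensor | float:
    probs = net.forward(x, prior)
    total = None
    for t, p in enumerate(probs):
        l = combo_loss(p, y[:, t], cfg.loss)
        total = l if total is None else total + l
    return total * (1.0 / len(probs)) if isinstance(total, Tensor) else total / len(probs)


# ---------------------------------------------------------------------------
# training

def train(
    spec: NetworkSpec,
    data: list[tuple[Volume, BinaryMask]],
    mean: MeanShapeModel | None,
    cfg: TrainConfig,
    validation: list[tuple[Volume, BinaryMask]] | None = None,
) -> tuple[SASeg, TrainHistory]:
    """Fit a network of the given spec; returns (network, history).

    ``validation`` defaults to the training cases (adequate only for
    overfitting experiments).  Fully seeded: weight initialization, data
    order and window sampling all derive from ``cfg.seed``.
    """
    if not data:
        raise ValueError("need at least one training case")
    if spec.has_psfe and mean is None:
        raise ValueError("this spec uses PSFE: a mean shape model is required")
    rng = np.random.default_rng(cfg.seed)
    net = assemble_saseg(spec, seed=int(rng.integers(2**31)))
    cases = [_Case(v, m, cfg.slice_size) for v, m in data]
    priors = (
        [_prior_stack(mean, c.depth, cfg.slice_size) for c in cases] if spec.has_psfe else None
    )
    val_pairs = validation if validation is not None else data
    val_cases = [_Case(v, m, cfg.slice_size) for v, m in val_pairs]
    val_priors = (
        [_prior_stack(mean, c.depth, cfg.slice_size) for c in val_cases]
        if spec.has_psfe
        else None
    )
    # fixed, seeded validation windows
    vrng = np.random.default_rng(cfg.seed + 1)
    val_windows = []
    for ci, c in enumerate(val_cases):
        for _ in range(cfg.val_windows_per_case):
            z0 = int(vrng.integers(0, max(c.depth - cfg.unroll, 0) + 1))
            val_windows.append((ci, z0))

    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_state = net.state_dict()
    for epoch in range(cfg.epochs):
        net.train()
        ep_loss = 0.0
        for _ in range(cfg.iterations_per_epoch):
            x, y, pr = _window_batch(rng, cases, priors, cfg)
            loss = _window_loss(net, x, y, pr, cfg)
            if not np.isfinite(float(loss.data)):
                raise FloatingPointError(
                    f"training diverged (loss={float(loss.data)}) at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
        history.train_loss.append(ep_loss / cfg.iterations_per_epoch)

        net.eval()
        vloss = 0.0
        with no_grad():
            for ci, z0 in val_windows:
                c = val_cases[ci]
                x = c.slices[z0 : z0 + cfg.unroll, None][None]
                y = c.masks[z0 : z0 + cfg.unroll, None][None]
                pr = val_priors[ci][z0 : z0 + cfg.unroll, None][None] if val_priors else None
                vloss += float(_window_loss(net, x, y, pr, cfg).data)
        vloss /= max(len(val_windows), 1)
        history.val_loss.append(vloss)
        if vloss < best_val:
            best_val = vloss
            best_state = net.state_dict()
            history.best_epoch = epoch
        stop = early_stop_epoch(history.val_loss, cfg.early_stop_patience)
        if stop is not None:
            history.stopped_epoch = stop
            break
        history.stopped_epoch = epoch
    net.load_state_dict(best_state)
    return net, history


# ---------------------------------------------------------------------------
# inference

def predict_volume(
    net: SASeg,
    v: Volume,
    mean: MeanShapeModel | None = None,
    slice_size: int = 64,
    threshold: float = 0.5,
) -> tuple[Volume, BinaryMask]:
    """Recurrent slice-by-slice segmentation of a whole volume.

    Returns the probability volume and its thresholded mask on the
    input grid.
    """
    spec = net.spec
    if spec.has_psfe and mean is None:
        raise ValueError("this network uses PSFE: a mean shape model is required")
    case = _Case(v, BinaryMask(np.zeros_like(v.data, dtype=np.uint8), v.spacing, v.origin), slice_size)
    prior = _prior_stack(mean, case.depth, slice_size) if spec.has_psfe else None
    net.eval()
    probs_small = np.empty((case.depth, slice_size, slice_size), dtype=np.float32)
    with no_grad():
        prev = None
        for z in range(case.depth):
            x = Tensor(case.slices[z][None, None])
            pslice = Tensor(prior[z][None, None]) if prior is not None else None
            p = net.forward_slice(x, prev, pslice)
            probs_small[z] = p.data[0, 0]
            prev = p
    nx, ny, _ = v.data.shape
    probs = np.stack(
        [resize(probs_small[z], (nx, ny), order=1, anti_aliasing=False) for z in range(case.depth)],
        axis=2,
    ).astype(np.float32)
    pv = Volume(probs, v.spacing, v.origin)
    pm = BinaryMask((probs >= threshold).astype(np.uint8), v.spacing, v.origin)
    return pv, pm


# ---------------------------------------------------------------------------
# ablation harness

def run_ablation(
    variants: list[str | NetworkSpec | tuple[str | NetworkSpec, LossConfig]],
    train_data: list[tuple[Volume, BinaryMask]],
    test_data: list[tuple[Volume, BinaryMask]],
    mean: MeanShapeModel | None,
    cfg: TrainConfig,
    seeds: tuple[int, ...] = (0, 1, 2),
    enc_channels: tuple[int, ...] | None = None,
    psfe_channels: tuple[int, ...] | None = None,
    collect_predictions: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train every variant on identical splits and seeds; report mean ± sd
    of Dice/ASD/95HD over test cases and seeds.

    A variant is a spec/variant name, optionally paired with a
    LossConfig (for loss ablations).  With ``collect_predictions`` each
    per-case row also carries the predicted mask (column ``pred``), for
    mechanism analyses such as false-positive localisation."""
    if len(variants) < 1:
        raise ValueError("need at least one variant")
    rows = []
    for var in variants:
        loss_cfg = cfg.loss
        if isinstance(var, tuple):
            var, loss_cfg = var
        if isinstance(var, str):
            kw = {}
            if enc_channels:
                kw["enc_channels"] = enc_channels
            if psfe_channels:
                kw["psfe_channels"] = psfe_channels
            spec = NetworkSpec(variant=var, unroll=cfg.unroll, **kw)
        else:
            spec = var
        label = _variant_label(spec, loss_cfg)
        for seed in seeds:
            run_cfg = replace(cfg, seed=seed, loss=loss_cfg)
            net, _ = train(spec, train_data, mean, run_cfg, validation=test_data)
            for case_i, (v, m) in enumerate(test_data):
                _, pred = predict_volume(net, v, mean if spec.has_psfe else None, run_cfg.slice_size)
                r = evaluate_pair(pred, m)
                row = {
                    "variant": label,
                    "seed": seed,
                    "case": case_i,
                    "dice": r.dice,
                    "asd_mm": r.asd_mm,
                    "hd95_mm": r.hd95_mm,
                }
                if collect_predictions:
                    row["pred"] = pred
                rows.append(row)
    df = pd.DataFrame(rows)
    summary = df.groupby("variant")[["dice", "asd_mm", "hd95_mm"]].agg(["mean", "std"])
    summary.columns = ["_".join(c) for c in summary.columns]
    return df, summary


def _variant_label(spec: NetworkSpec, loss_cfg: LossConfig) -> str:
    parts = [spec.variant]
    if loss_cfg.w_bce and not loss_cfg.w_dice:
        parts.append("bce")
    elif loss_cfg.w_dice and not loss_cfg.w_bce:
        parts.append("dice")
    return "+".join(parts)


# ---------------------------------------------------------------------------
# estimator front end

class SASegSegmenter(BaseEstimator):
    """Scikit-learn style front end for the recurrent shape-aware
    segmenter.

    Parameters mirror :class:`NetworkSpec` and :class:`TrainConfig`;
    ``fit`` takes lists of :class:`Volume` and :class:`BinaryMask` (plus
    an optional mean shape model for the PSFE variant), ``predict``
    returns a :class:`BinaryMask` per volume.

    Examples
    --------
    >>> model = SASegSegmenter(variant="saseg", epochs=5)
    >>> model.fit(volumes, masks, mean_shape=mean)          # doctest: +SKIP
    >>> pred = model.predict([volumes[0]])[0]               # doctest: +SKIP
    """

    def __init__(
        self,
        variant: str = "saseg",
        enc_channels: tuple[int, ...] | None = None,
        psfe_channels: tuple[int, ...] | None = None,
        unroll: int = 4,
        batch_size: int = 3,
        epochs: int = 50,
        learning_rate: float = 1e-4,
        early_stop_patience: int = 5,
        slice_size: int = 64,
        iterations_per_epoch: int = 25,
        w_bce: float = 1.0,
        w_dice: float = 1.0,
        seed: int = 0,
    ):
        self.variant = variant
        self.enc_channels = enc_channels
        self.psfe_channels = psfe_channels
        self.unroll = unroll
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.early_stop_patience = early_stop_patience
        self.slice_size = slice_size
        self.iterations_per_epoch = iterations_per_epoch
        self.w_bce = w_bce
        self.w_dice = w_dice
        self.seed = seed

    def _spec(self) -> NetworkSpec:
        kw = {}
        if self.enc_channels:
            kw["enc_channels"] = tuple(self.enc_channels)
        if self.psfe_channels:
            kw["psfe_channels"] = tuple(self.psfe_channels)
        return NetworkSpec(variant=self.variant, unroll=self.unroll, **kw)

    def _cfg(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            early_stop_patience=self.early_stop_patience,
            unroll=self.unroll,
            slice_size=self.slice_size,
            iterations_per_epoch=self.iterations_per_epoch,
            loss=LossConfig(w_bce=self.w_bce, w_dice=self.w_dice),
            seed=self.seed,
        )

    def fit(
        self,
        X: list[Volume],
        y: list[BinaryMask],
        mean_shape: MeanShapeModel | None = None,
        validation: list[tuple[Volume, BinaryMask]] | None = None,
    ) -> "SASegSegmenter":
        if len(X) != len(y):
            raise ValueError("X and y must pair up")
        spec = self._spec()
        self.network_, self.history_ = train(
            spec, list(zip(X, y)), mean_shape, self._cfg(), validation=validation
        )
        self.spec_ = spec
        self.mean_shape_ = mean_shape
        return self

    def predict(self, X: list[Volume]) -> list[BinaryMask]:
        self._check_fitted()
        return [
            predict_volume(self.network_, v, self.mean_shape_, self.slice_size)[1] for v in X
        ]

    def predict_proba(self, X: list[Volume]) -> list[Volume]:
        self._check_fitted()
        return [
            predict_volume(self.network_, v, self.mean_shape_, self.slice_size)[0] for v in X
        ]

    def score(self, X: list[Volume], y: list[BinaryMask]) -> float:
        """Mean Dice over the given cases."""
        from .metrics import dice_score

        preds = self.predict(X)
        return float(np.mean([dice_score(p, t) for p, t in zip(preds, y)]))

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
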