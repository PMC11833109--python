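"""Convolutional-autoencoder classifiers and their composite loss.

Two models are provided:

* ``CAE3DClassifier`` — a single 3D CAE over the 10-slice SSC volume;
  its latent code feeds a fully connected + softmax classification
  head.  It is trained with ``w1 = 0`` (no 2D reconstruction term).
* ``FusedCAEClassifier`` — a 2D CAE (transmission image) and a 3D CAE
  (SSC volume) whose latent codes are concatenated before the
  classification head.

The training objective combines reconstruction and classification:

    L_MSE = w1 * MSE_2d + (1 - w1) * MSE_3d          (per-element,
                                                      mini-batch mean)
    L_CE  = -(1/N) sum_i y_i . log(y_hat_i)           (natural log)
    L     = w2 * L_CE + (1 - w2) * L_MSE

Training is two-phase: the first ``recon_only_epochs`` epochs minimize
L_MSE alone with the classification head frozen; the remaining epochs
minimize the weighted loss L.  Optimization is Adam throughout.

Logits and class probabilities are plain numpy arrays of length C
(batched: N x C rows); probabilities always sum to 1 within 1e-6.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .config import LossWeights, TrainingConfig, derive_seed, to_dict
from .errors import ConfigurationError, InputError, NumericError

EPS_PROB = 1e-12   # probability clamp inside the cross-entropy


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax(x: np.ndarray) -> np.ndarray:
    """Softmax over the last axis, with max-subtraction for stability.

    Accepts a single logit vector of length C or a batch of N x C rows;
    each output row is a valid probability vector summing to 1.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise NumericError("softmax requires finite logits")
    shifted = x - x.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class ReconstructionBatch:
    """Paired input/reconstruction tensors for one mini-batch.

    Tensors may have any per-sample shape; they are flattened to
    (N, M) internally.  The 2D pair may be None only when it carries
    no loss weight (w1 = 0), as in the 3D-only classifier.
    """

    x_3d: np.ndarray
    xhat_3d: np.ndarray
    x_2d: np.ndarray | None = None
    xhat_2d: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_3d = _flat(self.x_3d)
        self.xhat_3d = _flat(self.xhat_3d)
        if self.x_3d.shape != self.xhat_3d.shape:
            raise InputError("3D input/reconstruction shape mismatch")
        if (self.x_2d is None) != (self.xhat_2d is None):
            raise InputError("2D input and reconstruction must come together")
        if self.x_2d is not None:
            self.x_2d = _flat(self.x_2d)
            self.xhat_2d = _flat(self.xhat_2d)
            if self.x_2d.shape != self.xhat_2d.shape:
                raise InputError("2D input/reconstruction shape mismatch")
            if self.x_2d.shape[0] != self.x_3d.shape[0]:
                raise InputError("2D and 3D batch sizes differ")

    @property
    def n(self) -> int:
        return self.x_3d.shape[0]


def _flat(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x.reshape(x.shape[0], -1)


def mse_loss(batch: ReconstructionBatch, w1: float) -> float:
    """Mini-batch averaged weighted reconstruction error.

    Equals ``w1 * MSE_2d + (1 - w1) * MSE_3d`` where each term is the
    per-element squared error averaged over the flattened image
    dimension and the batch.  With ``w1 = 0`` the 2D tensors are never
    referenced.
    """
    if not 0.0 <= w1 <= 1.0:
        raise ConfigurationError("w1: must be in [0, 1]")
    mse3 = float(np.mean((batch.x_3d - batch.xhat_3d) ** 2))
    if w1 == 0.0:
        return (1.0 - w1) * mse3
    if batch.x_2d is None:
        raise InputError("w1 > 0 requires the 2D tensor pair")
    mse2 = float(np.mean((batch.x_2d - batch.xhat_2d) ** 2))
    return w1 * mse2 + (1.0 - w1) * mse3


def cross_entropy(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mini-batch averaged cross-entropy, natural log.

    ``y`` holds one-hot rows; ``y_hat`` valid probability rows.
    Probabilities are clamped at 1e-12 before the log.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise InputError("y and y_hat must share shape")
    if y.ndim == 1:
        y, y_hat = y[None, :], y_hat[None, :]
    if not (np.all((y == 0) | (y == 1))
            and np.allclose(y.sum(axis=1), 1.0)):
        raise InputError("y rows must be one-hot")
    clamped = np.clip(y_hat, EPS_PROB, None)
    return float(-np.mean(np.sum(y * np.log(clamped), axis=1)))


def total_loss(l_ce: float, l_mse: float, w2: float) -> float:
    """Weighted combination ``w2 * L_CE + (1 - w2) * L_MSE``."""
    if not 0.0 <= w2 <= 1.0:
        raise ConfigurationError("w2: must be in [0, 1]")
    return w2 * l_ce + (1.0 - w2) * l_mse


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

def normalize_images(x: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 1]."""
    x = np.asarray(x, dtype=np.float64)
    flat = x.reshape(x.shape[0], -1)
    lo = flat.min(axis=1).reshape((-1,) + (1,) * (x.ndim - 1))
    hi = flat.max(axis=1).reshape((-1,) + (1,) * (x.ndim - 1))
    span = np.where(hi > lo, hi - lo, 1.0)
    return (x - lo) / span


@dataclass
class CellImageDataset:
    """Model-ready image stacks: normalized, with a channel axis."""

    x_3d: np.ndarray                 # (N, 1, D, H, W)
    x_2d: np.ndarray | None          # (N, 1, H, W) or None
    labels: np.ndarray | None        # (N,) int class labels

    @classmethod
    def from_records(cls, records, labels=None,
                     use_2d: bool = True) -> "CellImageDataset":
        x3 = normalize_images(np.stack([r.ssc_image for r in records]))
        x2 = (normalize_images(np.stack([r.trans_image for r in records]))
              if use_2d else None)
        if labels is None:
            labels = np.array([r.true_class for r in records], dtype=int)
        else:
            labels = np.asarray(labels, dtype=int)
        return cls(x3[:, None], None if x2 is None else x2[:, None], labels)

    def __len__(self) -> int:
        return self.x_3d.shape[0]

    def subset(self, idx) -> "CellImageDataset":
        return CellImageDataset(
            self.x_3d[idx],
            None if self.x_2d is None else self.x_2d[idx],
            None if self.labels is None else self.labels[idx],
        )


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

def _pool_factors(shape: tuple[int, ...],
                  levels: int) -> list[tuple[int, ...]]:
    """Per-level pooling factors; spatial axes halve per level, the
    depth axis halves only while it stays divisible."""
    factors = []
    cur = list(shape)
    for _ in range(levels):
        f = []
        for ax, s in enumerate(cur):
            is_depth = len(shape) == 3 and ax == 0
            if is_depth:
                k = 2 if (s % 2 == 0 and s > 1) else 1
            else:
                if s % 2 != 0:
                    raise ConfigurationError(
                        f"image_size: spatial extent {s} not divisible by 2 "
                        f"at every pooling level (need {levels} levels)")
                k = 2
            f.append(k)
            cur[ax] = s // k
        factors.append(tuple(f))
    return factors


class CAEBranch:
    """One modality's encoder/decoder pair with a dense latent."""

    def __init__(self, ndim: int, shape: tuple[int, ...],
                 channels: tuple[int, ...], latent_dim: int,
                 rng: np.random.Generator, tag: str):
        self.ndim = ndim
        self.shape = shape
        conv = nn.Conv2d if ndim == 2 else nn.Conv3d
        convT = nn.ConvTranspose2d if ndim == 2 else nn.ConvTranspose3d
        factors = _pool_factors(shape, len(channels))

        enc_layers: list[nn.Layer] = []
        c_prev = 1
        cur = list(shape)
        for lvl, (c, f) in enumerate(zip(channels, factors)):
            enc_layers += [conv(c_prev, c, rng, name=f"{tag}.enc{lvl}"),
                           nn.ReLU(), nn.MaxPoolND(f)]
            c_prev = c
            cur = [s // k for s, k in zip(cur, f)]
        self.bottleneck_shape = (c_prev,) + tuple(cur)
        flat = int(np.prod(self.bottleneck_shape))
        enc_layers += [nn.Flatten(),
                       nn.Dense(flat, latent_dim, rng, name=f"{tag}.to_z")]
        self.encoder = nn.Sequential(enc_layers)

        dec_layers: list[nn.Layer] = [
            nn.Dense(latent_dim, flat, rng, name=f"{tag}.from_z"),
            nn.ReLU(), nn.Reshape(self.bottleneck_shape)]
        rev_channels = (1,) + tuple(channels[:-1])
        for lvl in range(len(channels) - 1, -1, -1):
            dec_layers.append(convT(channels[lvl], rev_channels[lvl],
                                    factors[lvl], rng,
                                    name=f"{tag}.dec{lvl}"))
            dec_layers.append(nn.ReLU() if lvl > 0 else nn.Sigmoid())
        self.decoder = nn.Sequential(dec_layers)
        self.params = self.encoder.params + self.decoder.params

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.forward(x)

    def decode(self, z: np.ndarray) -> np.ndarray:
        return self.decoder.forward(z)


class _BaseCAEClassifier:
    """Shared forward/inference machinery of the CAE classifiers."""

    modalities: tuple[str, ...]
    branches: dict[str, CAEBranch]
    head: nn.Dense
    config: TrainingConfig

    @property
    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for m in self.modalities:
            out += self.branches[m].params
        out += self.head.params
        return out

    def _inputs(self, x_3d, x_2d) -> dict[str, np.ndarray]:
        xs = {"3d": np.asarray(x_3d, dtype=float)}
        if "2d" in self.modalities:
            if x_2d is None:
                raise InputError("fused model requires the 2D input")
            xs["2d"] = np.asarray(x_2d, dtype=float)
        return xs

    def forward(self, x_3d: np.ndarray,
                x_2d: np.ndarray | None = None) -> dict:
        """Full pass: encode, decode, classify.

        Returns a dict with per-modality latents ``z`` and
        reconstructions ``recon``, the concatenated latent ``z_cat``,
        ``logits`` and softmax ``probs``.
        """
        xs = self._inputs(x_3d, x_2d)
        z = {m: self.branches[m].encode(xs[m]) for m in self.modalities}
        recon = {m: self.branches[m].decode(z[m]) for m in self.modalities}
        z_cat = np.concatenate([z[m] for m in self.modalities], axis=1)
        logits = self.head.forward(z_cat)
        return {"x": xs, "z": z, "recon": recon, "z_cat": z_cat,
                "logits": logits, "probs": softmax(logits)}

    # --- convenience API -------------------------------------------------
    def encode_3d(self, x):
        return self.branches["3d"].encode(np.asarray(x, dtype=float))

    def decode_3d(self, z):
        return self.branches["3d"].decode(z)

    def classify(self, z_cat: np.ndarray) -> np.ndarray:
        return softmax(self.head.forward(z_cat))


class FusedCAEClassifier(_BaseCAEClassifier):
    """2D + 3D CAE with concatenated latents feeding the classifier."""

    modalities = ("2d", "3d")

    def __init__(self, config: TrainingConfig,
                 shape_3d: tuple[int, int, int],
                 shape_2d: tuple[int, int]):
        self.config = config
        rng2 = np.random.default_rng(derive_seed("branch2d", config.seed))
        rng3 = np.random.default_rng(derive_seed("branch3d", config.seed))
        rngh = np.random.default_rng(derive_seed("head", config.seed))
        self.branches = {
            "2d": CAEBranch(2, shape_2d, config.conv_channels,
                            config.latent_dim, rng2, "b2d"),
            "3d": CAEBranch(3, shape_3d, config.conv_channels,
                            config.latent_dim, rng3, "b3d"),
        }
        self.head = nn.Dense(2 * config.latent_dim, config.n_classes,
                             rngh, name="head")

    def encode_2d(self, x):
        return self.branches["2d"].encode(np.asarray(x, dtype=float))

    def decode_2d(self, z):
        return self.branches["2d"].decode(z)


class CAE3DClassifier(_BaseCAEClassifier):
    """The fused network with the 2D branch (and concatenation) removed."""

    modalities = ("3d",)

    def __init__(self, config: TrainingConfig,
                 shape_3d: tuple[int, int, int]):
        if config.loss_weights.w1 != 0.0:
            raise ConfigurationError(
                "loss_weights.w1: must be 0 for the 3D-only classifier "
                "(no 2D image input)")
        self.config = config
        rng3 = np.random.default_rng(derive_seed("branch3d", config.seed))
        rngh = np.random.default_rng(derive_seed("head", config.seed))
        self.branches = {
            "3d": CAEBranch(3, shape_3d, config.conv_channels,
                            config.latent_dim, rng3, "b3d"),
        }
        self.head = nn.Dense(config.latent_dim, config.n_classes,
                             rngh, name="head")


def build_fused_cae(config: TrainingConfig,
                    shape_3d: tuple[int, int, int],
                    shape_2d: tuple[int, int]) -> FusedCAEClassifier:
    return FusedCAEClassifier(config, shape_3d, shape_2d)


def build_3d_cae(config: TrainingConfig,
                 shape_3d: tuple[int, int, int]) -> CAE3DClassifier:
    if config.loss_weights.w1 != 0.0:
        config = TrainingConfig(**{**to_dict(config),
                                   "loss_weights": LossWeights(
                                       w1=0.0, w2=config.loss_weights.w2)})
    return CAE3DClassifier(config, shape_3d)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _batch_losses(model: _BaseCAEClassifier, out: dict,
                  y_1h: np.ndarray) -> tuple[float, float]:
    w1 = model.config.loss_weights.w1
    if "2d" in model.modalities:
        rb = ReconstructionBatch(out["x"]["3d"], out["recon"]["3d"],
                                 out["x"]["2d"], out["recon"]["2d"])
    else:
        rb = ReconstructionBatch(out["x"]["3d"], out["recon"]["3d"])
    l_mse = mse_loss(rb, w1)
    l_ce = cross_entropy(y_1h, out["probs"])
    return l_mse, l_ce


def train(model: _BaseCAEClassifier, dataset: CellImageDataset,
          config: TrainingConfig | None = None):
    """Two-phase training; returns ``(model, history)``.

    Epochs 1..recon_only_epochs minimize the reconstruction loss only
    (the classification head receives no gradient and stays at its
    initialization); the remaining epochs minimize
    ``w2 * L_CE + (1 - w2) * L_MSE``.  ``history`` is a list of
    per-epoch dicts with the mini-batch means of L_MSE, L_CE and the
    optimized total loss, plus the phase name.
    """
    if config is None:
        config = model.config
    if dataset.labels is None:
        raise InputError("training requires a labeled dataset")
    n = len(dataset)
    w = config.loss_weights
    y_all = one_hot(dataset.labels, config.n_classes)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(derive_seed("train", config.seed))

    history: list[dict] = []
    for epoch in range(1, config.total_epochs + 1):
        recon_phase = epoch <= config.recon_only_epochs
        order = rng.permutation(n)
        mse_sum = ce_sum = tot_sum = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            nb = len(idx)
            x3 = dataset.x_3d[idx]
            x2 = dataset.x_2d[idx] if dataset.x_2d is not None else None
            y = y_all[idx]

            opt.zero_grad()
            out = model.forward(x3, x2)
            l_mse, l_ce = _batch_losses(model, out, y)
            if recon_phase:
                l_opt = l_mse
                recon_scale, ce_scale = 1.0, 0.0
            else:
                l_opt = total_loss(l_ce, l_mse, w.w2)
                recon_scale, ce_scale = (1.0 - w.w2), w.w2

            # gradients into each branch latent
            grad_z = {m: np.zeros_like(out["z"][m])
                      for m in model.modalities}
            for m in model.modalities:
                wm = w.w1 if m == "2d" else (1.0 - w.w1)
                if wm == 0.0 or recon_scale == 0.0:
                    continue
                x, xh = out["x"][m], out["recon"][m]
                m_dim = x[0].size
                dxhat = recon_scale * wm * 2.0 * (xh - x) / (nb * m_dim)
                grad_z[m] += model.branches[m].decoder.backward(dxhat)
            if ce_scale > 0.0:
                dlogits = ce_scale * (out["probs"] - y) / nb
                dz_cat = model.head.backward(dlogits)
                ofs = 0
                for m in model.modalities:
                    dim = out["z"][m].shape[1]
                    grad_z[m] += dz_cat[:, ofs:ofs + dim]
                    ofs += dim
            for m in model.modalities:
                model.branches[m].encoder.backward(grad_z[m])
            opt.step()

            mse_sum += l_mse
            ce_sum += l_ce
            tot_sum += l_opt
            n_batches += 1
        history.append({
            "epoch": epoch,
            "l_mse": mse_sum / n_batches,
            "l_ce": ce_sum / n_batches,
            "l_total": tot_sum / n_batches,
            "phase": "recon" if recon_phase else "joint",
        })
    return model, history


def predict(model: _BaseCAEClassifier, x_3d: np.ndarray,
            x_2d: np.ndarray | None = None) -> np.ndarray:
    """Class probabilities, one row per input cell (pure function)."""
    xs = model._inputs(x_3d, x_2d)
    z = [model.branches[m].encode(xs[m]) for m in model.modalities]
    return softmax(model.head.forward(np.concatenate(z, axis=1)))


def encode_latent(model: _BaseCAEClassifier, x_3d: np.ndarray,
                  x_2d: np.ndarray | None = None) -> np.ndarray:
    """Concatenated latent matrix, one row per input cell."""
    xs = model._inputs(x_3d, x_2d)
    z = [model.branches[m].encode(xs[m]) for m in model.modalities]
    return np.concatenate(z, axis=1)


def history_to_csv(history: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["epoch", "l_mse", "l_ce", "l_total", "phase"])
        writer.writeheader()
        writer.writerows(history)


def save_model(model: _BaseCAEClassifier, path: str | Path,
               shape_2d: tuple[int, int] | None = None) -> None:
    """Save weights (npz) plus a JSON sidecar with the full config."""
    path = Path(path)
    arrays = {f"param_{i:04d}": p.value
              for i, p in enumerate(model.params)}
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "kind": type(model).__name__,
        "config": to_dict(model.config),
        "shape_3d": list(model.branches["3d"].shape),
        "shape_2d": (list(model.branches["2d"].shape)
                     if "2d" in model.modalities else None),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> _BaseCAEClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = TrainingConfig(**meta["config"])
    if meta["kind"] == "FusedCAEClassifier":
        model = FusedCAEClassifier(cfg, tuple(meta["shape_3d"]),
                                   tuple(meta["shape_2d"]))
    else:
        model = CAE3DClassifier(cfg, tuple(meta["shape_3d"]))
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.params):
        p.value[...] = data[f"param_{i:04d}"]
    return model
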