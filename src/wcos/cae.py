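"""1-D convolutional autoencoder trained on normal heart-sound windows.

Encoder: two strided Conv1d layers (1 -> i -> j channels), each followed by
batch normalization and Leaky ReLU. Decoder: two transposed-conv layers
(j -> i -> 1) with batch norm + ReLU after the first and a final Tanh, so
reconstructions live in (-1, 1). Training minimizes the per-element mean L1
reconstruction error with Adam, on normal samples only — the semi-supervised
premise is that a model fitted to normal morphology reconstructs murmurs badly,
so its latent space separates the classes.

The latent fed to the one-class SVM is the final encoder activation mean-pooled
down to ``pooled_steps`` time steps and flattened (length ``pooled_steps * j``);
the decoder consumes the *un-pooled* feature maps. A raw flatten of the feature
maps would hand the kernel machine 10^4-10^5 dimensions; pooling keeps the
representation compact without losing the coarse temporal energy profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .windowing import Sample, ABNORMAL

CHANNEL_GRID = ((2, 4), (4, 8), (8, 16), (16, 32), (32, 64), (64, 128))


@dataclass(frozen=True)
class CAEConfig:
    """Architecture and training hyperparameters of the autoencoder."""

    channels: tuple[int, int] = (8, 16)
    kernel_size: int = 16
    stride: int = 8
    padding: int = 4
    leaky_slope: float = 0.2
    pooled_steps: int = 4
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        i, j = self.channels
        if i < 1 or j < 1:
            raise ValueError("channel counts must be positive")
        if self.stride < 1 or self.pooled_steps < 1:
            raise ValueError("stride and pooled_steps must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CAEConfig":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        return cls(**d)


@dataclass
class TrainReport:
    """Per-epoch mean training loss plus provenance."""

    epoch_losses: list[float]
    final_loss: float
    seed: int
    config: CAEConfig


class CAE:
    """The autoencoder network, built for a fixed input window length."""

    def __init__(self, config: CAEConfig, input_length: int):
        i, j = config.channels
        k, s, p = config.kernel_size, config.stride, config.padding
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 4]))
        self.config = config
        self.input_length = int(input_length)

        self.conv1 = nn.Conv1d(1, i, k, s, p, rng)
        self.bn1 = nn.BatchNorm1d(i)
        self.act1 = nn.LeakyReLU(config.leaky_slope)
        self.conv2 = nn.Conv1d(i, j, k, s, p, rng)
        self.bn2 = nn.BatchNorm1d(j)
        self.act2 = nn.LeakyReLU(config.leaky_slope)

        L1 = self.conv1.out_len(self.input_length)
        L2 = self.conv2.out_len(L1)
        if L2 < config.pooled_steps:
            raise ValueError(
                f"encoded length {L2} shorter than pooled_steps={config.pooled_steps}"
            )
        self._enc_lengths = (self.input_length, L1, L2)
        op1 = L1 - ((L2 - 1) * s + k - 2 * p)
        op2 = self.input_length - ((L1 - 1) * s + k - 2 * p)
        self.deconv1 = nn.ConvTranspose1d(j, i, k, s, p, op1, rng)
        self.dbn1 = nn.BatchNorm1d(i)
        self.dact1 = nn.ReLU()
        self.deconv2 = nn.ConvTranspose1d(i, 1, k, s, p, op2, rng)
        self.dact2 = nn.Tanh()
        self.train_mode(False)

    # ---- mode -------------------------------------------------------------
    def train_mode(self, flag: bool = True) -> None:
        self.training = flag
        self.bn1.training = flag
        self.bn2.training = flag
        self.dbn1.training = flag

    # ---- forward ----------------------------------------------------------
    def _check_length(self, X: np.ndarray) -> None:
        if X.shape[-1] != self.input_length:
            need = self.input_length - X.shape[-1]
            raise ValueError(
                f"input length {X.shape[-1]} incompatible with model length "
                f"{self.input_length}; pad input by {need} samples"
            )

    def encode(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (feature_maps, latents).

        ``X`` is (batch, length) or (length,); feature_maps are
        (batch, j, T); latents are (batch, pooled_steps * j).
        """
        X = np.atleast_2d(np.asarray(X, dtype=nn.DTYPE))
        self._check_length(X)
        h = X[:, None, :]
        h = self.act1.forward(self.bn1.forward(self.conv1.forward(h)))
        h = self.act2.forward(self.bn2.forward(self.conv2.forward(h)))
        latent = self.pool(h)
        return h, latent

    def pool(self, feature_maps: np.ndarray) -> np.ndarray:
        chunks = np.array_split(feature_maps, self.config.pooled_steps, axis=2)
        pooled = np.stack([c.mean(axis=2) for c in chunks], axis=2)  # (B, j, T0)
        return pooled.reshape(pooled.shape[0], -1)

    def decode(self, feature_maps: np.ndarray) -> np.ndarray:
        """Map encoder feature maps back to (batch, length) waveforms in (-1, 1)."""
        if feature_maps.shape[1] != self.config.channels[1] or (
            feature_maps.shape[2] != self._enc_lengths[2]
        ):
            raise ValueError(
                f"feature-map shape {feature_maps.shape[1:]} does not match "
                f"encoder output ({self.config.channels[1]}, {self._enc_lengths[2]})"
            )
        h = self.dact1.forward(self.dbn1.forward(self.deconv1.forward(feature_maps)))
        h = self.dact2.forward(self.deconv2.forward(h))
        return h[:, 0, :]

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        fm, _ = self.encode(X)
        return self.decode(fm)

    def _backward(self, grad_xhat: np.ndarray) -> None:
        g = grad_xhat[:, None, :]
        g = self.deconv2.backward(self.dact2.backward(g))
        g = self.deconv1.backward(self.dbn1.backward(self.dact1.backward(g)))
        g = self.conv2.backward(self.bn2.backward(self.act2.backward(g)))
        self.conv1.backward(self.bn1.backward(self.act1.backward(g)))

    # ---- parameters -------------------------------------------------------
    def _layers(self):
        return [self.conv1, self.bn1, self.conv2, self.bn2, self.deconv1, self.dbn1, self.deconv2]

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads()]

    # ---- checkpointing ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {f"param_{i}": p for i, p in enumerate(self.parameters())}
        for name, bn in (("bn1", self.bn1), ("bn2", self.bn2), ("dbn1", self.dbn1)):
            arrays[f"{name}_mean"] = bn.running_mean
            arrays[f"{name}_var"] = bn.running_var
        meta = json.dumps(
            {"config": self.config.to_dict(), "input_length": self.input_length, "version": 1}
        )
        np.savez(str(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CAE":
        with np.load(str(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(CAEConfig.from_dict(meta["config"]), meta["input_length"])
            for i, p in enumerate(model.parameters()):
                p[...] = data[f"param_{i}"]
            for name, bn in (("bn1", model.bn1), ("bn2", model.bn2), ("dbn1", model.dbn1)):
                bn.running_mean = data[f"{name}_mean"]
                bn.running_var = data[f"{name}_var"]
        return model


def reconstruction_loss(X: np.ndarray, Xhat: np.ndarray) -> float:
    """Mean absolute reconstruction error (per-element L1 average)."""
    loss, _ = nn.l1_loss(np.asarray(X, float), np.asarray(Xhat, float))
    return loss


def _extract_values(samples) -> np.ndarray:
    if isinstance(samples, np.ndarray):
        return np.atleast_2d(samples.astype(np.float64))
    values = []
    for s in samples:
        if isinstance(s, Sample):
            if s.label == ABNORMAL:
                raise ValueError(
                    f"abnormal sample from record {s.record_id!r} passed to "
                    "train_cae; the autoencoder is trained on normal data only"
                )
            values.append(s.values)
        else:
            values.append(np.asarray(s, dtype=np.float64))
    return np.stack(values)


def train_cae(normal_samples, config: CAEConfig = CAEConfig()) -> tuple[CAE, TrainReport]:
    """Fit the autoencoder on normal windows with Adam + L1 loss.

    ``normal_samples`` may be a 2-D array (n, length) or a list of
    :class:`~wcos.windowing.Sample`; any abnormal-labeled sample raises.
    Seeded initialization and shuffling make the run bit-reproducible.
    """
    X = _extract_values(normal_samples).astype(nn.DTYPE)
    if X.shape[0] < 1:
        raise ValueError("training set is empty")
    model = CAE(config, X.shape[1])
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 5]))
    model.train_mode(True)
    epoch_losses: list[float] = []
    n = X.shape[0]
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = X[order[start : start + config.batch_size]]
            fm, _ = model.encode(batch)
            xhat = model.decode(fm)
            loss, grad = nn.l1_loss(batch, xhat)
            nn.Adam.zero_grads(model.gradients())
            model._backward(grad)
            opt.step(model.gradients())
            losses.append(loss)
        epoch_losses.append(float(np.mean(losses)))
    model.train_mode(False)
    report = TrainReport(
        epoch_losses=epoch_losses,
        final_loss=epoch_losses[-1] if epoch_losses else float("nan"),
        seed=config.seed,
        config=config,
    )
    return model, report
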