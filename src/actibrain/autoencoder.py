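"""1-D convolutional autoencoder features of daytime activity segments.

A 720-sample day segment is compressed by three strided conv blocks
(720 -> 240 -> 120 -> 60 time steps) into a C x 60 latent array, and
reconstructed by mirrored transposed convolutions with a linear output layer.
Hidden activations are ReLU; training minimizes reconstruction error with
Adam and reports RMSE per epoch on the train and validation splits, keeping
the best-validation checkpoint.

Per-subject features: each retained day is encoded, the latent is averaged
over channels to a 60-vector, and the subject's vectors are averaged over
days — so every subject contributes exactly 60 autoencoder features
regardless of channel width or number of days worn.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .preprocess import SEGMENT_LENGTH, DaySegment

__all__ = [
    "AutoencoderConfig",
    "SplitAssignment",
    "ConvAutoencoder",
    "make_split",
    "build_autoencoder",
    "train_autoencoder",
    "ae_features",
    "ae_feature_table",
    "save_model",
    "load_model",
    "AE_COLUMNS",
]

AE_COLUMNS = [f"ae_{i:02d}" for i in range(1, 61)]


@dataclass(frozen=True)
class AutoencoderConfig:
    """Architecture and training hyperparameters.

    The product of the encoder strides times ``latent_length`` must equal
    ``input_length`` (720 = 12 x 60 for the defaults), so the latent always
    has 60 time steps.
    """

    input_length: int = SEGMENT_LENGTH
    latent_length: int = 60
    channels: tuple[int, ...] = (8, 16, 32)
    kernel_size: int = 7
    strides: tuple[int, ...] = (3, 2, 2)
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")
        if any(c < 1 for c in self.channels):
            raise ValueError("channel widths must be >= 1")
        if int(np.prod(self.strides)) * self.latent_length != self.input_length:
            raise ValueError(
                "product of strides x latent_length must equal input_length "
                f"({np.prod(self.strides)} x {self.latent_length} != {self.input_length})"
            )

    def layer_plan(self) -> list[dict]:
        """Per-layer (length, padding, output_padding) satisfying the geometry."""
        plan = []
        length = self.input_length
        for stride in self.strides:
            target = length // stride
            pad = None
            for p in range((self.kernel_size + stride) // 2 + 1):
                if nn.conv_output_length(length, self.kernel_size, stride, p) == target:
                    pad = p
                    break
            if pad is None:
                raise ValueError(f"no padding makes {length} -> {target} with k={self.kernel_size}, s={stride}")
            out_pad = length - nn.conv_transpose_output_length(
                target, self.kernel_size, stride, pad, 0
            )
            if not 0 <= out_pad < stride:
                raise ValueError("inconsistent transposed-conv geometry")
            plan.append({"in_length": length, "out_length": target, "padding": pad, "output_padding": out_pad})
            length = target
        return plan


@dataclass(frozen=True)
class SplitAssignment:
    """Subject-level train/validation/test partition at ratios 8:1:1."""

    assignment: dict[str, str]
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def subjects(self, part: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == part]


def make_split(
    subject_ids: list[str],
    seed: int,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SplitAssignment:
    """Randomly partition subjects (not days) into train/validation/test.

    Subject-level assignment prevents leakage of a subject's days across the
    splits.  Counts honour the ratios to rounding: n_val = n_test =
    round(0.1 n), the rest train.
    """
    if len(subject_ids) < 10:
        raise ValueError("need at least 10 subjects for an 8:1:1 split")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    rng = np.random.default_rng(seed)
    order = list(np.array(subject_ids)[rng.permutation(len(subject_ids))])
    n = len(order)
    n_val = int(round(ratios[1] * n))
    n_test = int(round(ratios[2] * n))
    assignment = {}
    for i, sid in enumerate(order):
        if i < n_val:
            assignment[sid] = "validation"
        elif i < n_val + n_test:
            assignment[sid] = "test"
        else:
            assignment[sid] = "train"
    return SplitAssignment(assignment=assignment, ratios=ratios, seed=seed)


class ConvAutoencoder:
    """Encoder/decoder stacks over (N, 1, 720) arrays; float64 throughout."""

    def __init__(self, config: AutoencoderConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        plan = config.layer_plan()
        k = config.kernel_size
        self.encoder: list = []
        in_ch = 1
        for ch, stride, lay in zip(config.channels, config.strides, plan):
            self.encoder.append(nn.Conv1d(in_ch, ch, k, stride, lay["padding"], rng=rng))
            self.encoder.append(nn.ReLU())
            in_ch = ch
        self.decoder: list = []
        rev = list(zip(config.channels, config.strides, plan))[::-1]
        for i, (ch, stride, lay) in enumerate(rev):
            out_ch = rev[i + 1][0] if i + 1 < len(rev) else 1
            self.decoder.append(
                nn.ConvTranspose1d(ch, out_ch, k, stride, lay["padding"], lay["output_padding"], rng=rng)
            )
            if i + 1 < len(rev):
                self.decoder.append(nn.ReLU())  # linear final layer
        self.history: dict[str, list[float]] = {"train_rmse": [], "val_rmse": []}

    # -- plumbing ----------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.encoder + self.decoder:
            out.extend(layer.params)
        return out

    def set_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.params, values):
            p[...] = v

    def _run(self, layers: list, x: np.ndarray) -> np.ndarray:
        for layer in layers:
            x = layer.forward(x)
        return x

    def _backprop(self, layers: list, grad: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        grads: list[np.ndarray] = []
        for layer in reversed(layers):
            grad, layer_grads = layer.backward(grad)
            grads = layer_grads + grads
        return grad, grads

    # -- public surface ----------------------------------------------------
    def encode(self, segments: np.ndarray) -> np.ndarray:
        """(N, 720) -> latent (N, C, 60)."""
        x = np.asarray(segments, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.config.input_length:
            raise ValueError(f"segments must have length {self.config.input_length}")
        return self._run(self.encoder, x[:, None, :])

    def decode(self, latent: np.ndarray) -> np.ndarray:
        """latent (N, C, 60) -> reconstruction (N, 720)."""
        return self._run(self.decoder, latent)[:, 0, :]

    def reconstruct(self, segments: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(segments))

    def rmse(self, segments: np.ndarray) -> float:
        x = np.atleast_2d(np.asarray(segments, dtype=float))
        recon = self.reconstruct(x)
        return float(np.sqrt(np.mean((recon - x) ** 2)))

    def train_step(self, batch: np.ndarray, optimizer: nn.Adam) -> float:
        """One Adam update on the reconstruction error; returns batch RMSE.

        The update direction is the MSE gradient; since RMSE = sqrt(MSE) is a
        monotone transform the minimizers coincide and Adam normalizes the
        scale, so training curves are reported as RMSE.
        """
        x = batch[:, None, :]
        latent = self._run(self.encoder, x)
        recon = self._run(self.decoder, latent)
        err = recon - x
        grad = 2.0 * err / err.size
        grad, dec_grads = self._backprop(self.decoder, grad)
        _, enc_grads = self._backprop(self.encoder, grad)
        optimizer.step(enc_grads + dec_grads)
        return float(np.sqrt(np.mean(err**2)))


def build_autoencoder(config: AutoencoderConfig | None = None) -> ConvAutoencoder:
    """Construct an (untrained) autoencoder with seeded initial parameters."""
    return ConvAutoencoder(config or AutoencoderConfig())


def train_autoencoder(
    model: ConvAutoencoder,
    segments: np.ndarray,
    segment_subjects: list[str] | np.ndarray,
    split: SplitAssignment,
    config: AutoencoderConfig | None = None,
) -> ConvAutoencoder:
    """Train with Adam on the train split; track RMSE and keep the best
    validation checkpoint.

    ``segments`` is (n_days, 720) and ``segment_subjects`` gives the subject
    of each row, so the subject-level split maps onto rows.  Fully seeded:
    identical inputs and config give identical parameters.
    """
    config = config or model.config
    segments = np.asarray(segments, dtype=float)
    subjects = np.asarray(segment_subjects)
    if segments.shape[0] != subjects.shape[0]:
        raise ValueError("segments and segment_subjects must align")
    part = np.array([split.assignment.get(s, "train") for s in subjects])
    train_x = segments[part == "train"]
    val_x = segments[part == "validation"]
    if train_x.shape[0] == 0:
        raise ValueError("empty training split")

    rng = np.random.default_rng(config.seed + 1)
    optimizer = nn.Adam(model.params, lr=config.learning_rate)
    best_val = np.inf
    best_params = [p.copy() for p in model.params]
    for _epoch in range(config.epochs):
        order = rng.permutation(train_x.shape[0])
        epoch_sq, epoch_n = 0.0, 0
        for start in range(0, train_x.shape[0], config.batch_size):
            batch = train_x[order[start : start + config.batch_size]]
            batch_rmse = model.train_step(batch, optimizer)
            epoch_sq += batch_rmse**2 * batch.size
            epoch_n += batch.size
        train_rmse = float(np.sqrt(epoch_sq / epoch_n))
        val_rmse = model.rmse(val_x) if val_x.shape[0] else train_rmse
        model.history["train_rmse"].append(train_rmse)
        model.history["val_rmse"].append(val_rmse)
        if val_rmse < best_val:
            best_val = val_rmse
            best_params = [p.copy() for p in model.params]
    model.set_params(best_params)
    return model


def ae_features(
    model: ConvAutoencoder, segments_by_subject: dict[str, list[DaySegment] | list[np.ndarray]]
) -> tuple[pd.DataFrame, list[str]]:
    """Per-subject 60-vector: channel-averaged latent, then day-averaged.

    Subjects with zero retained days are skipped and returned in the second
    element so callers can log them.
    """
    rows: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for sid, segs in segments_by_subject.items():
        if not segs:
            skipped.append(sid)
            continue
        values = np.stack([s.values if isinstance(s, DaySegment) else np.asarray(s) for s in segs])
        latent = model.encode(values)  # (days, C, 60)
        per_day = latent.mean(axis=1)  # channel average -> (days, 60)
        rows[sid] = per_day.mean(axis=0)  # day average
    table = pd.DataFrame.from_dict(rows, orient="index", columns=AE_COLUMNS)
    table.index.name = "subject_id"
    return table.sort_index(), skipped


def ae_feature_table(
    model: ConvAutoencoder, segments_by_subject: dict[str, list[DaySegment]]
) -> pd.DataFrame:
    return ae_features(model, segments_by_subject)[0]


def save_model(model: ConvAutoencoder, path: str | Path) -> None:
    """Persist parameters, config and training history in one .npz archive."""
    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    arrays["history_json"] = np.frombuffer(
        json.dumps(model.history).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path: str | Path) -> ConvAutoencoder:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["config_json"]).decode())
        cfg["channels"] = tuple(cfg["channels"])
        cfg["strides"] = tuple(cfg["strides"])
        model = ConvAutoencoder(AutoencoderConfig(**cfg))
        model.set_params([data[f"param_{i}"] for i in range(len(model.params))])
        model.history = json.loads(bytes(data["history_json"]).decode())
    return model
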