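"""Denoising autoencoder for windowed motion-artifact correction.

The corrector is a small 1-D convolutional autoencoder operating on
fixed-length standardized-OD windows (default 100 samples, about 15 s at
6.67 Hz).  The encoder is three Conv1d layers (kernel 3, stride 2, ReLU)
widening 1 -> 16 -> 32 -> 64; the decoder mirrors it with three transposed
convolutions so the output length equals the input length exactly.  Training
minimizes the mean squared error between the model output on a contaminated
window and the corresponding clean window, with Adam (default 500 epochs,
learning rate 5e-4).

Training pairs are built by per-channel z-scoring clean OD recordings,
cutting them into non-overlapping windows, and adding exactly one sampled
spike+step artifact per window; both window scales are retained so callers
can reverse the standardization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _nn
from .synth import MASpec, render_ma, sample_ma_params

__all__ = [
    "DAEConfig",
    "TrainingWindows",
    "build_training_windows",
    "DenoisingAutoencoder",
    "load_checkpoint",
]


@dataclass(frozen=True)
class DAEConfig:
    """Architecture and training hyperparameters of the windowed denoiser."""

    window_length: int = 100
    widths: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 3
    stride: int = 2
    epochs: int = 500
    learning_rate: float = 5e-4
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        min_len = self.stride ** len(self.widths)
        if self.window_length < min_len:
            raise ValueError(
                f"window_length {self.window_length} too short for "
                f"{len(self.widths)} stride-{self.stride} halvings (need >= {min_len})"
            )


@dataclass
class TrainingWindows:
    """Paired (noisy, clean) standardized windows with their rescale metadata.

    ``mean``/``std`` are the per-channel statistics used for standardization,
    recorded per window so the caller can reverse it; ``specs`` holds the
    artifact injected into each window.
    """

    noisy: np.ndarray               # (n_windows, L)
    clean: np.ndarray               # (n_windows, L)
    channel: np.ndarray             # (n_windows,) channel id within its recording
    recording: np.ndarray           # (n_windows,) recording index
    mean: np.ndarray                # (n_windows,)
    std: np.ndarray                 # (n_windows,)
    specs: list[MASpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.noisy)


def build_training_windows(
    od_recordings: list[np.ndarray],
    rng: np.random.Generator,
    window_length: int = 100,
    sampling_rate: float = 6.67,
    spike_shape: str = "gaussian",
) -> TrainingWindows:
    """Construct supervised denoising pairs from clean OD recordings.

    Each recording is a (time x channel) OD array of already-pruned channels.
    Every channel is z-scored with its own whole-recording mean and sample
    std, segmented into non-overlapping ``window_length``-sample windows, and
    each window is contaminated with exactly one randomly drawn spike+step
    artifact on the standardized scale.
    """
    noisy, clean, chans, recs, means, stds, specs = [], [], [], [], [], [], []
    for r, od in enumerate(od_recordings):
        od = np.asarray(od, dtype=float)
        if od.ndim != 2:
            raise ValueError("each recording must be (time x channel)")
        n_t, n_ch = od.shape
        n_win = n_t // window_length
        if n_win == 0:
            raise ValueError(
                f"recording {r} has {n_t} samples, shorter than one "
                f"{window_length}-sample window"
            )
        mu = od.mean(axis=0)
        sd = od.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ValueError(f"recording {r} has a zero-variance channel")
        z = (od - mu) / sd
        for ch in range(n_ch):
            for w in range(n_win):
                seg = z[w * window_length:(w + 1) * window_length, ch]
                spec = sample_ma_params(rng, window_length, sampling_rate)
                noisy.append(seg + render_ma(spec, sampling_rate, window_length, spike_shape))
                clean.append(seg)
                chans.append(ch)
                recs.append(r)
                means.append(mu[ch])
                stds.append(sd[ch])
                specs.append(spec)
    return TrainingWindows(
        noisy=np.array(noisy),
        clean=np.array(clean),
        channel=np.array(chans),
        recording=np.array(recs),
        mean=np.array(means),
        std=np.array(stds),
        specs=specs,
    )


class DenoisingAutoencoder(BaseEstimator, TransformerMixin):
    """Sliding-window motion-artifact corrector (sklearn-style estimator).

    ``fit(X, y)`` trains on rows of noisy windows ``X`` against clean targets
    ``y`` (both ``(n_windows, window_length)``); ``transform(X)`` denoises.
    Training is fully deterministic for a fixed ``seed`` and data order.

    Attributes (after fit)
    ----------------------
    net_ : the layer stack
    loss_history_ : dict with per-epoch ``train`` (and ``val``) MSE
    n_features_in_ : window length seen at fit
    """

    def __init__(
        self,
        window_length: int = 100,
        widths: tuple[int, ...] = (16, 32, 64),
        kernel_size: int = 3,
        stride: int = 2,
        epochs: int = 500,
        learning_rate: float = 5e-4,
        batch_size: int = 64,
        seed: int = 0,
    ):
        self.window_length = window_length
        self.widths = widths
        self.kernel_size = kernel_size
        self.stride = stride
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    # -- architecture -------------------------------------------------------

    def _config(self) -> DAEConfig:
        return DAEConfig(
            window_length=self.window_length,
            widths=tuple(self.widths),
            kernel_size=self.kernel_size,
            stride=self.stride,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=self.seed,
        )

    def _build(self, rng: np.random.Generator) -> _nn.Sequential:
        cfg = self._config()
        k, s = cfg.kernel_size, cfg.stride
        pad = k // 2
        layers: list = []
        lengths = [cfg.window_length]
        widths = (1,) + cfg.widths
        for c_in, c_out in zip(widths[:-1], widths[1:]):
            conv = _nn.Conv1d(c_in, c_out, k, s, pad, rng)
            layers += [conv, _nn.ReLU()]
            lengths.append(conv.out_length(lengths[-1]))
        rev = tuple(reversed(widths))
        for i, (c_in, c_out) in enumerate(zip(rev[:-1], rev[1:])):
            target = lengths[-(i + 2)]
            l_in = lengths[-(i + 1)]
            base = (l_in - 1) * s - 2 * pad + k
            out_pad = target - base
            if out_pad not in (0, 1):
                raise ValueError(
                    f"window length {cfg.window_length} incompatible with the "
                    f"stride plan (needed output padding {out_pad})"
                )
            layers.append(_nn.ConvTranspose1d(c_in, c_out, k, s, pad, out_pad, rng))
            if i < len(rev) - 2:  # last layer stays linear
                layers.append(_nn.ReLU())
        return _nn.Sequential(layers)

    @property
    def encoder_widths(self) -> tuple[int, ...]:
        return tuple(self.widths)

    def init_model(self) -> "DenoisingAutoencoder":
        """Build (seed-deterministic) initial weights without training."""
        rng = np.random.default_rng(self.seed)
        self.net_ = self._build(rng)
        self.loss_history_ = {"train": [], "val": []}
        self.n_features_in_ = self.window_length
        return self

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        validation_data: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> "DenoisingAutoencoder":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape != y.shape:
            raise ValueError("X and y must both be (n_windows, window_length)")
        if X.shape[1] != self.window_length:
            raise ValueError(
                f"windows have length {X.shape[1]}, model expects {self.window_length}"
            )
        if len(X) == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.seed)
        self.net_ = self._build(rng)
        self.loss_history_ = {"train": [], "val": []}
        self.n_features_in_ = self.window_length
        opt = _nn.Adam(self.net_.params, lr=self.learning_rate)
        n = len(X)
        xb_all = X[:, None, :]
        yb_all = y[:, None, :]
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start: start + self.batch_size]
                xb, yb = xb_all[idx], yb_all[idx]
                out = self.net_.forward(xb, train=True)
                diff = out - yb
                loss = float(np.mean(diff * diff))
                if not np.isfinite(loss):
                    raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
                self.net_.zero_grad()
                self.net_.backward(2.0 * diff / diff.size)
                opt.step()
                losses.append(loss)
            self.loss_history_["train"].append(float(np.mean(losses)))
            if validation_data is not None:
                xv, yv = validation_data
                pred = self._forward_eval(np.asarray(xv, dtype=float))
                self.loss_history_["val"].append(float(np.mean((pred - yv) ** 2)))
        return self

    # -- inference ----------------------------------------------------------

    def _forward_eval(self, X: np.ndarray, chunk: int = 1024) -> np.ndarray:
        outs = [
            self.net_.forward(X[i: i + chunk, None, :], train=False)[:, 0, :]
            for i in range(0, len(X), chunk)
        ]
        return np.concatenate(outs, axis=0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Denoise standardized windows; deterministic (no stochastic layers)."""
        if not hasattr(self, "net_"):
            raise RuntimeError("model is not fitted/initialized")
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[None, :]
        if X.shape[1] != self.window_length:
            raise ValueError(
                f"window length {X.shape[1]} does not match model ({self.window_length})"
            )
        out = self._forward_eval(X)
        return out[0] if squeeze else out

    predict = transform

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Self-describing checkpoint: config JSON + weight arrays."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        cfg = self._config().__dict__.copy()
        cfg["widths"] = list(cfg["widths"])
        arrays = {
            f"param_{i}": p for i, (p, _) in enumerate(self.net_.params)
        }
        np.savez(
            path,
            config=json.dumps(cfg),
            loss_train=np.array(self.loss_history_["train"]),
            loss_val=np.array(self.loss_history_["val"]),
            **arrays,
        )
        return path


def load_checkpoint(path: str | Path) -> DenoisingAutoencoder:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["config"]))
        cfg["widths"] = tuple(cfg["widths"])
        model = DenoisingAutoencoder(**cfg).init_model()
        for i, (p, _) in enumerate(model.net_.params):
            p[:] = data[f"param_{i}"]
        model.loss_history_ = {
            "train": list(data["loss_train"]),
            "val": list(data["loss_val"]),
        }
    return model
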