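"""The graph-transformer mortality forecaster (GT-A) and its reductions.

The model treats the m countries as graph nodes. Each training sample is a
sliding window of ``t`` consecutive years of the (standardized) m x d
log-mortality field. At every time step a graph-convolution layer mixes
information across countries through the propagation matrix P from the
adjacency bundle; the resulting per-country feature sequences feed a
transformer encoder (shared weights across countries) whose last hidden
state is projected linearly onto next year's d age-specific log rates.
Training minimises one-step-ahead MSE with Adam; multi-year forecasts roll
the one-step prediction forward recursively.

Three kinds share one implementation:

* ``"gta"`` — propagation matrix from the bundle, adaptive alpha/beta
  trained jointly with the network;
* ``"gt"``  — propagation matrix from the bundle, adaptive parameters
  frozen at the bundle's values;
* ``"tf"``  — propagation matrix fixed to the identity (no spatial mixing):
  the pure transformer baseline. GT-A with P = I and frozen parameters is
  bit-identical to this baseline under a shared seed.

Inputs are z-scored per (country, age) using train-year statistics only and
predictions are mapped back to the log-rate scale, so evaluation metrics are
on natural-log mortality throughout. Within each window the model works on
anchored values: the per-(country, age) window mean is subtracted from the
inputs and the network predicts next year's offset from that mean. This
makes the learned map translation-invariant along the trend, so recursive
forecasts stay inside the training distribution instead of saturating once
the predicted level leaves the range seen during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import MortalityPanel
from .graph import AdjacencyBundle, propagation_tensor
from .nn import (Adam, EncoderLayer, GCNLayer, Linear, Module, Tensor,
                 mse_loss, positional_encoding)

__all__ = [
    "WindowConfig", "GTAConfig", "ForecastResult", "GTA", "GTAResults",
    "build_windows", "gcn_forward",
]


@dataclass
class WindowConfig:
    """Sliding-window geometry: length t, step s, forecast horizon."""

    t: int = 10
    s: int = 1
    horizon: int = 16

    def validate(self) -> None:
        if self.t < 1 or self.s < 1 or self.horizon < 1:
            raise ValueError("t, s and horizon must all be >= 1")


@dataclass
class GTAConfig:
    """Architecture and optimisation settings.

    Defaults are sized for desk-scale CPU training: one GCN layer into a
    64-dimensional encoder with 4 heads and 2 layers. d_model must be
    divisible by the head count so d_k = d_v = d_model / h.
    """

    gcn_sizes: tuple[int, ...] = (64,)
    d_model: int = 64
    heads: int = 4
    encoder_layers: int = 2
    ff_width: int = 256
    dropout: float = 0.0
    lr: float = 1e-3
    epochs: int = 500
    batch_size: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.d_model % self.heads != 0:
            raise ValueError(
                f"d_model={self.d_model} must be divisible by heads={self.heads}"
            )
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class ForecastResult:
    """Predicted log-mortality with provenance."""

    log_rates: np.ndarray          # (m, horizon, d)
    countries: list[str]
    years: np.ndarray              # (horizon,)
    ages: np.ndarray               # (d,)
    model_tag: str
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        expect = (len(self.countries), len(self.years), len(self.ages))
        if self.log_rates.shape != expect:
            raise ValueError(f"log_rates {self.log_rates.shape} != {expect}")
        if not np.all(np.isfinite(self.log_rates)):
            raise ValueError("forecast contains non-finite values")

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, code in enumerate(self.countries):
            for j, year in enumerate(self.years):
                rows.append(pd.DataFrame({
                    "country": code, "year": int(year),
                    "age": self.ages, "log_rate": self.log_rates[i, j],
                }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_windows(train: np.ndarray | MortalityPanel,
                  window: WindowConfig) -> tuple[np.ndarray, np.ndarray]:
    """Slice (m, T, d) into one-step-ahead samples.

    Returns inputs of shape (N, t, m, d) and targets (N, m, d); windows
    start at years 0, s, 2s, ... and the target is the year immediately
    after the window.
    """
    window.validate()
    arr = train.log_rates if isinstance(train, MortalityPanel) else np.asarray(train)
    m, T, d = arr.shape
    if window.t >= T:
        raise ValueError(f"window length t={window.t} must be < {T} train years")
    starts = range(0, T - window.t, window.s)
    X = np.stack([arr[:, s0:s0 + window.t].transpose(1, 0, 2) for s0 in starts])
    y = np.stack([arr[:, s0 + window.t] for s0 in starts])
    return X, y


def gcn_forward(P: np.ndarray, X: np.ndarray, W: np.ndarray, b: np.ndarray,
                activation: str = "relu") -> np.ndarray:
    """Functional graph-convolution step sigma(P X W + b) (numpy arrays)."""
    P, X, W, b = (np.asarray(a, dtype=float) for a in (P, X, W, b))
    if P.shape[-1] != X.shape[-2] or X.shape[-1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: P{P.shape} X{X.shape} W{W.shape}"
        )
    h = P @ X @ W + b
    if activation == "relu":
        return np.maximum(h, 0.0)
    if activation == "identity":
        return h
    if activation == "tanh":
        return np.tanh(h)
    raise ValueError(f"unknown activation {activation!r}")


class _GraphTransformerCore(Module):
    """GCN stack + encoder + linear head; shared by gta / gt / tf kinds."""

    def __init__(self, d_ages: int, config: GTAConfig, window_t: int,
                 rng: np.random.Generator):
        sizes = (d_ages,) + tuple(config.gcn_sizes)
        self.gcn_layers = [
            GCNLayer(sizes[i], sizes[i + 1], rng) for i in range(len(sizes) - 1)
        ]
        self.project = (
            None if sizes[-1] == config.d_model
            else Linear(sizes[-1], config.d_model, rng)
        )
        self.pos_table = positional_encoding(window_t, config.d_model)
        self.encoder = [
            EncoderLayer(config.d_model, config.heads, config.ff_width, rng)
            for _ in range(config.encoder_layers)
        ]
        self.head = Linear(config.d_model, d_ages, rng)
        self.d_ages = d_ages

    def __call__(self, X: Tensor, P, drop_p: float = 0.0,
                 drop_rng: np.random.Generator | None = None) -> Tensor:
        # X: (B, t, m, d). Spatial mixing per time step, shared weights.
        B, t, m, _ = X.shape
        h = X
        for layer in self.gcn_layers:
            h = layer(P, h)
        # (B, t, m, g) -> per-country sequences (B*m, t, g)
        h = h.transpose(0, 2, 1, 3).reshape(B * m, t, h.shape[-1])
        if self.project is not None:
            h = self.project(h)
        h = h + Tensor(self.pos_table)
        for layer in self.encoder:
            h = layer(h, drop_p, drop_rng)
        out = self.head(h[:, -1, :])
        return out.reshape(B, m, self.d_ages)


@dataclass
class _Standardizer:
    mean: np.ndarray   # (m, d)
    sd: np.ndarray     # (m, d)

    @classmethod
    def fit(cls, arr: np.ndarray) -> "_Standardizer":
        mean = arr.mean(axis=1)
        sd = arr.std(axis=1)
        return cls(mean, np.maximum(sd, 1e-8))

    def transform(self, arr: np.ndarray) -> np.ndarray:
        return (arr - self.mean[:, None, :]) / self.sd[:, None, :]

    def inverse(self, arr: np.ndarray) -> np.ndarray:
        return arr * self.sd[:, None, :] + self.mean[:, None, :]


class GTA:
    """Graph-transformer mortality model over a training panel.

    Parameters
    ----------
    train_panel : MortalityPanel
        Training years only; statistics and windows never see test years.
    bundle : AdjacencyBundle, optional
        Required for kinds ``"gta"`` and ``"gt"``; ignored for ``"tf"``.
    kind : {"gta", "gt", "tf"}
        Adaptive-trainable graph model, frozen graph model, or the pure
        transformer reduction with identity propagation.
    """

    def __init__(self, train_panel: MortalityPanel,
                 bundle: AdjacencyBundle | None = None,
                 window: WindowConfig | None = None,
                 config: GTAConfig | None = None,
                 kind: str = "gta"):
        if kind not in ("gta", "gt", "tf"):
            raise ValueError(f"unknown model kind {kind!r}")
        if kind in ("gta", "gt") and bundle is None:
            raise ValueError(f"kind {kind!r} requires an adjacency bundle")
        if kind == "gta" and (bundle.labels is None or bundle.params is None):
            raise ValueError(
                "trainable adaptive parameters need a bundle carrying cluster "
                "labels and AdaptiveParams"
            )
        self.panel = train_panel
        self.bundle = bundle
        self.window = window or WindowConfig()
        self.config = config or GTAConfig()
        self.kind = kind
        self.window.validate()
        self.config.validate()

    def fit(self) -> "GTAResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        init_seed, shuffle_seed, drop_seed = ss.spawn(3)
        rng = np.random.default_rng(init_seed)
        drop_rng = (np.random.default_rng(drop_seed)
                    if cfg.dropout > 0 else None)

        scaler = _Standardizer.fit(self.panel.log_rates)
        std = scaler.transform(self.panel.log_rates)
        X, y = build_windows(std, self.window)
        # anchor on the window mean: the net learns the offset of the next
        # year from the window's own level
        anchor = X.mean(axis=1)              # (N, m, d)
        X = X - anchor[:, None]
        y = y - anchor

        core = _GraphTransformerCore(self.panel.d, cfg, self.window.t, rng)
        params = core.parameters()

        alpha_raw = beta_raw = None
        if self.kind == "gta":
            alpha_raw = Tensor(self.bundle.params.alpha_raw.copy(),
                               requires_grad=True)
            beta_raw = Tensor(np.float64(self.bundle.params.beta_raw),
                              requires_grad=True)
            params = params + [alpha_raw, beta_raw]
        if self.kind == "tf":
            P_const = np.eye(self.panel.m)
        elif self.kind == "gt" or self.kind == "gta":
            P_const = self.bundle.propagation

        opt = Adam(params, lr=cfg.lr)
        shuffler = np.random.default_rng(shuffle_seed)
        n = len(X)
        history: list[float] = []
        for epoch in range(cfg.epochs):
            order = shuffler.permutation(n)
            epoch_losses = []
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo:lo + cfg.batch_size]
                if self.kind == "gta":
                    P = propagation_tensor(self.bundle, alpha_raw, beta_raw)
                else:
                    P = Tensor(P_const)
                pred = core(Tensor(X[idx]), P, cfg.dropout, drop_rng)
                loss = mse_loss(pred, y[idx])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} "
                        f"(last finite epoch loss: {history[-1] if history else None})"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
            history.append(float(np.mean(epoch_losses)))

        return GTAResults(self, core, scaler, history, alpha_raw, beta_raw)


class GTAResults:
    """Fitted model: forecasts, training diagnostics, summary."""

    def __init__(self, model: GTA, core: _GraphTransformerCore,
                 scaler: _Standardizer, loss_history: list[float],
                 alpha_raw: Tensor | None, beta_raw: Tensor | None):
        self.model = model
        self.core = core
        self.scaler = scaler
        self.loss_history = loss_history
        self._alpha_raw = alpha_raw
        self._beta_raw = beta_raw

    # ------------------------------------------------------------------
    def _propagation(self) -> np.ndarray:
        if self.model.kind == "tf":
            return np.eye(self.model.panel.m)
        if self.model.kind == "gta":
            return propagation_tensor(self.model.bundle, self._alpha_raw,
                                      self._beta_raw).data
        return self.model.bundle.propagation

    def adaptive_values(self) -> tuple[np.ndarray, float] | None:
        """Fitted (alpha, beta) on the constrained scale, if trainable."""
        if self._alpha_raw is None:
            return None
        alpha = 1.0 / (1.0 + np.exp(-self._alpha_raw.data))
        beta = float(1.0 + np.logaddexp(0.0, self._beta_raw.data))
        return alpha, beta

    def predict_next(self, context_log: np.ndarray) -> np.ndarray:
        """One-step prediction from an (m, t, d) log-rate context."""
        t = self.model.window.t
        if context_log.shape[1] < t:
            raise ValueError(f"context must supply at least t={t} years")
        std = self.scaler.transform(context_log[:, -t:, :])
        X = std.transpose(1, 0, 2)[None]           # (1, t, m, d)
        anchor = X.mean(axis=1)                    # (1, m, d)
        P = Tensor(self._propagation())
        pred = self.core(Tensor(X - anchor[:, None]), P).data[0] + anchor[0]
        return self.scaler.inverse(pred[:, None, :])[:, 0, :]

    def forecast(self, horizon: int | None = None) -> ForecastResult:
        """Recursive multi-year forecast from the end of the train panel."""
        horizon = self.model.window.horizon if horizon is None else int(horizon)
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        panel = self.model.panel
        context = panel.log_rates.copy()
        preds = []
        for _ in range(horizon):
            nxt = self.predict_next(context)
            preds.append(nxt)
            context = np.concatenate([context, nxt[:, None, :]], axis=1)
        log_rates = np.stack(preds, axis=1)        # (m, horizon, d)
        years = np.arange(panel.years[-1] + 1, panel.years[-1] + 1 + horizon)
        return ForecastResult(log_rates, panel.countries, years, panel.ages,
                              self.model.kind, self.loss_history)

    def save(self, path) -> None:
        """Checkpoint: one ``.npz`` of arrays plus a JSON config sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        arrays = {f"param_{i}": p.data for i, p in
                  enumerate(self.core.parameters())}
        arrays["scaler_mean"] = self.scaler.mean
        arrays["scaler_sd"] = self.scaler.sd
        if self._alpha_raw is not None:
            arrays["alpha_raw"] = self._alpha_raw.data
            arrays["beta_raw"] = np.atleast_1d(self._beta_raw.data)
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "kind": self.model.kind,
            "config": self.model.config.__dict__,
            "window": self.model.window.__dict__,
            "countries": self.model.panel.countries,
            "train_years": [int(self.model.panel.years[0]),
                            int(self.model.panel.years[-1])],
            "loss_history": self.loss_history,
        }
        sidecar["config"]["gcn_sizes"] = list(sidecar["config"]["gcn_sizes"])
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path, train_panel: MortalityPanel,
             bundle: AdjacencyBundle | None = None) -> "GTAResults":
        """Restore a checkpoint for forecasting on the same train panel."""
        import json
        from pathlib import Path

        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        config = GTAConfig(**{**sidecar["config"],
                              "gcn_sizes": tuple(sidecar["config"]["gcn_sizes"])})
        window = WindowConfig(**sidecar["window"])
        model = GTA(train_panel, bundle, window, config, kind=sidecar["kind"])
        arrays = np.load(path.with_suffix(".npz"))
        rng = np.random.default_rng(0)      # shapes only; data overwritten
        core = _GraphTransformerCore(train_panel.d, config, window.t, rng)
        for i, p in enumerate(core.parameters()):
            p.data = arrays[f"param_{i}"].copy()
        scaler = _Standardizer(arrays["scaler_mean"].copy(),
                               arrays["scaler_sd"].copy())
        alpha_raw = beta_raw = None
        if "alpha_raw" in arrays:
            alpha_raw = Tensor(arrays["alpha_raw"].copy(), requires_grad=True)
            beta_raw = Tensor(np.float64(arrays["beta_raw"][0]),
                              requires_grad=True)
        return cls(model, core, scaler, list(sidecar["loss_history"]),
                   alpha_raw, beta_raw)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            f"Graph-transformer mortality model [{self.model.kind}]",
            "=" * 48,
            f"countries (m):        {self.model.panel.m}",
            f"train years:          {self.model.panel.years[0]}-"
            f"{self.model.panel.years[-1]} (T={self.model.panel.T_L})",
            f"ages (d):             {self.model.panel.d}",
            f"window t / step s:    {self.model.window.t} / {self.model.window.s}",
            f"d_model / heads:      {cfg.d_model} / {cfg.heads}",
            f"encoder layers:       {cfg.encoder_layers}",
            f"epochs / lr / batch:  {cfg.epochs} / {cfg.lr} / {cfg.batch_size}",
        ]
        if self.loss_history:
            lines.append(f"final train MSE:      {self.loss_history[-1]:.6f} "
                         f"(initial {self.loss_history[0]:.6f})")
        adaptive = self.adaptive_values()
        if adaptive is not None:
            alpha, beta = adaptive
            alpha_txt = ", ".join(f"{a:.3f}" for a in alpha)
            lines.append(f"adaptive alpha:       [{alpha_txt}]")
            lines.append(f"adaptive beta:        {beta:.3f}")
        return "\n".join(lines)
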