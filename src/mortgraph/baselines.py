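"""Benchmark forecasters: Lee-Carter, persistence, and sequence networks.

The Lee-Carter model decomposes the log central death rate of one country,

    log m_{x,t} = a_x + b_x k_t,

with a_x the time-mean age profile and (b_x, k_t) the leading singular pair
of the centered surface, normalised so that sum(b_x) = 1 and sum(k_t) = 0.
The period factor is forecast as a random walk with drift: the point
forecast is k_{T+h} = k_T + h * theta with theta the mean first difference
of k_t.

The neural baselines (LSTM, plain RNN, causal 1-D CNN over time, and the
pure transformer) share the GT-A training protocol exactly — same sliding
windows, per-(country, age) train-only standardization, Adam on one-step
MSE, recursive multi-year forecasting — with only the spatio-temporal core
swapped. They are trained jointly over countries with shared weights on the
age-vector sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import MortalityPanel
from .gta import (ForecastResult, GTA, GTAConfig, WindowConfig, build_windows,
                  _Standardizer)
from .nn import (Adam, Conv1dCore, Linear, LSTMCore, Module, RNNCore, Tensor,
                 mse_loss)

__all__ = [
    "LeeCarter", "LeeCarterResults", "persistence_forecast", "train_baseline",
    "BASELINE_KINDS",
]

BASELINE_KINDS = ("lstm", "rnn", "cnn1d", "tf")


# ----------------------------------------------------------------------
# Lee-Carter
# ----------------------------------------------------------------------

class LeeCarter:
    """Lee-Carter model for one country's T x d log-rate surface."""

    def __init__(self, log_rates: np.ndarray):
        arr = np.asarray(log_rates, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 3:
            raise ValueError("need a T x d log-rate matrix with T >= 3")
        if not np.all(np.isfinite(arr)):
            raise ValueError("log rates must be finite")
        self.log_rates = arr

    @classmethod
    def from_panel(cls, panel: MortalityPanel, country: str) -> "LeeCarter":
        return cls(panel.country_matrix(country))

    def fit(self) -> "LeeCarterResults":
        Y = self.log_rates
        a_x = Y.mean(axis=0)
        C = Y - a_x
        if np.allclose(C, 0.0, atol=1e-14):
            raise ValueError("degenerate constant surface: no period variation")
        u, s, vt = np.linalg.svd(C, full_matrices=False)
        k_t = u[:, 0] * s[0]
        b_x = vt[0]
        scale = b_x.sum()
        if scale == 0:
            raise ValueError("leading age loading sums to zero; cannot normalise")
        b_x = b_x / scale          # sum(b) = 1
        k_t = k_t * scale
        k_shift = k_t.mean()
        k_t = k_t - k_shift        # sum(k) = 0
        a_x = a_x + b_x * k_shift
        dk = np.diff(k_t)
        drift = float(dk.mean())
        T = len(k_t)
        drift_se = float(dk.std(ddof=1) / np.sqrt(len(dk))) if len(dk) > 1 else 0.0
        resid = C - np.outer(k_t, b_x)
        resid_sd = float(resid.std(ddof=0))
        return LeeCarterResults(a_x, b_x, k_t, drift, drift_se, resid_sd, self)


@dataclass
class LeeCarterResults:
    """Fitted Lee-Carter parameters and the drift forecaster."""

    a_x: np.ndarray
    b_x: np.ndarray
    k_t: np.ndarray
    drift: float
    drift_se: float
    resid_sd: float
    model: LeeCarter | None = None

    def __post_init__(self):
        if abs(self.b_x.sum() - 1.0) > 1e-9:
            raise ValueError("b_x must sum to 1")
        if abs(self.k_t.sum()) > 1e-9:
            raise ValueError("k_t must sum to 0")

    def forecast(self, horizon: int) -> np.ndarray:
        """Point forecast of log rates: a_x + b_x (k_T + h * drift)."""
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        h = np.arange(1, horizon + 1)
        k_fut = self.k_t[-1] + h * self.drift
        return self.a_x[None, :] + np.outer(k_fut, self.b_x)

    def fitted(self) -> np.ndarray:
        return self.a_x[None, :] + np.outer(self.k_t, self.b_x)

    def summary(self) -> str:
        return "\n".join([
            "Lee-Carter fit",
            "=" * 32,
            f"ages:            {len(self.a_x)}",
            f"train years:     {len(self.k_t)}",
            f"drift theta:     {self.drift:.5f} (se {self.drift_se:.5f})",
            f"residual sd:     {self.resid_sd:.5f}",
            f"k_t range:       [{self.k_t.min():.3f}, {self.k_t.max():.3f}]",
        ])


def lc_forecast_panel(panel: MortalityPanel, horizon: int) -> ForecastResult:
    """Fit Lee-Carter independently per country and forecast jointly."""
    preds = np.stack([
        LeeCarter(panel.log_rates[i]).fit().forecast(horizon)
        for i in range(panel.m)
    ])
    years = np.arange(panel.years[-1] + 1, panel.years[-1] + 1 + horizon)
    return ForecastResult(preds, panel.countries, years, panel.ages, "lc")


# ----------------------------------------------------------------------
# Persistence
# ----------------------------------------------------------------------

def persistence_forecast(panel: MortalityPanel, horizon: int) -> ForecastResult:
    """Naive baseline: repeat the last observed year over the horizon."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    last = panel.log_rates[:, -1, :]
    preds = np.repeat(last[:, None, :], horizon, axis=1)
    years = np.arange(panel.years[-1] + 1, panel.years[-1] + 1 + horizon)
    return ForecastResult(preds, panel.countries, years, panel.ages,
                          "persistence")


# ----------------------------------------------------------------------
# Sequence-network baselines
# ----------------------------------------------------------------------

class _SequenceNet(Module):
    """Recurrent/convolutional core over per-country age-vector sequences."""

    def __init__(self, kind: str, d_ages: int, hidden: int,
                 rng: np.random.Generator):
        cores = {"lstm": LSTMCore, "rnn": RNNCore, "cnn1d": Conv1dCore}
        self.core = cores[kind](d_ages, hidden, rng)
        self.head = Linear(hidden, d_ages, rng)
        self.d_ages = d_ages

    def __call__(self, X: Tensor) -> Tensor:
        # X: (B, t, m, d) -> (B*m, t, d) -> last hidden -> (B, m, d)
        B, t, m, d = X.shape
        seq = X.transpose(0, 2, 1, 3).reshape(B * m, t, d)
        out = self.head(self.core(seq))
        return out.reshape(B, m, d)


class _SequenceResults:
    """Fitted sequence baseline with the shared recursive forecaster."""

    def __init__(self, panel: MortalityPanel, window: WindowConfig, kind: str,
                 net: _SequenceNet, scaler: _Standardizer,
                 loss_history: list[float]):
        self.panel, self.window, self.kind = panel, window, kind
        self.net, self.scaler, self.loss_history = net, scaler, loss_history

    def predict_next(self, context_log: np.ndarray) -> np.ndarray:
        t = self.window.t
        std = self.scaler.transform(context_log[:, -t:, :])
        X = std.transpose(1, 0, 2)[None]
        anchor = X.mean(axis=1)
        pred = self.net(Tensor(X - anchor[:, None])).data[0] + anchor[0]
        return self.scaler.inverse(pred[:, None, :])[:, 0, :]

    def forecast(self, horizon: int | None = None) -> ForecastResult:
        horizon = self.window.horizon if horizon is None else int(horizon)
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        context = self.panel.log_rates.copy()
        preds = []
        for _ in range(horizon):
            nxt = self.predict_next(context)
            preds.append(nxt)
            context = np.concatenate([context, nxt[:, None, :]], axis=1)
        years = np.arange(self.panel.years[-1] + 1,
                          self.panel.years[-1] + 1 + horizon)
        return ForecastResult(np.stack(preds, axis=1), self.panel.countries,
                              years, self.panel.ages, self.kind,
                              self.loss_history)


def train_baseline(kind: str, train_panel: MortalityPanel,
                   window: WindowConfig | None = None,
                   config: GTAConfig | None = None):
    """Train one benchmark network with the GT-A protocol.

    ``kind="tf"`` routes through the shared graph-transformer core with the
    propagation matrix fixed to the identity; the recurrent kinds use their
    own cores but identical windowing, loss, optimizer and epochs.
    """
    window = window or WindowConfig()
    config = config or GTAConfig()
    if kind == "tf":
        return GTA(train_panel, bundle=None, window=window, config=config,
                   kind="tf").fit()
    if kind not in ("lstm", "rnn", "cnn1d"):
        raise ValueError(f"unknown baseline kind {kind!r}")
    window.validate()
    config.validate()

    ss = np.random.SeedSequence(config.seed)
    init_seed, shuffle_seed = ss.spawn(2)
    rng = np.random.default_rng(init_seed)

    scaler = _Standardizer.fit(train_panel.log_rates)
    std = scaler.transform(train_panel.log_rates)
    X, y = build_windows(std, window)
    anchor = X.mean(axis=1)
    X = X - anchor[:, None]
    y = y - anchor

    net = _SequenceNet(kind, train_panel.d, config.d_model, rng)
    opt = Adam(net.parameters(), lr=config.lr)
    shuffler = np.random.default_rng(shuffle_seed)
    n = len(X)
    history: list[float] = []
    for epoch in range(config.epochs):
        order = shuffler.permutation(n)
        epoch_losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            loss = mse_loss(net(Tensor(X[idx])), y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))
    return _SequenceResults(train_panel, window, kind, net, scaler, history)
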