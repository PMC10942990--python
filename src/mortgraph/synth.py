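"""Seeded synthetic multi-country log-mortality panels with known structure.

Each country's surface follows a Lee-Carter factor decomposition

    log m_{x,t} = a_x + b_x k_t + eps,   eps ~ N(0, noise_sd^2),

where the period factor k_t is a random walk whose drift is shared within a
cluster (plus a small country-level perturbation), the age profile a_x is a
Siler-type curve (infant hump, mid-life plateau, Gompertz old-age rise) and
the sensitivities b_x are positive and sum to one. Capitals are drawn around
per-cluster geographic centres so geography correlates with cluster
membership. Every draw is reproducible from the seed.

The generator exists so that each pipeline stage — clustering, adjacency
construction, network training, Lee-Carter fitting — can be tested against a
known ground truth without the registration-gated HMD download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import CountryRegistry, MortalityPanel, MortalitySurface, build_panel

__all__ = ["SynthConfig", "SynthTruth", "simulate_panel", "panel_to_surfaces"]


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Defaults mirror the real panel: 16 countries, 67 years, 101 ages, three
    clusters. Cluster drifts are expressed on the period-factor scale; with
    b_x ~ 1/d ~ 0.01 a drift of -1.5 per year means roughly 1.5% annual
    decline in death rates. The default drifts straddle zero because
    age-wise standardization makes trend curves scale-free: clusters are
    distinguishable by the shape (sign/curvature) of their trend, not by
    its magnitude, so a recoverable cluster structure needs sign-separated
    drifts.
    """

    m: int = 16
    n_clusters: int = 3
    n_years: int = 67
    n_ages: int = 101
    first_year: int = 1950
    cluster_drifts: tuple[float, ...] = (-1.5, 0.0, 1.5)
    drift_jitter: float = 0.05        # country-level drift perturbation (sd)
    factor_corr: float = 0.9          # within-cluster correlation of k_t walks
    walk_sd: float = 0.6              # innovation sd of the period factor
    noise_sd: float = 0.05            # observation noise on the log scale
    geo_centers: tuple[tuple[float, float], ...] = (
        (61.0, 20.0), (47.0, 6.0), (49.0, 19.0),
    )
    geo_jitter: float = 2.5           # degrees, sd of capital placement
    missing_prob: float = 0.0         # optional missingness injector

    def validate(self) -> None:
        if not (self.m >= self.n_clusters >= 1):
            raise ValueError("need m >= n_clusters >= 1")
        if self.n_years < 2 or self.n_ages < 2 or self.m < 2:
            raise ValueError("all dimensions must be >= 2")
        if self.noise_sd < 0 or self.walk_sd < 0 or self.drift_jitter < 0:
            raise ValueError("noise/walk/jitter standard deviations must be >= 0")
        if len(self.cluster_drifts) != self.n_clusters:
            raise ValueError("one drift per cluster required")
        if len(self.geo_centers) < self.n_clusters:
            raise ValueError("one geographic centre per cluster required")
        if not (0.0 <= self.factor_corr <= 1.0):
            raise ValueError("factor_corr must lie in [0, 1]")
        if not (0.0 <= self.missing_prob < 1.0):
            raise ValueError("missing_prob must lie in [0, 1)")


@dataclass
class SynthTruth:
    """Ground truth behind a simulated panel, mirroring a Lee-Carter fit."""

    labels: np.ndarray                    # (m,) cluster label per country
    a_x: np.ndarray                       # (m, d) age profiles
    b_x: np.ndarray                       # (m, d) sensitivities, rows sum to 1
    k_t: np.ndarray                       # (m, T) period factors, rows sum to 0
    cluster_drifts: np.ndarray            # (n_clusters,)
    country_drifts: np.ndarray            # (m,) realised per-country drifts
    registry: CountryRegistry = field(default_factory=CountryRegistry)


def _siler_age_profile(ages: np.ndarray) -> np.ndarray:
    """Baseline log death rate by age: infant hump + plateau + Gompertz."""
    hazard = 0.05 * np.exp(-1.1 * ages) + 6e-4 + 4e-5 * np.exp(0.088 * ages)
    return np.log(hazard)


def simulate_panel(config: SynthConfig, seed: int) -> tuple[MortalityPanel, SynthTruth]:
    """Draw one panel and its ground truth, reproducibly from ``seed``."""
    config.validate()
    rng = np.random.default_rng(seed)
    m, T, d = config.m, config.n_years, config.n_ages
    n = config.n_clusters
    ages = np.arange(d, dtype=float)
    years = np.arange(config.first_year, config.first_year + T)

    labels = np.array([i % n for i in range(m)])

    # age profiles: shared Siler curve + small smooth country deviation
    base_a = _siler_age_profile(ages)
    a_x = np.empty((m, d))
    for i in range(m):
        phase = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.uniform(0.0, 0.08, size=2)
        a_x[i] = base_a + (
            amp[0] * np.sin(2 * np.pi * ages / d + phase[0])
            + amp[1] * np.cos(4 * np.pi * ages / d + phase[1])
        )

    # sensitivities: heavier at young ages, positive, normalised to sum 1
    b_x = np.empty((m, d))
    for i in range(m):
        raw = 0.5 + np.exp(-ages / 30.0) + rng.uniform(0, 0.1, size=d)
        b_x[i] = raw / raw.sum()

    # period factors: cluster-common walk mixed with a country-own walk
    rho = config.factor_corr
    cluster_walk = np.cumsum(rng.normal(0, config.walk_sd, size=(n, T)), axis=1)
    country_drifts = np.empty(m)
    k_t = np.empty((m, T))
    tgrid = np.arange(T, dtype=float)
    for i in range(m):
        c = labels[i]
        own_walk = np.cumsum(rng.normal(0, config.walk_sd, size=T))
        drift = config.cluster_drifts[c] + rng.normal(0, config.drift_jitter)
        walk = np.sqrt(rho) * cluster_walk[c] + np.sqrt(1 - rho) * own_walk
        k = drift * tgrid + (walk - walk.mean())
        k_mean = k.mean()
        k_t[i] = k - k_mean            # rows sum to 0
        a_x[i] = a_x[i] + b_x[i] * k_mean
        country_drifts[i] = drift

    log_rates = (
        a_x[:, None, :]
        + b_x[:, None, :] * k_t[:, :, None]
        + rng.normal(0, config.noise_sd, size=(m, T, d))
    )

    # capitals around the cluster centres, correlated with membership
    registry = CountryRegistry()
    codes = [f"C{i:02d}" for i in range(m)]
    for i, code in enumerate(codes):
        lat0, lon0 = config.geo_centers[labels[i]]
        lat = float(np.clip(lat0 + rng.normal(0, config.geo_jitter), -89.0, 89.0))
        lon = float(np.clip(lon0 + rng.normal(0, config.geo_jitter), -179.0, 179.0))
        registry.add(code, f"Synthetic country {i}", lat, lon)

    truth = SynthTruth(labels, a_x, b_x, k_t, np.asarray(config.cluster_drifts),
                       country_drifts, registry)

    if config.missing_prob > 0:
        # re-route through the Mx dialect surfaces so imputation is exercised
        rates = np.exp(log_rates)
        drop = rng.random(size=rates.shape) < config.missing_prob
        # never drop a cell in every country (imputation would be impossible)
        all_dropped = drop.all(axis=0)
        if all_dropped.any():
            keep_country = rng.integers(0, m, size=int(all_dropped.sum()))
            yy, aa = np.nonzero(all_dropped)
            drop[keep_country, yy, aa] = False
        rates = np.where(drop, np.nan, rates)
        surfaces = [
            MortalitySurface(codes[i], years, np.arange(d), rates[i])
            for i in range(m)
        ]
        panel = build_panel(surfaces, (years[0], years[-1]), (0, d - 1))
    else:
        panel = MortalityPanel(
            codes, years, np.arange(d), log_rates,
            np.zeros_like(log_rates, dtype=bool),
        )
    return panel, truth


def panel_to_surfaces(panel: MortalityPanel,
                      sex_channel: str = "total") -> list[MortalitySurface]:
    """Convert a panel back to raw-rate surfaces (e.g. to write Mx files)."""
    return [
        MortalitySurface(code, panel.years, panel.ages,
                         np.exp(panel.log_rates[i]), sex_channel)
        for i, code in enumerate(panel.countries)
    ]
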