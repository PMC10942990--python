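"""Config-driven orchestration: data -> cluster -> graph -> train -> evaluate.

Each stage writes its artifacts into the run directory and can be re-run or
resumed from cache; a single global seed fans out deterministically into
per-stage seeds via ``numpy.random.SeedSequence([global_seed, stage_id])``.
Stages that consume the panel only ever see the training years until the
evaluation stage compares forecasts with the held-out test years.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .baselines import lc_forecast_panel, persistence_forecast, train_baseline
from .cluster import dtw_matrix, first_pc, kmeans_shapes, select_k, standardize_ages
from .data_io import (MortalityPanel, build_panel, load_default_registry,
                      read_hmd_mx, split_train_test)
from .graph import (AdaptiveParams, adaptive_matrix, compose_adjacency,
                    geo_distance_matrix)
from .gta import GTA, GTAConfig, WindowConfig
from .metrics import metrics_all, metrics_country, prediction_intervals
from .synth import SynthConfig, simulate_panel

__all__ = ["RunConfig", "run_pipeline", "calibration_residuals"]

log = logging.getLogger("mortgraph.pipeline")

_STAGE_IDS = {"data": 0, "cluster": 1, "graph": 2, "train": 3, "evaluate": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Everything one run needs; every field has a sensible default."""

    source: str = "synthetic"              # "synthetic" | "hmd"
    hmd_dir: str | None = None
    sex_channel: str = "total"
    year_range: tuple[int, int] = (1950, 2016)
    age_range: tuple[int, int] = (0, 100)
    last_train_year: int = 2000
    synth: SynthConfig = field(default_factory=SynthConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    model_config: GTAConfig = field(default_factory=GTAConfig)
    k_range: tuple[int, int] = (2, 8)
    cluster_n_init: int = 4
    adaptive_mode: str = "trainable"       # "trainable" | "frozen"
    alpha_init: float = 0.5
    beta_init: float = 1.5
    models: tuple[str, ...] = ("gta",)
    outdir: str = "mortgraph_run"
    seed: int = 0
    resume: bool = False        # reuse cached cluster model if present

    def validate(self) -> None:
        if self.source not in ("synthetic", "hmd"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "hmd" and not self.hmd_dir:
            raise ValueError("hmd source requires hmd_dir")
        if self.adaptive_mode not in ("trainable", "frozen"):
            raise ValueError(f"unknown adaptive mode {self.adaptive_mode!r}")
        for kind in self.models:
            if kind not in ("gta", "gt", "tf", "lstm", "rnn", "cnn1d", "lc"):
                raise ValueError(f"unknown model kind {kind!r}")
        self.window.validate()
        self.model_config.validate()
        self.synth.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, klass in (("synth", SynthConfig), ("window", WindowConfig),
                           ("model_config", GTAConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        for key in ("year_range", "age_range", "k_range", "models"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        if "synth" in kwargs and isinstance(kwargs["synth"], SynthConfig):
            pass
        cfg = cls(**kwargs)
        return cfg


# ----------------------------------------------------------------------
# Stages
# ----------------------------------------------------------------------

def _stage_data(cfg: RunConfig, outdir: Path):
    if cfg.source == "hmd":
        hmd_dir = Path(cfg.hmd_dir)
        if not hmd_dir.is_dir():
            raise FileNotFoundError(f"HMD directory not found: {hmd_dir}")
        files = sorted(hmd_dir.glob("*.txt"))
        if not files:
            raise FileNotFoundError(f"no Mx_1x1 .txt files in {hmd_dir}")
        surfaces = [read_hmd_mx(f, cfg.sex_channel) for f in files]
        panel = build_panel(surfaces, cfg.year_range, cfg.age_range)
        registry = load_default_registry()
    else:
        panel, truth = simulate_panel(cfg.synth, stage_seed(cfg.seed, "data"))
        registry = truth.registry
        np.savetxt(outdir / "truth_labels.txt", truth.labels, fmt="%d")
    train, test = split_train_test(panel, cfg.last_train_year)
    summary = {
        "countries": panel.countries, "m": panel.m, "T_L": panel.T_L,
        "d": panel.d, "train_years": [int(train.years[0]), int(train.years[-1])],
        "test_years": [int(test.years[0]), int(test.years[-1])],
        "imputed_cells": int(panel.imputed_mask.sum()),
    }
    (outdir / "panel_summary.json").write_text(json.dumps(summary, indent=2))
    return panel, train, test, registry


def _stage_cluster(cfg: RunConfig, train: MortalityPanel, outdir: Path):
    seed = stage_seed(cfg.seed, "cluster")
    pcs = [first_pc(standardize_ages(train.log_rates[i])) for i in range(train.m)]
    series = [pc.pc1 for pc in pcs]
    cached = outdir / "cluster_model.json"
    if cfg.resume and cached.exists():
        from .cluster import ClusterModel
        log.info("cluster stage: reusing cached %s", cached)
        return ClusterModel.from_json(cached.read_text()), series
    k_lo, k_hi = cfg.k_range
    k_star, sils, sses = select_k(series, range(k_lo, k_hi + 1),
                                  n_init=cfg.cluster_n_init, seed=seed)
    model = kmeans_shapes(series, k_star, n_init=cfg.cluster_n_init, seed=seed)
    report = {
        "k_star": k_star,
        "silhouette_by_k": {str(k): v for k, v in sils.items()},
        "sse_by_k": {str(k): v for k, v in sses.items()},
        "first_pc_proportion": [float(pc.proportions[0]) for pc in pcs],
    }
    (outdir / "cluster_report.json").write_text(json.dumps(report, indent=2))
    (outdir / "cluster_model.json").write_text(model.to_json())
    return model, series


def _stage_graph(cfg: RunConfig, train, registry, model, series, outdir: Path):
    D_dtw = dtw_matrix(series)
    D_geo = geo_distance_matrix(registry, train.countries)
    params = AdaptiveParams.init(model.k, cfg.alpha_init, cfg.beta_init,
                                 trainable=cfg.adaptive_mode == "trainable")
    a_ada = adaptive_matrix(model.labels, params)
    bundle = compose_adjacency(D_dtw, D_geo, a_ada, countries=train.countries,
                               params=params, labels=model.labels)
    bundle.export(outdir / "adjacency")
    return bundle


def _stage_train(cfg: RunConfig, train, bundle, outdir: Path):
    seed = stage_seed(cfg.seed, "train")
    results = {}
    for kind in cfg.models:
        t0 = time.time()
        model_cfg = GTAConfig(**{**cfg.model_config.__dict__, "seed": seed})
        if kind == "lc":
            results[kind] = None       # fitted lazily at forecast time
        elif kind in ("gta", "gt", "tf"):
            use_kind = kind
            if kind == "gta" and cfg.adaptive_mode == "frozen":
                use_kind = "gt"
            model = GTA(train, bundle=None if kind == "tf" else bundle,
                        window=cfg.window, config=model_cfg, kind=use_kind)
            results[kind] = model.fit()
            results[kind].save(outdir / f"checkpoint_{kind}")
        else:
            results[kind] = train_baseline(kind, train, cfg.window, model_cfg)
        log.info("trained %s in %.1fs", kind, time.time() - t0)
    return results


def _stage_evaluate(cfg: RunConfig, train, test, fits, outdir: Path):
    horizon = test.T_L
    report = {}
    for kind, fit in fits.items():
        if kind == "lc":
            fc = lc_forecast_panel(train, horizon)
        else:
            fc = fit.forecast(horizon)
        fc.to_csv(outdir / f"forecast_{kind}.csv")
        rep = metrics_all(fc.log_rates, test.log_rates)
        per_country = {
            code: metrics_country(fc.log_rates[i], test.log_rates[i])
            for i, code in enumerate(test.countries)
        }
        report[kind] = {"global": rep.as_dict(), "per_country": per_country}
    persist = persistence_forecast(train, horizon)
    report["persistence"] = {
        "global": metrics_all(persist.log_rates, test.log_rates).as_dict()
    }
    (outdir / "metric_report.json").write_text(json.dumps(report, indent=2))
    return report


def calibration_residuals(train: MortalityPanel, forecaster,
                          n_calib_years: int = 10) -> np.ndarray:
    """Rolling-origin residuals inside the train window.

    ``forecaster(panel, horizon) -> ForecastResult`` is refit on the train
    years minus the last ``n_calib_years`` and evaluated on those held-out
    years; the returned array has shape (m, n_calib_years, d) and feeds
    :func:`mortgraph.metrics.prediction_intervals`.
    """
    if not (0 < n_calib_years < train.T_L):
        raise ValueError("calibration window must lie inside the train years")
    sub, calib = split_train_test(
        train, int(train.years[-1 - n_calib_years])
    )
    fc = forecaster(sub, calib.T_L)
    return fc.log_rates - calib.log_rates


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all stages; returns the run directory containing the artifacts."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    stage = "data"
    try:
        panel, train, test, registry = _stage_data(cfg, outdir)
        stage = "cluster"
        model, series = _stage_cluster(cfg, train, outdir)
        stage = "graph"
        bundle = _stage_graph(cfg, train, registry, model, series, outdir)
        stage = "train"
        fits = _stage_train(cfg, train, bundle, outdir)
        stage = "evaluate"
        report = _stage_evaluate(cfg, train, test, fits, outdir)
        # intervals for the Lee-Carter reference forecaster (cheap refit)
        lc_resid = calibration_residuals(
            train, lambda p, h: lc_forecast_panel(p, h)
        )
        intervals = prediction_intervals(
            lc_forecast_panel(train, test.T_L).log_rates, lc_resid
        )
        np.savetxt(outdir / "lc_rmsfe.txt", intervals.rmsfe)
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise
    return outdir
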