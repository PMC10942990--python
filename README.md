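# mortgraph

Joint mortality forecasting for groups of countries, combining shape-based
trend clustering, an adaptive country graph, and a graph-convolution +
transformer-encoder network (GT-A), benchmarked against Lee-Carter,
persistence and recurrent/convolutional baselines.

**Who it is for.** Actuaries, demographers and epidemiologists who want
multi-population forecasts of age-specific death rates — where pooling
information across similar countries stabilises each country's forecast —
and researchers who want a fully seeded, CPU-only reference implementation
of a spatio-temporal mortality network with classical baselines in one
harness.

## The model

The data object is a panel of natural-log central death rates
`log m_{i,t,x}` for m countries, T years and d ages (defaults: 16 European
countries, 1950-2016, ages 0-100, HMD 1x1 period format). The pipeline:

1. **Trend extraction.** Each country's age-standardized train surface is
   summarised by its first principal component — a single curve tracking
   the country's overall mortality trend.
2. **Shape clustering.** The m trend curves are clustered by k-means in
   dynamic-time-warping geometry (DTW assignment + DTW barycenter
   averaging); the cluster count maximises the mean silhouette on the DTW
   distance matrix, with the SSE elbow curve reported alongside.
3. **Country graph.** Trend (DTW) distances and capital-to-capital
   great-circle distances combine with the adaptive adjustment matrix
   `A_ada` — within-cluster factor `alpha_c in [0,1]` shrinks distances
   inside cluster c, between-cluster factor `beta >= 1` stretches clusters
   apart — into a similarity `A = exp(-D/tau)` and the propagation matrix
   `P = D^{-1/2}(A + I)D^{-1/2}` (eigenvalues in [-1, 1]).
4. **GT-A network.** Per time step, a graph convolution
   `sigma(P X W + b)` mixes countries; each country's feature sequence
   then runs through a transformer encoder (multi-head scaled dot-product
   attention, `softmax(QK^T / sqrt(d_k)) V`), and a linear head predicts
   next year's d log rates. `alpha`/`beta` train jointly with the network
   by gradient descent. Multi-year forecasts are recursive.
5. **Evaluation.** `RMSE_all`, `MAE_all`, `MAPE_all` over countries x
   years x ages, per-year and per-country breakdowns, per-age RMSE with
   quartiles, percent improvement between model pairs, and RMSFE-scaled
   Gaussian prediction intervals.

Everything neural runs on a small numpy autodiff engine in float64
(`mortgraph.nn`) — no GPU, bit-reproducible per seed. A seeded synthetic
generator (`mortgraph.synth`) draws panels with known Lee-Carter factor
structure, planted clusters and correlated geography, so the whole
pipeline is testable without the registration-gated HMD download.

## Worked example

```python
from mortgraph import (GTA, AdaptiveParams, GTAConfig, SynthConfig,
                       WindowConfig, adaptive_matrix, compose_adjacency,
                       dtw_matrix, first_pc, geo_distance_matrix,
                       kmeans_shapes, metrics_all, persistence_forecast,
                       select_k, simulate_panel, split_train_test,
                       standardize_ages)
from mortgraph.baselines import lc_forecast_panel

panel, truth = simulate_panel(SynthConfig(n_years=48), seed=0)
train, test = split_train_test(panel, last_train_year=int(panel.years[39]))

series = [first_pc(standardize_ages(train.log_rates[i])).pc1
          for i in range(train.m)]
k_star, sil, sse = select_k(series, range(2, 9), n_init=4, seed=0)
clusters = kmeans_shapes(series, k_star, n_init=4, seed=0)

params = AdaptiveParams.init(clusters.k)
bundle = compose_adjacency(
    dtw_matrix(series),
    geo_distance_matrix(truth.registry, train.countries),
    adaptive_matrix(clusters.labels, params),
    countries=train.countries, params=params, labels=clusters.labels)

res = GTA(train, bundle, WindowConfig(t=10, horizon=8),
          GTAConfig(epochs=100, seed=0)).fit()
print(res.summary())
for tag, fc in [("GT-A", res.forecast(test.T_L)),
                ("Lee-Carter", lc_forecast_panel(train, test.T_L)),
                ("persistence", persistence_forecast(train, test.T_L))]:
    rep = metrics_all(fc.log_rates, test.log_rates)
    print(f"{tag:12s} RMSE_all={rep.rmse_all:.4f} MAE_all={rep.mae_all:.4f}")
```

prints (abridged):

```
selected k = 3 (mean silhouette 0.879)
Graph-transformer mortality model [gta]
================================================
countries (m):        16
train years:          1950-1989 (T=40)
...
final train MSE:      0.161988 (initial 1.043241)
adaptive alpha:       [0.563, 0.440, 0.413]
adaptive beta:        1.502
GT-A         RMSE_all=0.0626 MAE_all=0.0497
Lee-Carter   RMSE_all=0.0546 MAE_all=0.0435
persistence  RMSE_all=0.1002 MAE_all=0.0786
```

Reading the numbers: the selection step recovers the three planted
clusters; GT-A's forecast error is ~40% below the persistence baseline.
Lee-Carter edges out the network here *by construction* — the synthetic
generator draws exactly from a Lee-Carter factor model, so LC is the true
model class on this panel. The network's advantage is expected on real
panels whose dynamics depart from a single country-wise factor, which is
precisely the regime the graph and attention components target.

The same pipeline runs from the shell:

```bash
mortgraph simulate --seed 3 --outdir synthetic_hmd     # Mx_1x1 files
mortgraph run-all --seed 2 --outdir run --model gta --model lc
```

For real data, point a YAML config at a directory of HMD `Mx_1x1` text
files (`source: hmd`, `hmd_dir: ...`); HMD is registration-gated, so the
files are never bundled. See `docs/methods.md` for model details, defaults
and limitations.

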