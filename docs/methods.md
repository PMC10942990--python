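# Methods

`mortgraph` forecasts age-specific mortality for a group of countries
jointly. This note documents the models it implements, the choices that
were genuinely open, and what the synthetic experiments do and do not
demonstrate.

## Data model

The working object is a panel `X` of natural-log central death rates with
shape m countries x T years x d ages (defaults m=16, T=67 covering
1950-2016, d=101 covering ages 0-100, matching the Human Mortality
Database's 1x1 period tables for the sixteen European countries with full
coverage of that span). Cells that are missing or non-positive in the
source are imputed, on the raw-rate scale, with the mean rate of the other
countries at the same (year, age), then flagged in an imputation mask; the
log transform follows imputation. Zero and negative rates are treated as
missing because their log is undefined and flooring them would distort the
cross-country mean rule. The sex channel defaults to Total and is
configurable; nothing downstream depends on the choice. Models are trained
on 1950-2000 and evaluated on 2001-2016 by default.

## Trend clustering

Each country's train-years surface is age-standardized (each age column
z-scored over time; constant columns map to zero) and summarised by its
first principal component, computed from the SVD of the centered surface.
The loading sign is chosen so the component correlates non-negatively with
the cross-age mean curve — the extracted series then tracks the overall
trend rather than its mirror image. PCA uses train years only so neither
clustering nor the graph ever sees test data.

The m trend curves are clustered with k-means in dynamic-time-warping
geometry: plain unconstrained DTW with absolute pointwise cost (no
Sakoe-Chiba window), assignment to the nearest barycenter, barycenter
update by DTW barycenter averaging (5 alignment-average iterations per
update, 20 assignment iterations cap, best of `n_init` seeded restarts by
the DTW-squared SSE). Ties in assignment break toward the lower cluster
index; a k-medoids update on the precomputed distance matrix is available
behind `method="medoids"`. DTW is not a metric — the triangle inequality
can fail — so silhouette scores are evaluated directly on the pairwise
distance matrix. Members of singleton clusters receive silhouette 0, where
the within-cluster mean is undefined. The cluster count is chosen by the
mean silhouette over k = 2..8 (ties to the smaller k), with the SSE curve
reported for elbow diagnostics.

## The country graph

Three m x m factors combine into one adjacency:

* `D_dtw` — DTW distances between the first-principal-component curves;
* `D_geo` — great-circle distances between capitals (haversine formula,
  Earth radius 6371.0088 km); capital coordinates ship with the package;
* `A_ada` — the adaptive adjustment matrix: entry alpha_c in [0, 1] when
  countries i and j share cluster c (shrinking the distance inside the
  cluster), beta >= 1 when they do not (stretching clusters apart), and 1
  on the diagonal.

Each distance matrix is divided by its largest off-diagonal entry
(scale-free) and then by its median off-diagonal entry (so both factors
weigh comparably). The composite distance is

    D = (D_dtw' + D_geo') o A_ada        (o = elementwise),

and the similarity is A = exp(-D / tau), diagonal zeroed. Because
exp(-(a+b)) = exp(-a)exp(-b), A is exactly the Hadamard product of the
kernelized trend similarity and the kernelized geographic similarity,
raised elementwise to the adaptive exponents. The additive composite is a
deliberate choice: a *product* of two distances collapses quadratically
toward zero wherever both are small, which drives every within-cluster
similarity to ~1 and turns the propagation operator into cluster
averaging — per-country signal is then unrecoverable (we measured
one-step training loss roughly doubling and multi-year forecasts falling
behind even a persistence forecast under that variant).

The kernel scale tau is self-tuned ("balanced"): it solves
mean off-diagonal row sum of A = 1, so each country weighs its own history
and its entire neighbourhood equally in the propagation matrix

    P = Dhat^{-1/2} (A + I) Dhat^{-1/2},   Dhat = diag(rowsum(A + I)).

A row-sum-target sweep (0.5 / 1 / 2) changed forecast RMSE by under 3%,
so the choice is insensitive; 1.0 is kept for its symmetric
interpretation. tau = median composite distance and fixed constants remain
available. P is symmetric with eigenvalues in [-1, 1], which keeps
repeated graph convolutions non-expansive.

When the adaptive parameters are trainable, alpha = sigmoid(raw) and
beta = 1 + softplus(raw) keep the constraints satisfied for every raw
value, the same composition is rebuilt inside the autodiff graph each
optimisation step, and tau stays frozen at its initial value so the
similarity scale is stable while alpha and beta move. Initial values are
alpha = 0.5 per cluster and beta = 1.5.

## The forecaster

Training samples are sliding windows of t consecutive years (default
t = 10, step s = 1); the target is the year immediately after the window.
Inputs are z-scored per (country, age) with train-year statistics, and
within each window the per-(country, age) window mean is subtracted, so
the network predicts next year's *offset from the window's own level*.
This anchoring makes the learned map translation-invariant along the
trend: recursive forecasts stay inside the training distribution instead
of drifting out of the standardized range, where the LayerNorm-bounded
encoder would otherwise saturate toward a flat (persistence-like)
continuation. Predictions are de-anchored and de-standardized back to log
rates.

The network applies, per time step with shared weights, one graph
convolution sigma(P X W + b) (sigma = ReLU; d -> 64), then feeds each
country's 64-dimensional feature sequence — with sinusoidal positional
encoding — through a 2-layer post-norm transformer encoder (d_model = 64,
4 heads, feed-forward width 256, d_k = d_v = d_model / h), and maps the
last hidden state linearly onto the d age-specific targets. Optimisation
is Adam at learning rate 0.001 on one-step MSE (standardized scale) for
500 epochs by default, minibatch 8, fully seeded: the same seed gives a
bit-identical run on one platform. Inverted dropout on the encoder's
residual branches is available (default 0 — the synthetic panels are too
small to need it); it acts during training only, so inference stays
deterministic. Multi-year forecasts append the
one-step prediction and roll the window forward recursively — one-step
training is preferred over direct multi-horizon heads because 51 train
years leave too few long-horizon samples.

Three model kinds share this implementation: `gta` (P from the bundle,
alpha/beta trained jointly), `gt` (P from the bundle, adaptive parameters
frozen), and `tf` (P fixed to the identity — the pure transformer
baseline). With P = I and frozen parameters the graph model is
bit-identical to the transformer baseline, a reduction the tests assert
exactly.

All neural components — the autodiff engine, GCN, attention, encoder,
LSTM/RNN/causal-CNN baselines, Adam — are implemented in numpy inside
`mortgraph.nn` in float64; gradients are verified against central finite
differences in the test suite.

## Baselines and evaluation

Lee-Carter fits log m_{x,t} = a_x + b_x k_t per country: a_x is the time
mean, (b_x, k_t) the leading singular pair of the centered surface,
normalised to sum(b) = 1, sum(k) = 0; the factor is forecast as a random
walk with drift theta = mean first difference of k_t (point forecast only,
no jump-off correction or refit, matching its role as the classical weak
baseline). LSTM, plain RNN and a causal 1-D CNN over time are trained with
exactly the GT-A protocol (same windows, anchoring, loss, optimizer,
epochs, recursion) with only the spatio-temporal core swapped; they share
weights across countries and are trained jointly. The persistence
forecast repeats the last observed year.

Metrics are computed on natural-log mortality: RMSE/MAE/MAPE over all
countries x years x ages, RMSE per forecast year, per-country metrics,
and per-age RMSE with mean and quartiles (linear interpolation between
order statistics). MAPE is in percent; exactly-zero truth entries are
excluded from MAPE with their count reported. The signed per-age error
profile subtracts the per-age residual standard deviation from the mean
residual — by construction it is negative for an unbiased forecast — so
the plain mean residual is always reported alongside.

Prediction intervals use the RMSFE recipe: the root mean squared forecast
error per (country, age) is estimated from a rolling-origin hold-out of
the last 10 train years (1991-2000 under the defaults), and the interval
at level q is point +/- z_{(1+q)/2} * RMSFE with the Gaussian quantile
(1.959964 at 95%).

## Synthetic data

The generator draws panels with a known Lee-Carter factor structure:
log m = a_x + b_x k_t + eps, eps iid Normal(0, 0.05) on the log scale by
default. a_x is a Siler-type age profile (infant hump, mid-life plateau,
Gompertz old-age rise) with a small smooth per-country deviation; b_x is
positive, heavier at young ages, and sums to 1; k_t mixes a cluster-common
random walk with a country-own walk (correlation 0.9, innovation sd 0.6)
around a linear drift shared within the cluster (country-level jitter sd
0.05). Capitals are drawn around per-cluster geographic centres (sd 2.5
degrees), so geography correlates with cluster membership as it does for
the real panel. The defaults — 16 countries, 3 clusters, 67 years, 101
ages — mirror the real study conditions.

The default cluster drifts are -1.5, 0, +1.5 per year on the factor
scale. They straddle zero deliberately: age-wise standardization removes
the *magnitude* of a trend, so clusters are recoverable by shape
clustering only if their trends differ in shape (sign/curvature), not
merely in slope. Two clusters with same-sign drifts of different size are
indistinguishable after standardization by construction — a property of
the method, not a defect of the generator.

An optional missingness injector masks each cell with probability p
(never all countries at once), routing the panel through the Mx-dialect
writer and reader so the imputation path is exercised end-to-end.

What the generator does **not** emulate: cohort effects, age-coherence
constraints between neighbouring ages beyond the smooth profiles, wars or
pandemic shocks, heteroskedastic observation noise at small exposures
(real old-age rates are much noisier), and cross-country correlation of
the observation noise. Passing the synthetic checks therefore shows the
pipeline recovers the structure it models — not that the same margins
hold on registered HMD data, which users must download themselves
(`mortgraph run-all --config ... ` with `source: hmd`).

## Experiment sizes

The property checks train on desk-scale problems chosen to finish in
minutes on one CPU: forecast-skill runs use 16 countries, 40 train years,
horizon 8, 100 epochs, d_model 64; reduction and loss-decrease checks use
4-6 countries with a 16-dimensional model. Cluster-recovery runs use the
full 16-country geometry over 10 seeds. Interval calibration uses 10,000
Gaussian draws.

## Known limitations

* The adaptive parameters move little over short trainings (beta drifts
  ~0.05 in 100 epochs); their gradient pathway is exact but weak, since P
  enters every sample identically.
* DTW barycenter averaging fixes the barycenter length to the series
  length and is a local method; with very short series the silhouette can
  legitimately prefer merging small clusters.
* The recursive forecaster propagates its own one-step errors; there is
  no direct multi-horizon head.
* Lee-Carter intervals and the RMSFE recipe assume Gaussian, serially
  independent forecast errors; real multi-year errors are autocorrelated,
  so coverage on real data will be optimistic at long horizons.
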