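# Methods

## Model and estimator

The package decides between two instantaneous linear structural models
for a standardized bivariate time series,

    model 1:  y_t = α x_t + d_t        (x → y)
    model 2:  x_t = α y_t + e_t        (y → x)

under the working assumptions that (i) the variables are jointly
stationary, (ii) the regressor of the true model is temporally
autocorrelated, and (iii) the disturbance's autocorrelation function
differs from the regressor's at one or more lags. Gaussianity is a
*working* assumption only: it restricts the estimator to second-order
statistics (covariances), and any non-Gaussianity affects higher moments
without biasing the covariance-based decision.

Estimation proceeds on windows. Both series are standardized, cut into m
aligned windows of length L, and the shared coupling coefficient is
estimated as the pooled lag-0 correlation α̂ (with standardized variables
the regression coefficient is the same in both directions, and the
correlation form is symmetric in its arguments, which makes the criterion
exactly antisymmetric under argument swap). Residual windows are
d = y − α̂x and e = x − α̂y, not re-standardized; their covariances enter
the criterion as they are. Each variable's m windows give an L×L sample
covariance (divisor m), each variable–residual pair a 2L×2L joint
covariance, and the decision criterion is

    C = 2 I(x, d) − 2 I(y, e),
    2 I(a, b) = logdet cov(a) + logdet cov(b) − logdet cov([a; b]),

with direction x → y for C < 0, y → x for C > 0, undetermined when
|C| ≤ 1e−12. C equals the log-likelihood ratio of the two Gaussian
models; in the true model the regressor–residual mutual information
vanishes in population, so the sign of C points at the model whose
residual is "more independent" of its regressor.

### Identifiability

The population criterion, derived in `soc.analytic` from closed-form
Toeplitz window covariances of the AR pair model, is strictly negative
for the true direction whenever regressor and disturbance
autocorrelations differ within the window span, and exactly zero when
they coincide. The boundary case is not a numerical artifact: with equal
autocorrelation spectra *no* second-order method can identify the
direction, and the package's simulations confirm chance-level accuracy
there. The same condition drives multivariate fixtures: a node whose
disturbance shares its parent's autocorrelation sits on the boundary, so
synthetic network generators should assign distinct per-node AR
coefficients (the defaults in the tests spread them over 0.2–0.9).

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `window_length` L | 5 | spans several lags of typical AR regressors while keeping 2L×2L covariances well-conditioned from modest m |
| `stride` | None | None = non-overlapping windows (stride L); falls back to stride 1 when fewer than `m_min` non-overlapping windows exist, so short recordings remain analyzable; an explicit stride is always honored |
| `m_min` | max(20, 10·L) | minimum window count for a stable L×L covariance |
| `ridge` | 1e−6 | relative diagonal regularization, escalated ×10 on factorization failure up to 1e−2, then an error; both mutual-information terms always use the same ridge |
| `toeplitz` | off | optional diagonal-averaging projection of window covariances onto stationary (Toeplitz) structure; reduces variance at small m, off by default to keep the plain covariance formulation |
| `tie_tol` | 1e−12 | |C| below this is an undetermined direction |

Numerical notes. Log-determinants are computed by Cholesky
factorization. Within one mutual information the ridge is applied as a
single absolute value (ridge × mean diagonal of the joint covariance) to
the joint matrix and its diagonal blocks; this preserves Fischer's
inequality det cov([a;b]) ≤ det cov(a) · det cov(b) exactly, so the
plug-in mutual informations are nonnegative to rounding. Covariances use
the population divisor m throughout. Standardization uses the population
standard deviation; constant series raise a zero-variance error. For
multi-instance input (instances × time), each time index is standardized
across instances; for a single long series, standardization is global
before windowing.

## Baselines

*Pairwise LiNGAM.* Likelihood-ratio statistic
R = ρ̂ · mean[x·tanh(y) − tanh(x)·y] on standardized series; R > 0
decides x → y. The tanh nonlinearity is the standard choice for
super-Gaussian sources; a cumulant variant (x³y − xy³) is available via
`nonlinearity="cube"` for sensitivity checks. The statistic is stored
negated in `criterion_C` so that negative always means x → y across
detectors.

*Granger causality.* Bivariate VAR fit by per-equation OLS with
intercept on standardized series; model order p ∈ {1..p_max} (default
p_max 10) minimizes AIC = n_eff·logdet Σ̂ + 2k computed on a common
effective sample (the last n − p_max points) so orders are comparable.
GC statistics are log variance ratios of own-lags-only vs full
equations; the larger statistic wins (no significance gating), so every
pair yields a direction, matching how accuracies are tabulated. The
benchmark harness clips p_max to (n−1)//11 on short series so the VAR
stays estimable at n = 100.

## Synthetic data

`simulate_ar` draws stationary AR(p) series (recursion via a linear
filter, 200-sample burn-in discarded; Laplace innovations use scale
b = σ/√2 so innovation variance matches the Gaussian case).
`simulate_pair` couples a regressor (default AR(1), coefficient 0.8) to
an AR(1) disturbance with coefficient 0.2 through y = αx + d and
optionally adds independent Gaussian observational noise to both
variables with variance var(signal)/SNR. `simulate_network` builds an
instantaneous SEM over independent AR disturbances in topological
order. The benchmark harness derives one generator per
(condition, dataset) pair from the master seed via `SeedSequence` spawn
keys, scores undetermined decisions as a fair coin flip with the
harness's own derived generator, and reports exact (Clopper–Pearson)
binomial 95% intervals.

Benchmark anchor conditions, fixed once from pilot runs: the
coupling-strength sweep uses α ∈ {0.1, 0.3, 0.5, 0.7} at n = 100 (large
enough to show a clean gradient, small enough not to saturate at 100%);
the SNR sweep uses α = 0.3, n = 300 over SNR ∈ {∞, 10, 3, 1}, where
both the second-order criterion and Granger causality degrade visibly.
Default replication is 400 datasets per condition (binomial SE ≤ 2.5
percentage points), configurable upward.

What the generators emulate: controlled temporal dependence, coupling
strength, observational noise, and innovation family — the axes the
method's identifiability theory speaks to. What they do not emulate:
biophysical dynamics, volume conduction / source leakage, nonstationarity,
and inter-subject variability of real M/EEG envelopes. Passing the
synthetic benchmarks therefore establishes the estimator's statistical
behaviour under its model class, not performance guarantees on real
recordings.

## Two-stage networks

Stage one estimates the undirected skeleton as the support of the
L1-penalized precision matrix (scikit-learn `GraphicalLassoCV`, 5-fold
CV with seed-controlled shuffling, columns standardized internally).
Cross-validation selects the penalty for predictive loss and is known to
under-penalize for support recovery — on autocorrelated samples the
selected penalty falls below the sampling-noise scale and spurious
precision entries survive as small nonzeros. The skeleton therefore also
requires the penalized *partial correlation* −P_ij/√(P_ii P_jj) to
exceed 0.1 in magnitude (configurable; 0 restores the raw lasso
support). In pilot chain simulations (n = 5000) spurious partial
correlations stay below ~0.05 while genuine edges sit near 0.5, so the
floor separates them by an order of magnitude. Stage two orients each
retained edge with the chosen pairwise detector on the full-length
columns; the stages are deliberately independent. Orientations are
pairwise and may jointly contain cycles — no global DAG search is
attempted.

## Split-half consistency

Three per-edge metrics: precision entries, raw pairwise criterion
values, and skeleton-masked criterion values (two-stage). Consistency is
the Pearson correlation (Spearman via flag) of vectorized upper-triangle
values between two data halves — temporal halves of one subject
(odd sample to the first half), or two random disjoint halves of the
cohort, each temporally concatenated (default 100 repeats).

For the two-stage metric the default correlates the *complete*
upper-triangle network vectors, with edges absent from a half's skeleton
contributing 0 there — i.e., the two half networks are correlated as
matrices. This is what makes skeleton masking raise reliability: pairs
that carry only noise are replaced by consistent zeros. A stricter
`mask_mode="union"` (correlate only pairs present in at least one half's
skeleton) is available; note that it removes exactly the pairs whose
suppression creates the two-stage advantage, so under it the two metrics
are statistically indistinguishable on synthetic cohorts.

The template procedure estimates a group-level network from the
concatenation of all subjects (a large-sample proxy for ground truth),
then re-orients the template's edges from each sampled subject's data
alone; per-edge accuracy is the fraction of subjects matching the
template, with undetermined subject-level directions scored as a seeded
coin flip (chance level 50%).

Cohort study condition for the reliability properties (fixed once from a
recorded pilot): 8 nodes, 5 edges, coupling 0.5, per-node AR(1)
coefficients 0.35–0.65, 800 samples per subject, 6 subjects per cohort.
The narrow spectrum spread is deliberate: it is the realistic
envelope-data regime where direction criteria are individually weak but
the correlation skeleton is robust — the regime where masking matters.
With widely separated spectra and strong coupling, raw consistency is
already at ceiling and the two metrics tie.

## Envelope preparation

Amplitude envelopes are the modulus of the analytic signal
(`scipy.signal.hilbert`) per column; the analytic signal is unreliable
near recording edges, so an optional `trim_edge_fraction` (e.g. 0.02)
drops that fraction at each end. Downsampling is polyphase
(`resample_poly` with line padding), output length floor(n·target/source);
upsampling is not supported. Envelopes of band-limited signals are slow,
so they are typically taken to ~1 Hz before causal analysis.

## Known limitations

- On the identifiability boundary (equal regressor/disturbance
  autocorrelations) the direction is undecidable in principle; results
  there are coin flips, and nothing in the output flags this beyond a
  small |C|.
- No significance test or p-value accompanies C; only its sign and
  magnitude are reported.
- Pairwise orientation of a skeleton ignores multivariate structure; with
  strong indirect paths the pairwise decision for an edge can reflect an
  ancestor's influence.
- The graphical-lasso skeleton assumes i.i.d. samples; autocorrelation
  inflates its effective noise, which the partial-correlation floor
  mitigates but does not model.
- Window covariances assume stationarity within the analysis segment.
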