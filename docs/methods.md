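# Methods

## The glycolysis oscillator

`glycodmd` simulates a minimal two-variable model of glycolytic
oscillations of the Higgins type.  Fructose-6-phosphate (F6P, `x`) is
produced from glucose at constant influx `v` and converted by
phosphofructokinase (PFK) into fructose-1,6-bisphosphate (F16BP, `y`);
PFK is allosterically activated by its own product, and F16BP is removed
by a first-order (linearized Michaelis–Menten) aldolase step:

```
dx/dt = v - k1 * x * h(y)
dy/dt = k1 * x * h(y) - k2 * y
h(y)  = (basal + (y/K)^n) / (1 + (y/K)^n)
```

All concentrations are in mM and time in minutes.  `K` is the
half-saturation concentration of the allosteric binding step, `n` the
Hill coefficient of its cooperativity, and `basal` the residual PFK
activity at vanishing product.

The basal activity matters twice.  Without it the region `y -> 0` is
absorbing — once the product concentration drops below the activation
threshold, the feedback never re-ignites, F6P accumulates without bound
and no stable limit cycle exists; the small leak rescues the trajectory
(F6P builds up until even the basal flux regenerates F16BP), which bounds
the relaxation oscillation.  It also bounds the instability region in `v`
from *below*: for the default parameters the fixed point of the `n = 3`
model is unstable only for `v` in roughly (8.2, 12.8) mM/min, so both
slow-influx (7 mM/min) and fast-influx (15 mM/min) cells show damped
oscillations while intermediate ones (10 mM/min) oscillate sustainedly.
This is the same structural role the basal term plays in the standard
Sel'kov-type PFK models.

### Fixed point and regimes

Flux balance of the linear removal step gives `y* = v/k2` and
`x* = v / (k1 h(y*))` in closed form.  The Jacobian at the fixed point
classifies each parameter set: complex eigenvalues with negative real
part are a stable focus (damped oscillations), real negative eigenvalues
a stable node, and any positive real part means the bounded nonlinearity
carries the trajectory to a limit cycle (sustained oscillations).
Eigenvalue classification is cross-checked by
`sustained_by_simulation`, a noiseless long-horizon simulation that
tests whether the peak oscillation amplitude decays; the two agree on a
5×5 (v, n) grid in the test suite.  A real part within `1e-8` of zero is
flagged as marginal with a warning rather than silently classified.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `v` | 10 | mM/min | reference single-cell influx; inside the `n = 3` instability window |
| `k1` | 4 | 1/min | PFK rate constant |
| `k2` | 4 | 1/min | removal rate; the value at which the Hill sweep turns sustained at n = 3 |
| `K` | 4.0 | mM | half-saturation of the product activation |
| `n_hill` | 3 | – | cooperativity; damped at 2, sustained at ≥ 3 |
| `basal` | 0.12 | – | basal PFK activity fraction |
| `noise_sigma` | 0.02 | – | per-sample log-sd of multiplicative trace noise |
| `dt`, `sample_every` | 1/600 min, 10 | – | RK4 step; output sampling 1 Hz as in time-lapse imaging |
| `t_end` | 10 | min | 601 samples per trace |

`k1`, `K` and `basal` were chosen once so that every qualitative regime
constraint holds simultaneously: damped at `n = 1, 2` and sustained at
`n = 3, 4` for the reference cell; a population centred at 14.5 mM/min
that is mostly damped foci with occasional sustained cells near
12.5 mM/min; and the (7, 10, 15) mM/min condition triple mapping to
(damped, sustained, damped).

### Integration, initial state and noise

The deterministic part is integrated with fixed-step 4th-order
Runge–Kutta (`dt = 1/600` min, decimated by 10 to a 1 Hz output grid; a
10×-finer reference integration agrees to better than 1e-4 relative).
The default initial state is the fixed point with F16BP displaced by
+25%, emulating the synchronized transient that follows a glucose bolus;
sustained cells spiral out to their limit cycle from the same start.

Noise is a multiplicative log-normal factor (log-mean 0, log-sd
`noise_sigma`) applied independently to every recorded sample of each
species.  This represents fluctuations at the observation timescale —
molecular noise plus imaging noise as seen by the camera — is
positivity-preserving, and is essential for the spectral phenomenology
studied here: white multiplicative observation noise biases the
eigenvalues of an unembedded DMD fit toward the origin (the classic
errors-in-variables shrinkage), which delay embedding then repairs.
Noise applied inside the integrator instead would make the sampled data
an almost exact Markov realization, for which even the unembedded
one-step fit is unbiased and delay embedding has nothing to correct.

Heterogeneous populations draw per-cell influx values from a log-normal
distribution parameterized by its median (centre 14.5 mM/min, log-sd
0.065, spanning roughly 12.5–16.5 mM/min at ±2 sd).

## DMD with time-delay embedding

`fit_exact_dmd` implements exact DMD: a rank-`r` truncated SVD of the
first snapshot matrix, the reduced operator
`A' = U_r* X2 V_r S_r^{-1}`, its eigen-decomposition, exact modes
`X2 V_r S_r^{-1} W` (projected modes are substituted for eigenvalues at
the origin), and amplitudes solved by least squares against the first
augmented snapshot.  Continuous rates use the principal branch,
`omega = ln(lambda)/dt`, round-trip-tested to 1e-12.  Eigen-triplets are
ordered by `|b_j| * ||phi_j||`, ties broken by `|lambda_j|`; singular
values below `eps * max(dim) * s_max` are treated as zero, and a
requested rank above the numerical rank is truncated with a warning.

`build_hankel` stacks `d` extra copies of every data row shifted by
`l, 2l, ..., d*l` samples (block-per-shift layout, `m(d+1)` rows,
`n - d*l` columns).  Higher-order DMD — DMD under a multi-lag evolution
assumption with a companion-structured operator — is algebraically DMD
on the same stacked snapshot vectors and is implemented that way;
`fit_hodmd(snapshots, d)` equals exact DMD on a Hankel embedding with
`d - 1` extra shifts, and `d = 1` reproduces plain exact DMD to 1e-10.

De-embedding reads only the shift-0 block of the modes (no anti-diagonal
averaging); the modal sum can be evaluated at any step index, so
full-length reconstructions extrapolate the trailing `d*l` samples
beyond the embedded column range.  Because that trailing piece is a
forecast, not a fit, the embedding-sweep RMSE (`embedding_scan`) is
scored over the Hankel column range — the window the regression actually
fits — while forecast quality is measured by the prediction experiments.
`embedding_scan` centers each trace by default: the analytic spectrum
describes deviations from the steady state, and centering keeps the
rank budget from being spent on static offsets.

Per-cell amplitude features for classification are
`|phi_j(cell i, shift 0) * b_j|` — the modulus (root of the summed
squared real and imaginary parts), which is invariant to the arbitrary
phase gauge of each mode/amplitude pair.

## Spectral diagnostics

Each eigenpair gets the relative data-space residual
`||X2 w_j - lambda_j X1 w_j|| / ||X1 w_j||`, with `w_j` the eigenvector
in the snapshot basis of `X1`.  Exactly linear noiseless data give
residuals at machine precision; an injected random mode scores more than
10× the valid maximum.  The default acceptance threshold is 0.5
(relative, configurable); the embedding studies in the test suite use a
stricter 0.1 to resolve the difference between unembedded and deeply
embedded spectra.  Residuals are invariant to global rescaling of the
data.

`compare_to_analytic` matches each DMD eigenvalue's unit-circle phase to
the nearest analytic phase (`exp(lambda dt)` rescaled to unit modulus)
by greedy nearest neighbour — adequate at the ranks used here (≤ 50) —
and reports angular distances in [0, π].

## Experiment design

**Reconstruction sweep.**  100 cells, influx median 14.5 mM/min, Hankel
DMD at `r = 25` over `d ∈ {10, 50, 100, 150}`.  At 1 Hz the damped
oscillation period is ≈ 130 samples, so the sweep spans a tenth of a
period up to slightly more than one; the spectrum and the training RMSE
stabilize as `d` passes the period, and a 5-step delay with `d = 30`
(same embedded span) agrees with the 1-step `d = 150` embedding to
within 10%.

**Prediction benchmark.**  The averaged trace of a field of 100 cells at
`v = 12.9` mM/min — weakly damped, just outside the Hopf window, so the
held-out window still oscillates, as the averaged bolus-response traces
it emulates do.  Three replicate fields are simulated per run
(simulated for 30 min so the forecast horizon is long); training
prefixes of {200, 300, 400, 500} samples at subsampling factors
{1, 2, 3} are each scored on the training window and on the fixed
held-out segment that starts after the longest training window, so every
setting forecasts the same target data.  The embedding is `d = 150`
(capped at half the training window), rank 8, and eigenvalues outside
the unit circle are projected onto it before forecasting — the standard
stabilization for DMD extrapolation.  Replicate-averaged held-out R²
then increases monotonically with training length, and factor-3
subsampling changes it by well under 0.1.

**Classification.**  Populations at `v = 7, 10, 15` mM/min (damped /
sustained / damped) are concatenated, embedded at `d = 100`, truncated
at `r = 50`; per-cell amplitude features are standardized per mode,
embedded with kernel PCA (RBF, bandwidth = median pairwise distance;
linear kernel available for testing) and clustered with seeded k-means
(10 restarts) on the first three components into four clusters (the
silhouette criterion independently selects k = 4 on this mixture).
Labels are canonicalized by descending cluster size.  The two damped
populations each concentrate ≥ 90% in one cluster; the sustained
population scatters across the remainder, reflecting its broad range of
limit-cycle amplitudes.

**Imaging round trip.**  `synth_video` renders traces as non-overlapping
disks on a hexagonal grid with constant background and optional
per-pixel Gaussian noise, storing the ground truth; `extract_traces`
inverts it exactly in the noise-free case, and with noise the extracted
trace error shrinks as `noise_sd / sqrt(pixels per cell)`.  Whole-video
HoDMD (`d = 30`, flattened frames as snapshots) reconstructs a noiseless
32×32×200 stack to SSIM > 0.9 per frame and per-cell trace R² > 0.9.
Segmentation itself is out of scope: masks are inputs (integer TIFF or
PNG), coordinates are 0-based with `x` = column and `y` = row.

## What the synthetic data do and do not emulate

The generator reproduces the features the analysis depends on: a
heterogeneous population of damped and sustained oscillators with
influx-controlled regimes, synchronized bolus-like transients,
multiplicative observation noise, and imaging geometry (disk-shaped
cells, label masks, mean-intensity traces).  It does not emulate
photobleaching, cell movement or growth, secretory coupling between
neighbouring cells, non-stationary baseline drift, or segmentation
errors — so passing tests demonstrate correctness of the algorithms
under the model's assumptions, not robustness to every artifact of real
recordings.

## Numerical choices and limitations

- SVD truncation tolerance `eps * max(dim) * s_max`; all-zero input is
  rejected as degenerate.
- Reconstruction takes the real part; the relative imaginary residue is
  recorded and warned about above 1e-6 for conjugate-closed spectra.
- A zero eigenvalue maps to the infinite-decay sentinel `-inf` and is
  excluded from reconstruction.
- k-means and kernel PCA are deterministic under the provided seed;
  kernel-PCA component signs are arbitrary.
- The master seed fans out to per-stage seeds via
  `SeedSequence([master, stage])`, so pipeline stages can be re-run
  independently.
- Forecast quality degrades for strongly nonlinear (sustained) dynamics;
  the linear modal form cannot track limit-cycle phase indefinitely, and
  the package reports rather than hides this (damped forecasts score
  higher than sustained ones at equal horizon).
- The mean nearest-phase distance to the analytic spectrum is an
  aggregate over all retained eigenvalues, including low-energy ones;
  it is meaningful for comparisons across embedding depths, not as an
  absolute error measure.
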