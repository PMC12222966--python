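# glycodmd

Dynamic mode decomposition (DMD) with time-delay embedding for
single-cell glycolytic oscillations.

Glycolysis in fermenting yeast oscillates: NAD(P)H autofluorescence of
individual cells waxes and wanes as key intermediates cycle through the
pathway's allosteric feedback.  Time-lapse imaging turns each cell into
a noisy time series; the analysis problem is to decompose, denoise,
forecast and *classify* hundreds of such traces at once.  `glycodmd`
implements that pipeline for computational biologists: a minimal
two-variable glycolysis oscillator as a fully controlled synthetic data
source, Hankel/time-delay-embedded DMD and higher-order DMD (HoDMD) as
the decomposition engine, spectral diagnostics against the model's exact
linearization, and mode-amplitude-based clustering of single-cell
trajectories.

## The model and the method

The oscillator is a Higgins-type scheme for the two intermediates
fructose-6-phosphate (F6P, x) and fructose-1,6-bisphosphate (F16BP, y),
with constant glucose influx v, product-activated phosphofructokinase
and first-order removal:

    dx/dt = v − k₁·x·h(y),    dy/dt = k₁·x·h(y) − k₂·y,
    h(y) = (ε + (y/K)ⁿ) / (1 + (y/K)ⁿ)

Depending on v and the Hill coefficient n, the fixed point
(y* = v/k₂, x* = v/(k₁h(y*))) is a stable node, a stable focus (damped
oscillations) or unstable with a surrounding limit cycle (sustained
oscillations); the Jacobian eigenvalues λ₁,₂ decide which, and
`exp(λ·Δt)` rescaled to the unit circle is the analytic reference
spectrum for DMD.

DMD approximates the one-step evolution of snapshots x₁…x_m by a
best-fit linear operator through a rank-r truncated SVD and represents
the data as a modal sum

    x_k ≈ Σⱼ φⱼ · λⱼ^(k−1) · bⱼ,    ωⱼ = ln(λⱼ)/Δt.

Time-delay embedding stacks d time-shifted copies of every cell's trace
into a Hankel matrix before fitting, which is what lets a rank-25 model
faithfully capture a 100-cell heterogeneous population.

## Worked example

```python
import glycodmd as g

base = g.OscillatorParams()              # v = 10 mM/min, n = 3, 1 Hz
print(g.jacobian_eigenvalues(base))
print(g.classify_regime(base).value)

spec = g.PopulationSpec(n_cells=100, v_log_mean=14.5, seed=7, base=base)
f6p, f16bp, v = g.simulate_population(spec)

records = g.embedding_scan(f6p, d_list=[10, 50, 100, 150], r=25)
for rec in records:
    print(f"d = {rec['d']:3d}: training RMSE = {rec['rmse']:.3f} mM")

ana = g.population_analytic_spectrum(
    [base.with_(v=float(x)) for x in v], f6p.dt)
print(g.compare_to_analytic(records[0]["model"], ana).mean,
      g.compare_to_analytic(records[-1]["model"], ana).mean)
```

prints

```
((0.2600+2.1483j), (0.2600-2.1483j))
sustained_oscillation
d =  10: training RMSE = 0.188 mM
d =  50: training RMSE = 0.180 mM
d = 100: training RMSE = 0.147 mM
d = 150: training RMSE = 0.146 mM
1.198  0.922
```

The reference cell (v = 10 mM/min) has eigenvalues with positive real
part — an unstable focus orbited by a limit cycle, i.e. sustained
oscillations at 2.15 rad/min.  For the heterogeneous population (influx
median 14.5 mM/min, mostly damped cells), the training RMSE of the
rank-25 Hankel DMD falls as the embedding depth grows toward one
oscillation period (~130 samples at 1 Hz), and the mean angular distance
between the DMD eigenvalue phases and the analytic linearized spectrum
shrinks from 1.20 to 0.92 rad — deeper embedding concentrates the
recovered spectrum around the true one.

The classification arm turns a fitted model into per-cell features
(`cell_mode_amplitude_features`), embeds them with kernel PCA and
clusters with k-means; on a mixture of populations simulated at v = 7,
10 and 15 mM/min, the two damped populations each land ≥ 90% in a single
cluster while the sustained one scatters.  The imaging arm
(`synth_video` / `extract_traces` / `fit_hodmd`) closes the loop from
per-cell traces to label-masked videos and back.

## Command line

```bash
glycodmd simulate --n-cells 100 --seed 1 --out traces.csv
glycodmd embed-fit --input traces.csv --delay 150 --rank 25 --out model.json
glycodmd classify --config experiment.yaml --seed 1 --out results/
glycodmd synth-video --input traces.csv --out video.tif
glycodmd extract-traces --stack video.tif --mask video_mask.tif --out out.csv
```

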