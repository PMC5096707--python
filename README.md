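# prefmode

Preferred-mode tensor analysis of neural population recordings.

A trial-averaged population recording across `N` neurons, `C` experimental
conditions and `T` times is naturally a third-order tensor
`X ∈ ℝ^{N×C×T}`. Two very different generative hypotheses leave opposite
fingerprints in that tensor:

- **Tuning for external variables** — `x(t,c) = B u(t,c)` with `M` input
  variables — makes every neuron a linear readout of the same `M` signals.
  The data then need at most `M` *basis-neurons* (C×T patterns) no matter
  how many times are analyzed: the tensor is **neuron-preferred**.
- **Internal population dynamics** — `x(t+1,c) = A x(t,c)`, the same rule
  for every condition — make every condition a trajectory of the same
  system launched from a different initial state. If the initial states
  span an `r`-dimensional subspace, the data need at most `r`
  *basis-conditions* (N×T patterns) at any timespan: the tensor is
  **condition-preferred**.

The package measures this by truncated SVD of the two matrix unfoldings
`X₍₁₎ ∈ ℝ^{N×CT}` (rows = neurons) and `X₍₂₎ ∈ ℝ^{C×NT}` (rows =
conditions). With a shared basis count `k` — chosen at the single central
timepoint, where neither mode can be preferred — it tracks the normalized
squared reconstruction error of both modes on symmetrically growing time
windows, sweeps `k`, and issues a verdict (neuron / condition / none) from
a paired test across conditions. This is the population-level diagnostic
used to separate representational ("tuning") models from dynamical-system
models of cortex: sensory-driven areas come out neuron-preferred, areas
that generate output through internal dynamics come out condition-preferred.

The library also ships what is needed to interrogate the method itself:
linear-system simulators with known ground truth (pure tuning, pure
dynamics, mixtures, partial observation `y = C_obs x`, time-varying
dynamics), Poisson spike emission and PSTH preprocessing (Gaussian
smoothing, soft normalization, cross-condition mean removal, N=C
equalization), control manipulations that provably flip the preferred
mode, condition subsampling, HDF5/CSV/JSON serialization, and a CLI.

## Worked example

Simulate a pure autonomous dynamical system (orthogonal `A`, eigenvalues
clustered near 1; initial states spanning 10 of 20 dimensions) and run the
full analysis:

```python
import prefmode as pm

tensor, truth = pm.simulate_lds(pm.preset_config("fig8d"))  # a=1, b=0
results = pm.PreferredModeAnalysis(tensor).fit()
print(results.summary())
```

```
Preferred-mode analysis
=======================================================
tensor shape (N x C x T):   20 x 20 x 300
units / centered:           soft_normalized / True
basis elements k:           9 (threshold rule)
-------------------------------------------------------
neuron-mode error (full):    0.4176 (sem 0.0292)
condition-mode error (full): 0.0166 (sem 0.0064)
relative difference:         -24.150
paired test (wilcoxon):      p = 1.91e-06 (20 conditions)
-------------------------------------------------------
preferred mode:              condition
=======================================================
```

Nine basis-conditions reconstruct the full tensor to within 1.7% error
while nine basis-neurons leave 42% unexplained — the signature of shared
dynamics. The condition-mode error is also *flat* as the analyzed timespan
grows (`results.sweep.condition_errors`), exactly as the theory predicts
for an autonomous system. Running the same pipeline on the pure
input-driven preset (`"fig8a"`, `a=0, b=1`) gives the mirror image:
neuron-mode error 0.1375, condition-mode error 0.3994, preferred mode
`neuron`.

`results.plot_sweep()` and `results.plot_diff()` draw the error-vs-timespan
curves (with SEM bands across conditions) and the error-difference-vs-k
curve; `results.to_report().save("report.json")` writes the full record.

The same pipeline is available from the shell:

```bash
prefmode simulate --preset fig8d --seed 0 --out sim.h5
prefmode analyze --in sim.h5 --k auto --threshold 0.05 \
    --out report.json --curves curves.csv
```

## Documentation

`docs/methods.md` describes the model classes, the analysis procedure and
its parameters, the synthetic-data generator and its scale conventions,
numerical choices, and known limitations.
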