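# condrobust

Conditional robustness analysis for dynamical biochemical network models.

`condrobust` answers a design question that classical sensitivity analysis
does not: *which few parameters of a model should be fixed, and at what
values, to push a system's output toward a desired regime?*  Motivating
applications are drug-target selection (silencing the proliferation signal
of a cancer signaling network by conditioning a handful of kinetic
constants) and synthetic-circuit tuning (maximizing the area or sharpness
of a gene-circuit pulse).

## The method

A model is an ODE system `dx/dt = f(x, u, p)` with a scalar *evaluation
function* `z = ζ(p)` summarizing one simulated trajectory (area under a
curve, peak value, time of the peak).  Over a parameter box
`P = Π [c_ℓ,i·p_wt,i, c_u,i·p_wt,i]` with uniform prior ψ, the robustness
of the capability measured by ζ is the integral `R = ∫ ψ(p) ζ(p) dp`,
estimated by Monte Carlo as the sample mean of z.

The analysis pipeline:

1. **Sample** N points of the box by Latin hypercube sampling with linearly
   spaced strata (one sample per equal-width stratum per dimension).
2. **Simulate** the model at every point and collect `Z = {ζ(p)}`.
3. **Partition** Z into the lower and upper probability-α tails L(α), U(α)
   (empirical order statistics) and aggregate the corresponding parameter
   subsets P_L, P_U.
4. **Estimate** per-parameter conditional densities `f_{P_i|L}` and
   `f_{P_i|U}` by Gaussian kernel density estimation.
5. **Rank** parameters by the moment-independent robustness indicator

       μ_i = ∫ | f_{P_i|U}(p_i) − f_{P_i|L}(p_i) | dp_i  ∈ [0, 2],

   the L₁ distance between the two conditional densities: μ_i ≈ 0 means
   p_i does not discriminate extreme outputs; μ_i → 2 means complete
   separation.
6. **Condition**: fix the top-μ parameters (the conditioning set K) at the
   modes of their conditional densities — from `f_{P_i|U}` to maximize the
   output, from `f_{P_i|L}` to minimize it — then re-sample the free
   parameters and measure how the conditional output density `f_{Z|K}`
   has shifted (mean, variance, mode).

Two networks ship with the package: a two-state incoherent-feedforward
**pulse generator** (Hill-kinetics activation and repression, rectangular
470 nM × 50 min input) and the ten-state **EGFR-IGF1R** signal-transduction
cascade whose output is the active-ERK (ERK*) trace.  The published nominal
parameter values for the EGFR-IGF1R network live in supplementary tables
and must be supplied as a `name,value` CSV; without one the model runs on
clearly labelled non-canonical placeholders.  Closed-form fixture models
(`condrobust.fixtures`) exercise the whole pipeline without an ODE solver.

## Worked example

```python
import condrobust as cr

model = cr.pulse_generator_model()
space = cr.build_parameter_space(model.nominal_parameters)   # factor-10 bounds
objectives = [
    cr.EvaluationFunction("area", "Y", "maximize"),
    cr.EvaluationFunction("maximum", "Y", "maximize"),
    cr.EvaluationFunction("time_to_maximum", "Y", "minimize"),
]
cra = cr.ConditionalRobustnessAnalysis(model, space, objectives,
                                       alpha=0.1, n_samples=2000)
print(cra.fit(seed=1).summary())
```

prints (about 4 s; N=2000 shown for speed — use the default N=10000 for
production runs):

```
Conditional Robustness Analysis
================================================
model: pulse_generator    dimensions: 6
N = 2000   alpha = 0.1   realizations = 1   seeds = [1]

objective: area(Y), maximize
  robustness (mean z): 37637
  parameter    median MIRI
  lambda       1.7195
  K2           1.1010
  k12          1.0415
  k1           0.5597
  lambda2      0.1788
  K1           0.1516
  conditioning set (k=3, maximize, source U): lambda=0.01794, K2=742.6, k12=178.9

objective: maximum(Y), maximize
  robustness (mean z): 615.935
  parameter    median MIRI
  k12          1.6897
  lambda       1.5565
  ...
```

Reading: the output-degradation rate `lambda` separates large-area from
small-area pulses most sharply (MIRI 1.72 of a possible 2), and fixing
`lambda ≈ 0.018 /min`, `K2 ≈ 743 nM`, `k12 ≈ 179 nM/min` — the modes of the
upper-tail conditional densities — retunes the circuit toward large-area
pulses.  `results.conditional()` then quantifies the shift of `f_{Z|K}`.

The same pipeline is available as a CLI:

```bash
condrobust run --model pulse_generator --n-samples 10000 --seed 0 \
    --output-dir results/pulse
```

which writes `samples.csv`, `outputs.csv`, `miri.csv`, `conditioning.json`,
`stats.json` and a `manifest.json` recording seeds and versions; reruns
with the same manifest are byte-identical.

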