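# erlangcell

Multi-stage (Erlang) birth–death models of dividing cell populations, with
generation tracking and likelihood-free calibration to CFSE-style
generation-count data.

## The problem

When lymphocytes are labelled with CFSE and transferred to lymphopenic
mice, flow cytometry later classifies each recovered cell by the number of
divisions it has completed (the dye halves at each division; divisions
beyond five blur into a single "5+" class). Plain Markov birth–death
models describe such data with exponentially distributed division times,
which badly overestimate the probability of very short division times. The
multi-stage representation keeps the Markov machinery but routes every cell
through `N` sequential exponential stages of rate `λ` before it divides, so
the division time is Erlang(`λ`, `N`) distributed, while an independent
exponential clock with rate `μ` can kill the cell at any stage.

For the stage-cycling model (daughters re-enter stage 1) the package
evaluates the exact mean solution

&nbsp;&nbsp;&nbsp;&nbsp;M_j(t) = C₀ · 2^{(1−j)/N}/N · e^{−μt} · Σ_k z^{(1−j)k} exp((2^{1/N} z^k − 1)λt),&nbsp;&nbsp; z = e^{2πi/N},

together with the late-time growth exponent σ_N = 2^{1/N} − 1 (per-capita
rate σ_N λ − μ, with N·σ_N → log 2: N quick stages are *not* one slow
step), the extinction probabilities from the first-step recursion
(p₁ = (1−r)^{−N} − 1 with r = μ/(μ+λ), or 1 when μ ≥ σ_N λ), and the
universal stationary stage occupancies P*_j = (2^{1/N})^{N−j}(2^{1/N}−1).

The generation-tracking variant (MS-G) sends daughters to stage 1 of
generation g+1 with per-generation stage counts `N_g`, birth rates `λ_g`
and the linear death law `μ_g = α·g`. It is solved in closed form where
parameters are shared, by matrix exponential in general, simulated exactly
by a compartment-aggregated Gillespie algorithm, cross-validated against a
cyton-model integrator (independent division/death clocks, progressor
fraction 1), and calibrated to generation-count tables by ABC-SMC with
AICc model comparison between the multi-stage and single-stage variants.

Intended users: modellers of lymphocyte proliferation (or any
dye-dilution / division-tracking assay) who need Erlang division times with
death, and a tested, reproducible inference pipeline for them.

## Worked example

```python
import numpy as np
import erlangcell as ec

chain = ec.StageChain.erlang(5, 0.8, 0.1, C0=100)   # N=5, lam=0.8/h, mu=0.1/h
M = ec.ms_mean_stages(chain, 100.0)
print("stage means at t=100 h:", np.round(M, 1))
print("M1/M5 =", round(M[0]/M[4], 4), " 2^(4/5) =", round(2**0.8, 4))
ext = ec.extinction_probabilities(ec.StageChain.erlang(5, 0.5, 0.1))
print("extinction (lam=0.5): certain =", ext.certain, " p =", ext.p)
```

prints

```
stage means at t=100 h: [133.2 115.9 100.9  87.9  76.5]
M1/M5 = 1.7411  2^(4/5) = 1.7411
extinction (lam=0.5): certain = True  p = [1. 1. 1. 1. 1.]
```

The stage means decay geometrically front-to-back (M₁/M₅ → 2^{4/5} — early
stages always hold more cells, which is why the growth exponent is σ_N λ
and not λ/N), and at λ = 0.5/h the death rate 0.1/h exceeds σ₅λ ≈ 0.074/h,
so extinction is certain from any starting stage.

A full synthetic calibration round trip — simulate a transfer experiment
under a known truth (4.5×10⁴ founder cells, 3 stages at 0.05/h to the
first division, then 5 stages at 0.12/h, death slope α = 2×10⁻⁴), fit the
multi-stage model by ABC-SMC at a reduced scale:

```python
ds = ec.generate_dataset(
    ec.build_schedule(C0=4.5e4, N0=3, lambda0=0.05, N=5, lam=0.12,
                      alpha=2e-4, G_max=15),
    ec.ExperimentDesign(days=(3, 4, 5, 6, 7), mice_per_day=5), seed=11)
post = ec.run_abc_smc(ds, variant="ms",
                      config=ec.ABCConfig(n_particles=200, n_iterations=8,
                                          n_prior_predictive=2000), seed=1)
print(ec.posterior_report(post).to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

```
 parameter  minimum  maximum     mean   median       sd
        C0 1.64e+04 9.35e+04 3.05e+04 2.87e+04 1.05e+04
        N0        1       48     19.2     15.6     15.7
         N        2       42     11.3        8     8.39
   lambda0   0.0218     9.28     2.26     1.41      2.2
    lambda   0.0196     1.17    0.226    0.136    0.228
     alpha 1.25e-05   0.0125  0.00105 0.000516  0.00166
N0/lambda0    0.294     94.6     16.9     9.57       18
  N/lambda     25.7      118     61.5     59.8     16.4
```

At eight SMC iterations the marginals are deliberately broad, but the
identifiable combinations are already meaningful: the derived mean division
times `N0/lambda0` and `N/lambda` (hours to first and to subsequent
divisions) and the death slope `alpha` (small — death barely matters during
lymphopenic expansion) bracket the truth. The stage count and rate are
individually soft because they trade off along an `N/λ` ridge — only their
ratio and the Erlang shape are pinned as tolerances tighten.

The same pipeline is scriptable: `erlangcell generate | fit | report`, plus
`solve` (mean-field trajectories) and `simulate` (exact realisations); see
`erlangcell --help`. Model/design configuration is one small YAML file,
data files are plain CSV (`time_h, replicate_id, generation_class,
cell_count` with the literal `5+` class).

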