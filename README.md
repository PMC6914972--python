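# fractalbench

Simulation and estimation of long-range correlated (fractal) time series,
with a cross-validation benchmark of generators against estimators.

Repeated physiological and behavioural measurements — stride intervals,
heartbeat intervals, tapping times — typically show long-range correlated,
statistically self-similar variability. Two methodological questions arise
for anyone working with such data: how to *generate* signals with a
prescribed fractal exponent (for metronomes, virtual environments,
simulation studies), and how to *estimate* the exponent of an empirical
series. Each generation method and each estimation method carries its own
biases, and evaluating one kind of method requires trusting the other.
This package implements both sides so they can be cross-validated: every
generator is run against every estimator across the full exponent range,
making it possible to attribute a bias to the generation or to the
estimation step.

## Model

Fractional Gaussian noise (fGn) and fractional Brownian motion (fBm) form a
continuum of Gaussian processes indexed by the Hurst exponent H ∈ (0, 1):
fGn is stationary with autocovariance

  γ(τ) = (σ²/2) [ (τ+1)^2H − 2τ^2H + |τ−1|^2H ],

and fBm, its cumulative sum, is self-similar with Var[B(t+Δ)−B(t)] ∝ Δ^2H.
The unified scaling exponent α ∈ (0, 2) (α = H for fGn, α = H + 1 for fBm)
is linearly related to the spectral exponent β of the 1/f^β power law
(β = 2α − 1) and to the ARFIMA fractional differencing parameter d
(α = d + ½). α = 1 is the 1/f boundary.

**Generators** — Davies–Harte circulant embedding (exact fGn: the output has
*exactly* the theoretical autocovariance), spectral synthesis (random-phase
Fourier coefficients following the 1/f^β law), and ARFIMA(0, d, 0)
simulation (truncated MA(∞) filter a_k = Γ(k+d)/(Γ(k+1)Γ(d))). fBm is
obtained by cumulative summation of fGn.

**Estimators** — evenly-spaced detrended fluctuation analysis (log-binned
fit of the fluctuation function F(n) ∝ n^α), low-frequency windowed PSD
regression (parabolic window, bridge detrending, fit restricted to the
lowest eighth of frequencies, α̂ = (β̂+1)/2), and Whittle maximum likelihood
for ARFIMA(0, d, 0) with automatic fGn/fBm classification: an optimiser
pinned at d = 0.4999 flags a nonstationary series, which is differenced,
re-estimated, and reported as d̂ = d̂_diff + 1.

The package also provides the closed-form finite-length expected lag-1
autocorrelation of discrete fBm,

  ρ(1) = 1 − N(N−1) / ( 2 Σ_{t=1}^{N−1} (N−t) t^2H ),

which explains why integrated near-white fGn (α slightly above 1) is
statistically indistinguishable from white noise — the cause of the strong
downward bias every estimator shows on circulant-embedding "fBm" near the
boundary.

## Worked example

```python
from fractalbench import (RandomStreams, generate_series, dfa_estimate,
                          psd_estimate, arfima_estimate, dh_lag1_check)

series = generate_series("ARFIMA", alpha=0.8, N=1024, rng=RandomStreams(42))
for estimate in (dfa_estimate, psd_estimate, arfima_estimate):
    r = estimate(series)
    print(f"{r.method:>6}: alpha_hat = {r.alpha_hat:.3f}   "
          f"({r.native_metric} = {r.native_estimate:.3f})")
```

```
   DFA: alpha_hat = 0.691   (alpha = 0.691)
   PSD: alpha_hat = 0.797   (beta = 0.595)
ARFIMA: alpha_hat = 0.847   (d = 0.347)
```

One persistent fGn with target α = 0.8 is generated and estimated three
ways; the spread (0.69–0.85) around the target is typical single-series
estimation error — averaged over replicates the Whittle estimate is within
about 0.01 of the target and DFA within about 0.03. The estimators are also
available as scikit-learn style classes (`DFA`, `LowPSD`, `WhittleARFIMA`)
with `fit` and fitted attributes `alpha_`, `beta_`, `d_`, …

The boundary-breakdown check:

```python
print(dh_lag1_check([0.05], n_reps=500, n=1024, seed=7).round(4).to_string(index=False))
```

```
   H    n  n_reps  expected_rho1  observed_rho1  mc_se
0.05 1024     500         0.4228         0.4092 0.0034
```

Integrated exact fGn with H = 0.05 (nominally fBm with α = 1.05) has lag-1
autocorrelation ≈ 0.41, far below the ≈ 1 of a random walk — the formula
and the simulation agree that such series are closer to noise than to
motion.

A command-line interface mirrors the library:

```
fractalbench generate --method arfima --alpha 0.8 --n 1024 --seed 42 --out series.txt
fractalbench estimate --method all --in series.txt
fractalbench benchmark --reps 120 --seed 1 --out-dir bench/
fractalbench lag1check --reps 1000 --seed 1
```

`benchmark` writes a per-(generator, estimator, α) CSV of mean/SD estimates
plus a JSON manifest that reproduces the run byte-for-byte.

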