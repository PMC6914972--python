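# Methods

## The fGn/fBm continuum and its parameterisations

The package works on the unified scaling exponent α ∈ (0, 2). A stationary
fractional Gaussian noise (fGn) with Hurst exponent H ∈ (0, 1) has α = H;
its cumulative sum, a fractional Brownian motion (fBm), has α = H + 1.
Equivalent parameterisations are the spectral exponent β = 2α − 1 ∈ (−1, 3)
of the 1/f^β power law and the ARFIMA fractional differencing parameter
d = α − ½ ∈ (−0.5, 1.5); d > 0.5 is meaningful only under the
"difference, estimate, add one" convention used for nonstationary series.
All conversions are exact linear maps and round-trip to machine precision.
The boundary α = 1 (1/f noise) is representable on the α, β and d scales
but has no H representation; conversions to an H metric at or across the
boundary raise.

## Generators

**Davies–Harte / circulant embedding** (`davies_harte_fgn`). The
unit-variance fGn autocovariance γ(0..N) is mirrored into a circulant
sequence of size M = 2N whose DFT gives nonnegative eigenvalues λ_k (checked;
tiny negative round-off above −1e−9 is clipped, anything worse is a hard
error). Spectral amplitudes are built from 2N independent Gaussian draws —
a_0 = √(λ_0/M) z, interior a_k = √(λ_k/2M)(z′ + i z″) with conjugate
mirroring, Nyquist real — and Fourier transformed; the first N points of
the (real) transform are returned. The output is Gaussian with *exactly*
the theoretical covariance at every lag below N; the tests verify this
against the closed form at H ∈ {0.1, 0.5, 0.9}, and a naive O(M²) DFT
serves as the oracle for the eigenvalue computation. The size-2N embedding
is the textbook-exact construction; output variance is exactly 1. N must be
a power of two.

**Spectral synthesis** (`ssm_series`). For f = 1..N/2, amplitudes
r(f) = W_gn(f)/f^{β/2} and phases φ = 2π W_un; coefficients r e^{iφ} are
extended by conjugate (Hermitian) mirroring, the DC term is zero (the power
law is undefined at f = 0 and the series should be zero-mean), and the
Nyquist coefficient keeps only its real part so the inverse transform is
exactly real (residual imaginary parts ~1e−16 are asserted tiny and
discarded). The expected log-periodogram slope is −β, verified by a
Monte-Carlo periodogram oracle. Any β ∈ (−1, 3), including the boundary,
is generable; N must be even.

**ARFIMA(0, d, 0)** (`arfima_fgn`). MA(∞) coefficients
a_k = Γ(k+d)/(Γ(k+1)Γ(d)) are computed by the overflow-free recurrence
a_k = a_{k−1}(k−1+d)/k and truncated at K = 100 (the convention of the
simulation literature this mirrors). N + K unit-Gaussian innovations are
convolved with the filter and the first K outputs discarded as burn-in, so
every retained point sees the full filter. The truncation loses variance
near the d boundary — at d = 0.45 the truncated filter carries only ≈ 55%
of the theoretical variance Γ(1−2d)/Γ(1−d)², versus ≈ 99.95% at d = 0.1 —
but leaves the low-frequency spectral slope, and hence exponent estimates,
essentially intact; the tests quantify this against the Γ closed form.

**Dispatch** (`generate_series`). For α < 1 the generators produce fGn
directly (DH: H = α; ARFIMA: d = α − ½); for α > 1 an fGn with H = α − 1
(d = α − 3/2) is generated and cumulatively summed. SSM synthesises any α
directly via β = 2α − 1. DH and ARFIMA cannot produce α = 1 exactly.

**Randomness.** Every series draws from one seeded PCG64 stream
(`RandomStreams`); Gaussian and uniform sub-blocks are drawn in a fixed
documented order, so a (method, α, N, seed) tuple is bit-reproducible.
Benchmark replicates derive their seeds from
`SeedSequence(master, spawn_key=(generator, α-index, replicate))`, masked
below 2³¹.

## Estimators

**Evenly-spaced DFA** (`DFA`). The profile X(t) = Σ_{i≤t}(x_i − x̄) is cut
into k = ⌊N/n⌋ non-overlapping windows taken from the start (the last
N − kn points are excluded); each window is detrended by its own OLS line
and F(n) is the RMS of the residuals over the kn retained points. F(n) is
computed for every integer n ∈ [n_min, n_max] and both n and F(n) are
averaged arithmetically within P equal-width log10 bins (half-open
intervals, last bin closed); α̂ is the OLS slope of log10 F̄ on log10 n̄
with equal bin weights. Defaults n_min = 10, P = 18, and n_max = min(512,
N/2) — the canonical 512 for the reference length N = 1024, adapting for
shorter series. The classical unbinned variant is available via
`evenly_spaced=False` for comparison. Perfectly detrendable profiles
(F(n) = 0, e.g. constant input) and empty bins raise rather than producing
−∞ slopes. Windows are forward-only and detrending is linear (order 1).

**Low-frequency windowed PSD** (`LowPSD`). Preprocessing: mean removal;
parabolic window W(t) = 1 − (2t/(N+1) − 1)² for t = 1..N; bridge detrending
by the straight line through the first and last windowed values (endpoints
exactly zero afterwards). The periodogram is taken at Fourier frequencies
j/N, j = 1..⌊(N−1)/2⌋ (DC and Nyquist excluded; normalisation is
irrelevant to slopes and is pinned only by a Parseval test). β̂ is minus
the OLS slope of log power on log frequency over f ≤ f_Nyquist/8 (64
frequencies at N = 1024; at least 8 required), and α̂ = (β̂+1)/2.

**Whittle ARFIMA** (`WhittleARFIMA`). The concentrated Whittle criterion
L(d) = log σ̂²(d) + (1/m) Σ log g_d(λ_j), with g_d(λ) = (2 sin(λ/2))^{−2d}
and σ̂²(d) = (1/m) Σ I_j/g_d(λ_j), is minimised over d ∈ [−0.4999, 0.4999]
by bounded scalar minimisation (absolute tolerance 1e−6). Because a bounded
optimiser never lands exactly on a bound, the objective is also evaluated
at both bounds and the estimate snaps to a bound that beats the interior
optimum; this makes the boundary rule deterministic. A minimiser at the
upper bound classifies the series as fBm: it is differenced, re-estimated,
and d̂ = d̂_diff + 1 is reported (an out-of-range error if the differenced
estimate is still at the bound). α̂ = d̂ + ½. The criterion is invariant to
rescaling the periodogram, and a 1e−4 grid search is the oracle for the
optimiser.

All three estimators are invariant to adding a constant and to positive
rescaling of the input, and are exposed both as scikit-learn style
estimator classes and as plain functions returning an `EstimateResult`.

## The benchmark and what it emulates

`run_grid` runs every requested generator at every α of the grid — by
default 0.1..0.9 and 1.1..1.9 in steps of 0.1 plus 0.91..0.99 and
1.01..1.09 in steps of 0.01 (36 values; α = 1 excluded) — for R replicates
of length N, and applies every requested estimator to the *same* replicate
series (paired design, so estimator contrasts within a cell are not
confounded by generation noise). Defaults R = 120 and N = 1024 are the
reference study conditions; the test suite and the acceptance script run
reduced replication (R = 40 for mean-bias cells, R = 120 where a standard
deviation ordering is compared, 1000 replicates for the covariance and
lag-1 Monte-Carlo checks), chosen so every asserted effect is several
standard errors wide at those sizes. Replicates on which any step raises
are excluded and counted; a cell losing more than 5% of replicates fails
the run. Failed replicates are never imputed.

The generated data are idealised in ways real physiological series are
not: Gaussian, exactly stationary (or exact cumulative sums), free of
trends, artefacts, short-range (AR/MA) contamination, and measurement
noise. Passing benchmarks therefore demonstrates correctness of the
methods on their own model class, not robustness to empirical
contaminants.

## The finite-length fBm lag-1 autocorrelation

For a length-N discrete fBm the expected lag-1 autocorrelation is

  ρ(1) = 1 − N(N−1) / (2 Σ_{t=1}^{N−1} (N−t) t^{2H}).

Algebraically this is the ratio of expectations of the mean-removed sample
lag-1 autocovariance and sample variance; it reduces to 1 − 3/(N+1) at
H = ½ and tends to 0 as H → 0 — integrated near-white fGn *is*
statistically white, which is why every estimator reads circulant-embedding
series with α slightly above 1 as α ≈ 0.5–0.8 (the "boundary disruption").
Only lag 1 is implemented; N ≥ 16 is required. Empirical checks use the
mean-removed, biased (divide by N) sample autocorrelation. Note that the
*mean of the sample ratio* differs from this ratio-of-expectations by a
small finite-sample (Jensen) offset — about 0.004 at H = 0.5 and 0.02 at
H = 0.1 for N = 1024 — which no amount of replication removes; agreement
checks therefore use an absolute band of 0.02 in the low-H regime rather
than Monte-Carlo standard errors.

## Group comparison helper

`compare_groups` performs a two-group one-way ANOVA (df1 = 1,
df2 = n_a + n_b − 2) and reports partial η² = F·df1/(F·df1 + df2). The
identity is exercised against the published stride-interval study's printed
F(1, 43) statistics, which reproduce the printed effect sizes 0.179, 0.044
and 0.318 to three decimals. Zero within-group variance with equal means
(F undefined) raises; with unequal means it reports an infinite F and
η² = 1.

## Numerical conventions and degenerate inputs

- Series must be finite, one-dimensional, length ≥ 2; constant series are
  rejected wherever an estimate would be undefined.
- Circulant eigenvalues below −1e−9 abort generation (invalid covariance);
  smaller negatives are clipped to zero.
- Log-log fits use base-10 logarithms throughout (slopes are base
  invariant; a test asserts the estimate is unchanged under rescaling).
- Bin membership is half-open [lo, hi) with the last bin closed, so every
  integer window size belongs to exactly one bin.
- Whittle frequencies exclude DC and Nyquist; the boundary-hit threshold is
  0.4999 − 1e−6.

## Known limitations

- Only ARFIMA(0, d, 0) likelihoods and simulations; AR and MA components
  are out of scope, as are model-selection procedures for detecting genuine
  long-range correlation.
- Exact fBm is obtained only by integrating exact fGn (no Cholesky/Hosking
  generators).
- The DH generator requires power-of-two lengths; SSM requires even
  lengths.
- The evenly-spaced DFA fit carries a small negative bias (~0.02 at
  α = 0.5, N = 1024) from the noisy large-window bins entering the log fit;
  this is a property of the prescribed procedure, not of the
  implementation, and is well inside the recovery tolerances asserted in
  the tests.
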