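# Methods

This note records the models implemented by `timescale-reservoir`, the
numerical choices behind them, and what the synthetic benchmarks do and do
not establish.

## Rate network (`rate`)

Units obey `τ_i dx_i/dt = -x_i + s_i φ(x_i) + g Σ_j J_ij φ(x_j) + I_i(t)`
with `φ = tanh`, couplings i.i.d. `N(0, 1/N)` and zero diagonal (the
self-interaction enters only through `s_i`; drawing diagonal entries from
the same `1/N`-variance law would change nothing at leading order, zeroing
them is the cleaner convention).  Time is in units of the membrane time
constant; 1 unit = 3 ms when results are reported in milliseconds
(configurable).  Per-unit `τ_i` support the control experiment in which
heterogeneous *membrane* time constants, rather than heterogeneous
self-couplings, are tested as a timescale mechanism.

*Integration.* Explicit Euler.  Default `dt = 0.05`; `dt = 0.01` for the
headline timescale measurement.  Halving `dt` from 0.05 changes the
population HWHM by under 2% in the regimes studied, so the scheme's bias
is well below the sampling error of the statistics computed on top.
Initial conditions default to i.i.d. uniform on [-1, 1] (seeded);
trajectories carry a burn-in marker (default: the larger of 20% of the
duration and 50 time units, capped at half the duration) that every
statistic respects.

*Discrete self-coupling sampling* uses largest-remainder apportionment so
the realized composition matches the requested fractions exactly, then
shuffles unit order by seed.

*White-noise probes.* A probe driven by white noise of "equivalent
strength" to a colored noise with integrated autocorrelation D receives
Euler increments of variance `g² · 2D · dt`, so the injected input has the
same integrated autocorrelation `g² D`.

## Dynamic mean-field theory (`dmft`)

The self-consistency `C(τ) = Σ_α n_α ⟨φ(x_α(t)) φ(x_α(t+τ))⟩` with
`⟨η η⟩ = g² C` is solved by iteration: stationary Gaussian paths with the
current `C` are synthesized spectrally (negative periodogram values of the
iterate are clipped to zero — iterates need not be valid autocorrelations),
the single-unit equations are integrated against them (three sweeps of the
periodic path; the last is recorded, so the series is stationary), and `C`
is re-estimated.

*Damping and convergence.*  The map is applied undamped for 20 warm-up
iterations — long enough for the slow regimes (two-population chaotic
states) to reach the fixed point, which a short-memory average would lock
out — and the estimate is then the cumulative mean of at least 20 further
iterations; convergence is declared when the normalized estimate changes
by less than 1e-2 in sup norm.  A response-step check (feeding a
simulation-measured C through one iteration) confirms the fixed point: at
N=2000 the converged per-population autocorrelations match direct network
simulation within ~4% sup-norm after normalization.

*Defaults.* Path length 1200 time units at `dt = 0.02`, 40 units per
self-coupling value.  Continuous distributions are handled by drawing
fresh self-couplings each iteration on a doubling schedule
(8 → 512) and weighting each draw 1/n.  Per-self-coupling autocorrelations
(`per_s`) are evaluated against the converged mean field with per-unit
means removed, so the conditional HWHM reflects fluctuations rather than
the window-dependent well-occupancy plateau of bistable units.

*Noise strength.* `D = ∫₀^∞ C dτ`, integrated to the first zero crossing
of the converged estimate (beyond it the tail is sampling noise);
`τ₁` is the HWHM of C.  For the marginal network (all s = 1, g = 1.5)
the solver yields `τ₁ ≈ 6.8–7.0` and `D ≈ 6.6`, with direct N=1000
simulations giving HWHM estimates of 7.1–7.5 depending on window length —
the mean-field value sits at the lower edge of the finite-N simulation
range.

*Statics and stability.* Fixed points solve `x_α - s_α tanh x_α = η` with
`⟨η²⟩ = g² C`, `C = Σ n_α ⟨tanh² x_α⟩` (Gauss–Hermite quadrature, 201
nodes).  The `most_stable` branch takes, for `s_α > 1`, the outer root
whose sign matches η (the larger-|x| choice); outer roots satisfy
`cosh² x > s`, so `q_α = (s_α - cosh² x_α)²` is bounded away from zero on
that branch and the stability expectation `g² Σ n_α ⟨1/q_α⟩` is finite
(fold-touching samples on other branch policies are excluded from the
quadrature with weight renormalization).  A configuration is chaotic when
the most stable fixed point violates `g² Σ n_α ⟨1/q_α⟩ ≤ 1`; phase
boundaries are located by bisection along parameter-grid lines.  For the
degenerate zero-self-coupling network this reproduces the classic
transition at `g = 1` to machine precision of the bisection.

## Colored-noise escape theory (`ucna`)

A slow probe `dx/dt = f(x) + η`, `f = -x + s tanh x`, driven by colored
noise of strength D and color τ₁ has the stationary law
`p(x) = Z⁻¹ |h(x)| exp(-U_eff/D)` on the support `|x| > x_c` where
`h = 1 - τ₁ f′ > 0`, `tanh² x_c = 1 - (1+τ₁)/(τ₁ s)` and
`U_eff = x²/2 - s log cosh x + (τ₁/2) f² - U_min` (normalized so the
well minimum is zero).  Well centers are located by root finding on
`x = s tanh x`, never by the large-s approximation `±s`.

*Conventions.*  D is the integrated autocorrelation `∫₀^∞ C dτ` of the
*population* autocorrelation and τ₁ its HWHM.  Both the `(D, τ₁)` pairing
and the alternative with the mean-field gain factor folded in were
implemented and compared against simulated probe dwell times; the adopted
pairing reproduces the simulated mean dwell within ~10% at s = 4 (the
alternative is several-fold too fast) and within a factor ~3 at s = 5,
where the closure overestimates the dwell.  The white-noise limit τ₁ = 0
recovers the naive potential and a Gaussian stationary law.

*Mean first-passage time.*  Three estimators:

- `integral`: `⟨T⟩ = (1/D) ∫_{x₋}^{-x_c} |h| e^{U_eff/D} [∫_{-∞}^{x} p] dx`
  with the inner cumulative integral tabulated on 4001 points and the
  outer integral by adaptive quadrature (the normalization constants of
  the two factors cancel).
- `steepest`: Laplace evaluation of both integrals,
  `⟨T⟩ ≈ 2π |h(x₋)| / sqrt(U_eff″(x₋) |ρ″(x_f)|) · exp(Δ/D)` with
  `ρ = U_eff + D log|h|`, `Δ = ρ(x_f) - U_eff(x₋)`, and `x_f` located
  numerically as the maximizer of ρ between the well and the support edge
  (the `tanh² x_f ≈ 1 - 1/2s` approximation serves only as a bracket).
  The `|h(x₋)| ≈ 1 + τ₁` prefactor comes from evaluating the density at
  the well bottom; without it the estimate is low by that factor.  With
  it, steepest and integral agree to within ~1% in log⟨T⟩ for
  s ∈ {5, 6, 7} at the mean-field noise parameters.
- `asymptotic`: `log⟨T⟩ ≈ (τ₁+1)/(2D) · (s² - s log s)`, the large-s
  exponent; regressing the integral log⟨T⟩ on `(s² - s log s)/2D` over
  s ∈ [8, 14] recovers a slope within ~12% of `τ₁ + 1` (the bias shrinks
  as s grows; at s ∈ {5, 6, 7} it is still ~25%, which is why the slope
  check runs in the asymptotic range).

*Dwell measurement convention.*  Switches are detected with hysteresis:
a state change requires crossing the opposite threshold (±½x* for raw
probes, ±x_c when a UCNA model supplies the support edge); incomplete
first/last dwells are discarded.

## Timescale and spectral statistics (`stats`)

- Autocorrelation: FFT-based unbiased time average, per-unit mean removed
  by default (without it the HWHM of signals with a baseline is
  ill-defined; a degenerate flag marks constant inputs), averaged over a
  unit subset.
- HWHM: first crossing of C(0)/2, linearly interpolated between lag
  samples; a truncation flag is set when the half level is never reached
  within the lag window.  `convert_decay_to_hwhm` multiplies exponential
  decay constants by ln 2.
- PSD: Hann-windowed Welch estimator, ~8 segments at 50% overlap, density
  scaling — integrated power matches the signal variance within 1%.
  Spectra are computed on x by default (configurable to φ(x)).
- Modulation index `m(f) = (P₂-P₁)/(P₂+P₁)` from per-population spectral
  peaks read at the nearest frequency bins; the crossover frequency is the
  sign change of m interpolated linearly in (log f, m); entries with zero
  total power are flagged undefined.
- Lognormal timescale fits are maximum likelihood on log-timescales with a
  Kolmogorov–Smirnov distance as goodness measure.

## Clustered spiking network (`spiking`)

Current-based LIF neurons (τ_m = 20 ms, τ_s = 5 ms, τ_refr = 5 ms,
V_reset = 0), N neurons split 80/20 into E and I, Erdős–Rényi
connectivity (p_EE = 0.2, others 0.5), and paired E/I assemblies: E sizes
uniform with mean 60 + N/100 and 30% SD (the rounding remainder is spread
one neuron at a time across the largest assemblies so sizes stay inside
the drawn range), I sizes a quarter of their E partners, 10% of each
population unclustered.  Intra-assembly weights are potentiated
(J⁺_EE = 14, J⁺_II = 5, with the E-I factors derived from
g_EI = 10, g_IE = 8 via J⁺ = p/(1 + (p-1)/g); all four scale linearly in
N/2000), inter-assembly weights depressed by
`J⁻_αα = 1 - γ(J⁺_αα - 1)`, `γ = f(2 - f(p+1))`, `J⁻ = J⁺/g` for the
mixed pairs; background connections carry unit factor.

*Weight scale.*  Synaptic magnitudes are `j / sqrt(2N)` mV with table
values j_EE = j_IE = 0.9, j_EI = 2.7, j_II = 5.4, j_E0 = 3.7, j_I0 = 3.3.
This scale is pinned by the balanced state itself: with it, inverting the
mean-field transfer for target rates (2, 5) spk/s returns thresholds
(1.434, 0.744) mV — the defaults (1.43, 0.74) to within 5 μV — whereas
other conventional scalings miss by large factors.  External drive is the
constant current `I_ext = N_ext J_α0 r_ext`, `N_ext = n_E N p_EE`
(no variance contribution).

*Simulation.*  Clock-driven forward Euler (`dt = 0.05 ms` default) in a
numba kernel; a spike increments its targets' synaptic currents by
`J/τ_s` at the next step (exponential kernel of unit integral), and the
membrane is clamped for τ_refr.  Against the deterministic
suprathreshold closed form the simulated rate agrees within 2%.

*Mean-field transfer.*  `F = [τ_refr + τ_m √π ∫_H^Θ erfcx(-u) du]⁻¹`
(the identity `e^{u²}(1+erf u) = erfcx(-u)` keeps both tails stable;
far-subthreshold inputs return 0 rather than overflowing), with
`H, Θ = (V_reset/thr - μ)/σ + a k`, the synaptic-filtering shift
`k = sqrt(τ_s/τ_m)` and `a = |ζ(½)|/√2 ≈ 1.0326` (the `|ζ(½)|/2` reading
remains available as a config switch).  σ here follows the input
convention: `σ² = τ_m Σ_pre N p J² r`, i.e. √2 times the stationary
membrane dispersion.  The two-population fixed point is solved by damped
iteration plus a root polish; threshold calibration inverts the transfer
per population (μ and σ depend only on the target rates).

*Assembly statistics.*  The effective self-coupling of assembly i is
`s_i = C_i^E p_EE J_EE J⁺_EE` (mV); an empirical variant averages the
realized intra-assembly weights instead and agrees within 10%.  Assembly
activations binarize the 25-ms-binned population rate at the midpoint of
its 10th and 90th percentiles (assemblies without bimodal separation are
flagged and excluded); activation intervals touching the epoch edges are
kept, so the longest dwells are censored at the epoch length — at the
desk scale used here (N = 2000, 20 s epochs) the largest assemblies
saturate the epoch, which compresses the top of the log T vs s curve.

*Model selection.*  Polynomial degrees for log T vs s are compared by
split-half cross-validation repeated over 25 random splits, selecting the
smallest degree within one standard error of the minimal averaged test
MSE (a single split cannot distinguish nested models on this noise
level).  On dwell data generated by the bistable-probe pipeline over
s ∈ [2.5, 5] the procedure selects degree 2 with positive curvature; on
the N=2000/20 s spiking data the curvature term is masked by epoch
censoring and degree 1 is typically selected, with the pooled quadratic
coefficient still positive.

*Reduced matrix.*  The (2p+2)-population matrix `J_MF[A,B] = N_B ×
mean(W[A,B])` (E clusters, E background, I clusters, I background) has a
spectrum contained in that of the block-averaged full matrix by
construction.  Its Schur basis is built by QR-orthonormalizing the
eigenvectors in descending order of eigenvalue real part; the leading
p-1 modes map to E/I cluster pairs by maximal loading, and their order
tracks assembly size.

## Experiments and synthetic data (`experiments`)

Six pipelines (two-population phase, lognormal reservoir, bistable probe,
clustered spiking, broadband de-mixing, heterogeneous-τ control) are
driven by a YAML-serializable config carrying an experiment name, a seed,
a scale factor (multiplying sizes, durations, and realization counts) and
parameter overrides; every stochastic step receives a seed derived from
the config seed, and a JSON manifest makes each run bitwise reproducible.

The synthetic timescale generator draws lognormal samples in ms
(defaults μ = 5.15, σ = 1.23, chosen so the 1st–99th percentiles span
roughly 10 ms to 3 s, the range reported for cortical populations); it is
tagged `synthetic` and stands in for recorded datasets in the
distribution-fitting pipeline, which also accepts a user-supplied CSV.
Passing fits on synthetic data show the estimator recovers lognormal
parameters; they say nothing about whether any particular recorded
population is lognormal.

What the synthetic benchmarks do not cover: real spike trains' refractory
and rate nonstationarities beyond the model's own, finite-duration bias
in the longest timescales (epoch censoring above), and any claim about
the anatomical identity of assemblies.

## Scales used in the shipped checks

Test-suite and acceptance runs use N = 1000–2000 rate units, mean-field
paths of 600–1200 time units, spiking networks of N = 2000 for 20 s, and
5–10 realizations per condition — sizes chosen so the full suite runs on
a single CPU in minutes while keeping every qualitative regime (chaotic
phase, bistable switching, metastable assemblies, crossover of the
modulation index) well inside its detectable range.  The known cost is
wider sampling error on slow-dwell statistics and censoring of the
longest assembly activations; both are discussed where they matter.

## Known limitations

- The colored-noise closure overestimates the probe dwell time at s = 5
  by a factor ~3 under the adopted conventions (exact at s = 4); the
  discrepancy is documented in the tests rather than hidden by retuning D.
- The iterative mean-field solver assumes a chaotic (time-varying)
  regime; in fixed-point regimes it returns a near-zero C rather than
  diagnosing stability (use the static solver for that).
- No synaptic delays, conductance synapses, plasticity, or adaptation.
- The spiking mean field covers the homogeneous network; the clustered
  fixed-point hierarchy is probed by simulation, not solved analytically.
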