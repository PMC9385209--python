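# Methods

## Population model

A growing culture is described by counts of template (N_T), synthesizing
(N_S) and post-replication (N_P) genomes with linear dynamics: fork firing at
rate k per genome creates synthesizing genomes, completion at rate β converts
them to post-replication genomes, division at rate α converts those to
templates. In steady exponential growth the total grows at rate k and the
type fractions are constant (f_S = k/(k+β), etc.). k therefore doubles as
"fork firing rate" and "population growth rate" and is always measured from
optical density, never fitted. α cannot be identified from coverage at all;
functions that need it (DNA content per cell) take it as user input.

The ODE integrator is classical fixed-step RK4 with the step clipped to
1/(10·max rate); the system is linear, so this is exact to rounding for every
use in the package.

## Fork dynamics and the abundance forward map

A fork pair is a point (x1, x2) in the triangle x1 + x2 ≤ L, drifting at
v(x) = v̄[1 + δ cos(ωx + φ)] per coordinate with diffusion D, absorbed on the
completion line, and reset to the origin at rate k (the dilution of an
exponentially growing population, implemented as stochastic resetting). The
stationary density p_st and completion rate β give the contains-probability

    P(y) = k/(k+β) · [mass of p_st in which the fork on the y arm has passed
           |y|, symmetrized] + β/(k+β),

with P(0) = 1 by construction, and A(y) = P(y)/∫P. Special cases used as
oracles throughout: constant speed and D = 0 give a diagonal p_st with an
exponential profile, β = k e^{-c}/(1-e^{-c}) with c = kL/(2v̄), and
P(y) = e^{-k|y|/v̄}; position-dependent speed with D = 0 gives
P(y) = exp(-k·T(|y|)), T(x) = ∫ dx'/v(x'), because the fork schedule is then
deterministic and the incomplete-genome age distribution is exponential.

Numerics: P is held on a uniform "arm grid" of |y| (250 bp by default,
1000 bp inside the fitting hot loop); T(x) is a composite-trapezoid
cumulative on that grid (exact for constant speed; relative error
~(k·h/v̄)²/12 ≈ 1e-9 otherwise). Per-bin read fractions are differences of a
trapezoid cumulative along the linear coordinate on a fixed 500-bp lattice
augmented with all bin edges and the two |y| kink points, which makes
re-binning exactly additive. The constant-speed fork density keeps its exact
diagonal representation alongside the 2-D histogram so the analytic round
trip (p_st → P → A) agrees with the closed form to better than 1e-8 per bin.

## Simulator

Trajectories advance with a midpoint-rule drift step (plain Euler drift
leaves an O(dt) distortion of the occupation density that is visible against
the exact D = 0 profile at default resolution) plus Euler–Maruyama noise of
variance 2D·dt; x = 0 is reflecting; absorption is detected by x1 + x2 ≥ L
after a step without overshoot interpolation; Poisson resetting uses the
exact per-step probability 1 − e^{-k·dt}. The default time step is
cell/(5·v_max) for histogram cells of 50 kbp (both configurable), and the
default burn-in is 4/k + L/v̄: relaxation to the stationary resetting law is
governed by the dilution rate k, not by the completion time, and a
synchronized start decays only as e^{-kt}. β is estimated as absorptions per
trajectory-time after burn-in; its standard error is β/√(events). All runs
require an explicit seed and are bit-reproducible.

## Likelihood, bias correction and model selection

Reads are modelled as one multinomial draw over unmasked 10-kbp bins with
probabilities equal to the model's bin fractions (renormalized over the same
mask as the data). This sampling model is an assumption of the package, made
because it is the natural read-counting noise model.

Coverage bias (GC, mappability, library chemistry) is taken as multiplicative
and shared between exponential and stationary phases, so each exponential bin
frequency is divided by the matching stationary frequency; bins with zero (or
below-threshold) stationary signal are masked, with no pseudocounts. The
corrected curve is rescaled to pseudo-counts carrying the effective depth of
a ratio estimator, N_eff = (1/N_exp + 1/N_stat)^{-1}, because both phases
contribute counting noise; without this the multinomial likelihood is about
2× overdispersed and every likelihood-ratio or AIC comparison is inflated.
Per-bin dispersion still varies around this global calibration — a known
residual approximation.

The constant-speed model has one free parameter (v̄; k and v̄ enter only
through k/v̄) and is fitted by bounded 1-D search in log v̄. The oscillatory
model (v̄, δ, ω, φ) is fitted by Nelder–Mead from several starts: a
least-squares scan of the log-residuals against the constant fit over
ω ∈ 0.5–8 rad/Mbp localizes candidate frequencies (for small δ the
log-abundance deviation is (kδ/v̄ω)[sin(ω|y|+φ) − sin φ]), and the top
candidates seed (δ, ω, φ). Fits are bounded to δ ∈ [0, 0.95) and
ω ∈ [0.4, 10] rad/Mbp; the lower ω bound is an identifiability cut —
oscillation periods several times the arm length are degenerate with a
rescaled constant model. φ is reported wrapped to [0, 2π).

Model choice is minimum AIC (2p − 2 ln L). A caveat this package measures and
documents: because the oscillatory fit maximizes over a continuum of
candidate frequencies, the null distribution of its likelihood gain is
heavier than the χ²₃ scale AIC assumes; on oscillation-free synthetic data
the oscillatory model is falsely preferred in roughly a third of datasets.
AIC is therefore decisive only when the gap is large — which it is, by
2–3 orders of magnitude, for the oscillation amplitudes the method is
designed to detect (ΔAIC ≈ 400 at δ = 0.17 and 5×10⁶ reads).

Diffusion is not fitted jointly: with allow_diffusion the (v̄, δ, ω, φ) fit
is kept and D is profiled over a grid with a common-random-number simulation
likelihood (the D = 0 grid member is also evaluated by simulation so the
comparison is like-for-like); D is reported as significant only if it
improves AIC by ≥ 2.

## Growth and temperature analysis

Each replicate OD curve is fitted with a logistic a/(1 + b e^{-kt}) by
nonlinear least squares (initial values from the plateau and the early
log-linear slope); the per-temperature k is the replicate mean. Temperature
dependence of any positive rate or speed is summarized by an unweighted
least-squares Arrhenius fit of ln(value) on 1/(R·T), T in kelvin
(T[K] = T[°C] + 273.15 exactly), with the activation energy in kJ/mol; an
off-trend temperature (e.g. the coldest point) can be excluded by label.

## Synthetic data and what passing tests show

The generator emulates the paired sequencing design: exponential-phase reads
are multinomial over normalize(A_bin × bias) and stationary reads over
normalize(bias), with a shared log-normal per-bin bias (σ = 0.2 by default) —
so stationary division cancels the bias exactly in expectation. Defaults
match the study conditions the inference is calibrated against: full
4,641,652-bp circular genome (origin at 3,925,744 bp on the linear reference
— a configurable annotation convention), 10-kbp bins (465), 5×10⁶ reads per
phase. A 200-kbp mini-geometry is used in tests where full scale adds nothing.

Reference parameter sets (presets) give the oscillatory-speed parameters at
17/22/27/32/37 °C with their replicate standard deviations. Growth rates per
temperature are fixed as doubling times: 1500 s (37 °C) and 4000 s (22 °C)
as defined by the recovery protocol; 3100 s and 1900 s for 27/32 °C from the
growth Arrhenius law (B = 6.0×10¹² hr⁻¹, 74 kJ/mol); and 10800 s for 17 °C,
which sits off that law and below the multi-fork threshold (kL/2v̄ < ln 2).

What the closure tests demonstrate: the inference recovers parameters from
data generated by the package's own forward model with multinomial noise and
multiplicative shared bias. Real coverage additionally contains
origin-firing asynchrony, fork stalling and restart, copy-number variants,
phase-dependent bias, and imperfect exponential growth — none of which are
modelled, so passing tests bound estimator correctness, not robustness to
those effects.

## Known limitations

- Asymmetric fork dynamics (different speed profiles for the two arms) are
  out of scope; p_st is symmetrized on input.
- The D > 0 likelihood is simulation-based and noisy; only a grid profile
  with a significance threshold is offered, not joint optimization.
- The multinomial/N_eff calibration is first-order; per-bin overdispersion
  from bias heterogeneity is not modelled.
- Stationary-phase references are assumed replication-free; residual
  replication in stationary samples would bias the corrected profile.
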