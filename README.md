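# forkspeed

Infer bacterial replisome dynamics — mean speed, speed oscillations along the
genome, and positional diffusion — from the DNA abundance distribution of an
exponentially growing population.

## The problem

In a steadily growing bacterial culture, many chromosomes are caught
mid-replication. Because every genome contains the replication origin but only
complete genomes contain the terminus, sequencing coverage decays from origin
to terminus, and the *shape* of that decay encodes how the replication forks
move. `forkspeed` turns binned read coverage (marker-frequency analysis) into
quantitative estimates of replisome behaviour. It is aimed at microbial
genomicists and biophysicists who have exponential-phase and stationary-phase
sequencing of the same strain.

## The model

Genomes are of three types — templates, synthesizing, post-replication — with
fork firing at rate *k* (equal to the population growth rate), completion at
rate *β*, and division at rate *α*. Each fork pair starts at the origin
(*x*₁ = *x*₂ = 0) and advances by

  d*x*/d*t* = *v*(*x*) + √(2*D*) ξ(*t*),  *v*(*x*) = v̄ [1 + δ cos(ω*x* + φ)],

meeting when *x*₁ + *x*₂ = *L*. The probability that a random genome contains
position *y* (distance from the origin along the circle) is

  P(*y*) = k/(k+β) · Pr[covered | incomplete] + β/(k+β),

and the DNA abundance distribution is A(*y*) = P(*y*) / ∫P. For constant speed
and *D* = 0, P(*y*) = e^(−k|y|/v̄) exactly; for position-dependent speed with
*D* = 0, P(*y*) = exp(−k T(|y|)) with T(*x*) = ∫₀ˣ d*x*′/*v*(*x*′); for
*D* > 0 a stochastic-resetting simulation supplies the fork distribution.
Fitting is by multinomial maximum likelihood over 10-kbp bins with *k* fixed
from growth curves; constant vs oscillatory speed is decided by AIC. Derived
physiology: mean genome length ℓ = 1/A(0), replisomes per complete genome
N = 2k/β = 2[A(0) − A(L/2)]/A(L/2), DNA content per cell, and the fork
meeting-region width l_D ≈ 2√(2D·L/2v̄).

## Worked example

`examples/fit_synthetic_coverage.py` generates 5×10⁶ reads from a known
oscillatory-speed truth (fast growth, 25-min doubling), removes the shared
per-bin bias with a stationary reference, and refits:

```
ground truth : vbar=970.0  delta=0.170  omega=4.30 rad/Mbp  phi=3.00 rad
oscillatory  : vbar=968.9  delta=0.181  omega=4.42 rad/Mbp  phi=2.93 rad
constant     : vbar=960.0

 model_kind  n_params        loglik          aic  delta_aic
   constant         1 -1.522641e+07 3.045281e+07 412.915933
oscillatory         4 -1.522620e+07 3.045240e+07   0.000000

selected model: oscillatory
```

The fitted mean speed is within 0.2% of truth; the ~17% speed wave is
detected and the AIC gap (~413) makes the model choice unambiguous. Other
examples cover the forward abundance model (`abundance_profile.py`), the
stochastic fork simulator against its closed-form oracle
(`simulate_forks.py`), growth-rate and Arrhenius analysis
(`growth_rates.py`), and cosine fits/correlations of genomic profiles
(`speed_mutation_correlation.py`).

A thin CLI mirrors the library: `forkspeed synth|simulate|abundance|fit|growth|report`.

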