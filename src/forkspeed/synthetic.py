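"""Synthetic coverage and growth-curve generation with known ground truth.

Emulates the paired sequencing design the inference expects: reads from an
exponentially growing culture are multinomial over bins with probabilities
proportional to (model abundance × per-bin bias), and reads from a stationary
culture (all genomes complete, uniform abundance) are multinomial over the
bias alone. The bias is multiplicative and shared between the two phases, so
stationary division cancels it exactly in expectation — precisely the
assumption behind the bias-correction step. Default bias: log-normal with
sigma = 0.2 per bin.

Every generator takes an explicit seed and returns the full ground-truth
record, so the whole pipeline can be exercised end-to-end with no external
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .abundance import abundance_varspeed_D0
from .coverage import CoverageTrack
from .geometry import GenomeGeometry
from .growth import GrowthCurve
from .model import ReplisomeModel

__all__ = ["SyntheticSpec", "generate_coverage", "generate_od"]


@dataclass
class SyntheticSpec:
    """Ground truth for one synthetic exponential/stationary track pair."""

    geometry: GenomeGeometry
    model: ReplisomeModel
    k: float
    n_reads_exponential: int = 5_000_000
    n_reads_stationary: int = 5_000_000
    bias_sd: float = 0.2
    bias_profile: np.ndarray | None = None
    seed: object = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.n_reads_exponential <= 0 or self.n_reads_stationary <= 0:
            raise ValueError("read counts must be positive")
        if self.bias_sd < 0:
            raise ValueError("bias_sd must be >= 0")
        if self.bias_profile is not None:
            self.bias_profile = np.asarray(self.bias_profile, dtype=float)
            if self.bias_profile.shape != (self.geometry.n_bins,):
                raise ValueError("bias_profile must have one entry per bin")
            if np.any(self.bias_profile <= 0):
                raise ValueError("bias multipliers must be positive")


def generate_coverage(
    spec: SyntheticSpec,
) -> tuple[CoverageTrack, CoverageTrack, dict]:
    """Draw one exponential and one stationary track plus the truth record.

    The exponential track is multinomial(n, normalize(A_bin × bias)); the
    stationary track is multinomial(n, normalize(bias)). The truth record
    holds every generating parameter, the bias vector and the seed.
    Diffusive ground truth is not supported on this analytic path — simulate
    the fork distribution explicitly for that.
    """
    if spec.model.diffusion != 0:
        raise ValueError(
            "generate_coverage draws from the D = 0 abundance; use "
            "simulate_stationary + probability_contains for D > 0 truth"
        )
    rng = np.random.default_rng(spec.seed)
    n_bins = spec.geometry.n_bins
    if spec.bias_profile is not None:
        bias = spec.bias_profile
    elif spec.bias_sd > 0:
        bias = rng.lognormal(mean=0.0, sigma=spec.bias_sd, size=n_bins)
    else:
        bias = np.ones(n_bins)

    profile = abundance_varspeed_D0(spec.geometry, spec.model, spec.k)
    a_bin = profile.bin_fractions()
    p_exp = a_bin * bias
    p_exp /= p_exp.sum()
    p_stat = bias / bias.sum()

    exp_counts = rng.multinomial(spec.n_reads_exponential, p_exp)
    stat_counts = rng.multinomial(spec.n_reads_stationary, p_stat)
    exponential = CoverageTrack(
        spec.geometry, exp_counts, phase="exponential", replicate_id="synthetic-exp"
    )
    stationary = CoverageTrack(
        spec.geometry, stat_counts, phase="stationary", replicate_id="synthetic-stat"
    )
    truth = {
        "vbar": spec.model.vbar,
        "delta": spec.model.delta,
        "omega_per_mbp": spec.model.omega_per_mbp,
        "phi": spec.model.phi,
        "diffusion_kbp2": spec.model.diffusion_kbp2,
        "k": spec.k,
        "n_reads_exponential": spec.n_reads_exponential,
        "n_reads_stationary": spec.n_reads_stationary,
        "bias_sd": spec.bias_sd,
        "bias": bias,
        "seed": spec.seed,
        "abundance_fractions": a_bin,
    }
    return exponential, stationary, truth


def generate_od(
    a: float,
    b: float,
    k: float,
    times,
    noise_sd: float = 0.0,
    seed=None,
    temperature: float | None = None,
    replicate_id: str = "",
) -> GrowthCurve:
    """Logistic optical-density curve a/(1 + b e^{-kt}) with multiplicative noise."""
    if min(a, b, k) <= 0:
        raise ValueError("a, b and k must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = np.asarray(times, dtype=float)
    od = a / (1.0 + b * np.exp(-k * times))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od * (1.0 + rng.normal(0.0, noise_sd, size=od.shape))
        od = np.clip(od, 1e-12, None)
    return GrowthCurve(times=times, od=od, temperature=temperature,
                       replicate_id=replicate_id)
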