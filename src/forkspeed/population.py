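"""Genome-type bookkeeping for an exponentially growing population.

Each cell carries exactly one template genome; replication initiation (rate k
per genome) creates synthesizing genomes, completion (rate beta) turns them
into post-replication genomes, and cell division (rate alpha) turns those into
templates of newborn cells:

    dN_T/dt = alpha N_P
    dN_S/dt = k N - beta N_S
    dN_P/dt = beta N_S - alpha N_P

with N = N_T + N_S + N_P. In steady exponential growth N grows at rate k and
the three fractions are constant; several cell-physiology quantities (DNA
content per cell, mean genome length, replisomes per complete genome) follow
from those fractions and from the DNA abundance profile.

The division rate alpha cannot be inferred from the abundance distribution;
operations that need it take it as a user-supplied value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .abundance import AbundanceProfile

__all__ = [
    "GenomeTypeRates",
    "GenomeTypeState",
    "integrate_genome_type_odes",
    "genome_fractions",
    "replisomes_per_genome",
    "replisomes_from_abundance",
    "average_genome_length",
    "dna_content_per_cell",
]


@dataclass(frozen=True)
class GenomeTypeRates:
    """Fork-firing rate k, division rate alpha, completion rate beta (1/s)."""

    k: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("k", "alpha", "beta"):
            value = getattr(self, name)
            if not (value > 0 and np.isfinite(value)):
                raise ValueError(f"rate {name} must be positive and finite, got {value}")


@dataclass(frozen=True)
class GenomeTypeState:
    """Counts (or densities) of template, synthesizing and post-replication genomes."""

    n_template: float
    n_synthesizing: float
    n_post: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.n_template <= 0:
            raise ValueError("n_template must be > 0 (each cell holds one template)")
        if self.n_synthesizing < 0 or self.n_post < 0:
            raise ValueError("genome counts must be non-negative")

    @property
    def total(self) -> float:
        return self.n_template + self.n_synthesizing + self.n_post


def _derivatives(rates: GenomeTypeRates, state: np.ndarray) -> np.ndarray:
    n_t, n_s, n_p = state
    n = n_t + n_s + n_p
    return np.array(
        [
            rates.alpha * n_p,
            rates.k * n - rates.beta * n_s,
            rates.beta * n_s - rates.alpha * n_p,
        ]
    )


def integrate_genome_type_odes(
    rates: GenomeTypeRates,
    init: GenomeTypeState,
    horizon: float,
    step: float,
) -> pd.DataFrame:
    """Integrate the genome-type ODEs with a fixed-step classical RK4 scheme.

    The system is linear, so fixed-step RK4 with a step well below the fastest
    rate is effectively exact; the step is clipped to 1/(10 max-rate) if the
    caller asks for a coarser one.

    Returns a DataFrame with columns ``time, n_template, n_synthesizing,
    n_post, total``.
    """
    if horizon <= 0 or step <= 0:
        raise ValueError("horizon and step must be positive")
    max_rate = max(rates.k, rates.alpha, rates.beta)
    h = min(step, 0.1 / max_rate)
    n_steps = int(math.ceil(horizon / h))
    h = horizon / n_steps

    y = np.array([init.n_template, init.n_synthesizing, init.n_post], dtype=float)
    out = np.empty((n_steps + 1, 4))
    out[0] = (init.time, *y)
    t = init.time
    for i in range(1, n_steps + 1):
        k1 = _derivatives(rates, y)
        k2 = _derivatives(rates, y + 0.5 * h * k1)
        k3 = _derivatives(rates, y + 0.5 * h * k2)
        k4 = _derivatives(rates, y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        out[i] = (t, *y)
    frame = pd.DataFrame(
        out, columns=["time", "n_template", "n_synthesizing", "n_post"]
    )
    frame["total"] = frame[["n_template", "n_synthesizing", "n_post"]].sum(axis=1)
    return frame


def genome_fractions(rates: GenomeTypeRates) -> tuple[float, float, float]:
    """Steady-state fractions (template, synthesizing, post-replication).

    f_T = alpha beta / ((k+beta)(k+alpha)),
    f_S = k / (k+beta),
    f_P = beta k / ((k+beta)(k+alpha));
    they sum to one.
    """
    k, a, b = rates.k, rates.alpha, rates.beta
    denom = (k + b) * (k + a)
    return (a * b / denom, k / (k + b), b * k / denom)


def replisomes_per_genome(k: float, beta: float) -> float:
    """Mean number of replisomes per complete genome, 2 N_S / (N_P + N_T) = 2k/beta."""
    if k <= 0 or beta <= 0:
        raise ValueError("k and beta must be positive")
    return 2.0 * k / beta


def replisomes_from_abundance(profile: "AbundanceProfile") -> float:
    """Replisomes per complete genome from the abundance profile alone.

    The complete-genome fraction equals the terminus-to-origin abundance ratio
    A(L/2)/A(0), so the replisome count is 2 [A(0) - A(L/2)] / A(L/2).
    """
    p0 = profile.p_origin
    p_term = profile.p_terminus
    if p_term <= 0:
        raise ValueError("terminal abundance is zero; replisome count undefined")
    return 2.0 * (p0 - p_term) / p_term


def average_genome_length(profile: "AbundanceProfile") -> float:
    """Mean genome length in the population, ell = 1/A(0) = ∫ P(y) dy (bp)."""
    return profile.mean_genome_length()


def dna_content_per_cell(k: float, alpha: float, vbar: float, length_bp: float) -> float:
    """Average DNA per cell (bp) for the constant-speed model.

    C = (2 vbar / k) ((k + alpha) / alpha) (e^{k L / 2 vbar} - 1): the product
    of the mean genome length and the mean number of genomes per cell. Reduces
    to L as k -> 0 (one complete genome per cell).
    """
    if min(k, alpha, vbar, length_bp) <= 0:
        raise ValueError("all arguments must be positive")
    c = k * length_bp / (2.0 * vbar)
    return (2.0 * vbar / k) * ((k + alpha) / alpha) * math.expm1(c)
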