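"""Forward map from fork dynamics to the DNA abundance distribution.

``P(y)`` is the probability that a randomly chosen genome in the population
(complete or incomplete) already contains position ``y``; the DNA abundance
``A(y)`` is ``P`` normalized to unit integral over the circle. A complete
genome contains every position, an incomplete one contains ``y`` if the fork
on that arm has passed ``|y|``, so

    P(y) = [k/(k+beta)] * Pr[fork coverage reaches y | incomplete]
         + beta/(k+beta),

with the incomplete-genome term read off the stationary fork distribution
p_st(x1, x2). ``P(0) = 1`` always (every genome contains the origin), and the
mean genome length in the population is ``ell = ∫ P dy = 1/A(0)``.

For zero diffusion the incomplete-genome term is an explicit function of the
deterministic fork schedule: ``P(y) = exp(-k T(|y|))`` with
``T(x) = ∫_0^x dx'/v(x')``, which reduces to ``exp(-k |y| / vbar)`` for
constant speed.

Profiles are represented on a fine "arm grid" of |y| values in [0, L/2]; the
per-bin quantities (P at bin midpoints, expected read fraction per bin) are
derived views. Bin aggregation integrates a single fixed fine-grid cumulative,
so refining the bin width and re-aggregating is exactly additive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import GenomeGeometry
from .forksim import ForkDistribution
from .model import ReplisomeModel

__all__ = [
    "AbundanceProfile",
    "abundance_constant_speed",
    "abundance_varspeed_D0",
    "probability_contains",
    "normalize_abundance",
    "bin_model_abundance",
    "write_profile",
    "read_profile",
]

_DEFAULT_ARM_STEP = 250.0


def _arm_grid(length_bp: float, arm_step: float) -> np.ndarray:
    half = length_bp / 2.0
    n = int(math.ceil(half / arm_step)) + 1
    return np.linspace(0.0, half, n)


@dataclass
class AbundanceProfile:
    """P(y) on a fine arm grid plus the geometry that defines the bins.

    ``x_arm`` is an increasing grid of distances |y| from the origin covering
    [0, L/2]; ``p_arm`` holds P at those distances with ``p_arm[0] = 1``.
    """

    geometry: GenomeGeometry
    x_arm: np.ndarray
    p_arm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_arm = np.asarray(self.x_arm, dtype=float)
        self.p_arm = np.asarray(self.p_arm, dtype=float)
        if self.x_arm.shape != self.p_arm.shape or self.x_arm.ndim != 1:
            raise ValueError("x_arm and p_arm must be 1-D arrays of equal length")
        if self.x_arm[0] != 0.0 or np.any(np.diff(self.x_arm) <= 0):
            raise ValueError("x_arm must be strictly increasing from 0")
        if np.any(self.p_arm <= 0):
            raise ValueError("P(y) must be strictly positive")
        if abs(self.p_arm[0] - 1.0) > 1e-6:
            raise ValueError("P at the origin must equal 1")

    # -- scalar summaries -------------------------------------------------
    @property
    def p_origin(self) -> float:
        return float(self.p_arm[0])

    @property
    def p_terminus(self) -> float:
        """P at |y| = L/2 (the fork meeting point)."""
        return float(
            np.interp(self.geometry.length_bp / 2.0, self.x_arm, self.p_arm)
        )

    def mean_genome_length(self) -> float:
        """ell = ∫ P(y) dy over the circle = 2 ∫_0^{L/2} P dx (bp)."""
        return 2.0 * float(np.trapezoid(self.p_arm, self.x_arm))

    @property
    def a_origin(self) -> float:
        """Abundance density A(0) = P(0)/ell (per bp)."""
        return self.p_origin / self.mean_genome_length()

    @property
    def a_terminus(self) -> float:
        return self.p_terminus / self.mean_genome_length()

    def p_at(self, abs_y) -> np.ndarray:
        """P evaluated at arbitrary |y| by linear interpolation."""
        return np.interp(np.abs(abs_y), self.x_arm, self.p_arm)

    # -- per-bin views ----------------------------------------------------
    def p_contains_bins(self, geometry: GenomeGeometry | None = None) -> np.ndarray:
        """P at bin midpoints (the per-bin contains-probability)."""
        geometry = geometry or self.geometry
        return self.p_at(np.abs(geometry.bin_y_mid()))

    def bin_fractions(self, geometry: GenomeGeometry | None = None) -> np.ndarray:
        """Expected read fraction per bin: ∫_bin A(y) dy, summing to 1.

        Integrates P along the linear coordinate on a fixed fine grid that
        includes every bin edge and the two kink points of |y(s)| (origin and
        antipode), then differences the cumulative at bin edges — exact
        additivity under bin refinement.
        """
        geometry = geometry or self.geometry
        if geometry.length_bp != self.geometry.length_bp:
            raise ValueError("geometry length does not match the profile")
        edges = geometry.bin_edges()
        s, cum = self._linear_cumulative(geometry)
        idx = np.searchsorted(s, edges)
        if not np.allclose(s[idx], edges):
            raise AssertionError("bin edges missing from integration grid")
        masses = np.diff(cum[idx])
        return masses / masses.sum()

    def _linear_cumulative(self, geometry: GenomeGeometry):
        L = geometry.length_bp
        # fixed lattice, independent of bin width: cumulative values at shared
        # bin edges then agree exactly, so re-binning is exactly additive
        sub = min(500.0, geometry.bin_bp / 2.0)
        antipode = (geometry.origin_bp + L / 2.0) % L
        base = np.arange(0.0, L, sub)
        s = np.union1d(
            np.union1d(base, geometry.bin_edges()),
            np.array([geometry.origin_bp, antipode]),
        )
        s = s[(s >= 0.0) & (s <= L)]
        d = np.abs(
            np.mod(s - geometry.origin_bp + L / 2.0, L) - L / 2.0
        )
        p = np.interp(d, self.x_arm, self.p_arm)
        cum = np.concatenate(
            ([0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(s)))
        )
        return s, cum

    def to_frame(self, geometry: GenomeGeometry | None = None) -> pd.DataFrame:
        geometry = geometry or self.geometry
        edges = geometry.bin_edges()
        return pd.DataFrame(
            {
                "bin_start_bp": edges[:-1],
                "bin_end_bp": edges[1:],
                "y_mid_bp": geometry.bin_y_mid(),
                "p_contains": self.p_contains_bins(geometry),
                "abundance": self.bin_fractions(geometry),
            }
        )


def abundance_constant_speed(
    geometry: GenomeGeometry,
    k: float,
    vbar: float,
    arm_step: float = _DEFAULT_ARM_STEP,
) -> AbundanceProfile:
    """Closed-form abundance for constant speed and D = 0.

    A(y) = k e^{-k|y|/vbar} / [2 vbar (1 - e^{-kL/2vbar})]; stored through
    P(y) = e^{-k|y|/vbar}.
    """
    if k <= 0 or vbar <= 0:
        raise ValueError("k and vbar must be positive")
    x = _arm_grid(geometry.length_bp, arm_step)
    return AbundanceProfile(
        geometry, x, np.exp(-k * x / vbar), meta={"k": k, "vbar": vbar, "model": "constant"}
    )


def abundance_varspeed_D0(
    geometry: GenomeGeometry,
    model: ReplisomeModel,
    k: float,
    arm_step: float = _DEFAULT_ARM_STEP,
) -> AbundanceProfile:
    """Exact abundance for a position-dependent speed with zero diffusion.

    With D = 0 the fork schedule is deterministic, T(x) = ∫_0^x dx'/v(x'), and
    an incomplete genome of age t covers |y| iff T(|y|) <= t; exponential
    demography then gives P(y) = exp(-k T(|y|)). Reduces exactly to the
    constant-speed closed form when delta = 0.
    """
    if model.diffusion != 0:
        raise ValueError(
            "abundance_varspeed_D0 requires D = 0; use simulate_stationary + "
            "probability_contains for diffusive models"
        )
    if k <= 0:
        raise ValueError("k must be positive")
    x = _arm_grid(geometry.length_bp, arm_step)
    t = model.time_to_position(x)
    return AbundanceProfile(
        geometry,
        x,
        np.exp(-k * t),
        meta={"k": k, "model": "oscillatory", **model.__dict__},
    )


def probability_contains(
    dist: ForkDistribution,
    beta: float | None,
    k: float,
    geometry: GenomeGeometry,
    arm_step: float = _DEFAULT_ARM_STEP,
) -> AbundanceProfile:
    """P(y) from a stationary fork distribution and completion rate.

    The incomplete-genome term is the p_st mass in which the fork on the |y|
    arm has copied at least |y| (symmetrized over the two replisomes); the
    complete-genome term is beta/(k+beta). ``beta`` defaults to ``dist.beta``.
    The raw P(0) equals 1 whenever p_st is normalized; a deviation beyond 1%
    triggers a warning and the profile is renormalized to P(0) = 1.
    """
    if beta is None:
        beta = dist.beta
    if beta <= 0 or k <= 0:
        raise ValueError("beta and k must be positive")
    L = dist.length_bp
    if geometry.length_bp != L:
        raise ValueError("geometry length does not match the fork distribution")
    x = _arm_grid(L, arm_step)
    kf = k / (k + beta)
    bf = beta / (k + beta)

    if dist.diagonal is not None:
        s, g = dist.diagonal
        cum = np.concatenate(([0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(s))))
        total = cum[-1]
        if abs(total - 1.0) > 1e-6:
            raise ValueError("diagonal fork density is not normalized")
        tail = total - np.interp(x, s, cum)
        incomplete = tail  # the mirror term vanishes except at |y| = L/2
    else:
        mass = dist.cell_masses()
        total = mass.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError("fork distribution grid is not normalized")
        mass = 0.5 * (mass + mass.T)  # enforce replisome exchange symmetry
        cell = dist.cell_bp
        edges = np.arange(dist.n_cells + 1) * cell
        row_tail = np.concatenate(
            (np.cumsum(mass.sum(axis=1)[::-1])[::-1], [0.0])
        )  # mass with x1 >= edge
        col_tail = np.concatenate(
            (np.cumsum(mass.sum(axis=0)[::-1])[::-1], [0.0])
        )  # mass with x2 >= edge
        term1 = np.interp(x, edges, row_tail)
        term2 = np.interp(np.clip(L - x, edges[0], edges[-1]), edges, col_tail)
        incomplete = term1 + term2

    p = kf * incomplete + bf
    p0 = p[0]
    if abs(p0 - 1.0) > 0.01:
        warnings.warn(
            f"raw P(0) = {p0:.4f} deviates from 1 by more than 1%; renormalizing",
            stacklevel=2,
        )
    p = p / p0
    return AbundanceProfile(geometry, x, p, meta={"k": k, "beta": beta})


def normalize_abundance(
    p_contains,
    geometry: GenomeGeometry,
) -> AbundanceProfile:
    """Normalize a contains-probability into an abundance profile.

    Accepts an :class:`AbundanceProfile` (returned unchanged, as profiles
    normalize on demand) or per-bin P values at the geometry's bin midpoints,
    from which an arm-grid profile is interpolated.
    """
    if isinstance(p_contains, AbundanceProfile):
        return p_contains
    values = np.asarray(p_contains, dtype=float)
    if values.shape != (geometry.n_bins,):
        raise ValueError(
            f"expected {geometry.n_bins} per-bin values, got shape {values.shape}"
        )
    if np.any(values <= 0):
        raise ValueError("P(y) must be strictly positive")
    d = np.abs(geometry.bin_y_mid())
    order = np.argsort(d)
    x_sorted = d[order]
    p_sorted = values[order]
    # collapse duplicate |y| (mirror bins) by averaging
    x_unique, inverse = np.unique(np.round(x_sorted, 6), return_inverse=True)
    p_unique = np.bincount(inverse, weights=p_sorted) / np.bincount(inverse)
    half = geometry.length_bp / 2.0
    x = np.concatenate(([0.0], x_unique, [half])) if x_unique[0] > 0 else np.concatenate((x_unique, [half]))
    p = np.interp(x, x_unique, p_unique)
    p[0] = 1.0 if x[0] == 0.0 else p[0]
    return AbundanceProfile(geometry, x, p, meta={"source": "per-bin"})


def bin_model_abundance(
    profile: AbundanceProfile,
    geometry: GenomeGeometry | None = None,
) -> np.ndarray:
    """Expected read fraction per bin under the model profile (sums to 1)."""
    return profile.bin_fractions(geometry)


def write_profile(profile: AbundanceProfile, path) -> None:
    """Serialize the per-bin view as TSV with a geometry header."""
    geometry = profile.geometry
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# length_bp={geometry.length_bp!r}\torigin_bp={geometry.origin_bp!r}"
            f"\tbin_bp={geometry.bin_bp!r}\n"
        )
        profile.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_profile(path) -> AbundanceProfile:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing geometry header line")
        fields = dict(
            item.split("=", 1) for item in header[1:].strip().split("\t")
        )
        geometry = GenomeGeometry(
            length_bp=float(fields["length_bp"]),
            origin_bp=float(fields["origin_bp"]),
            bin_bp=float(fields["bin_bp"]),
        )
        frame = pd.read_csv(fh, sep="\t")
    return normalize_abundance(frame["p_contains"].to_numpy(), geometry)
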