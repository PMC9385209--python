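"""Replisome speed models and constant-speed closed forms.

The replisome at arm position ``x`` (base pairs copied from the origin along
one arm) moves with deterministic speed ``v(x)`` plus Brownian fluctuations of
diffusion coefficient ``D``:

    dx/dt = v(x) + sqrt(2 D) xi(t)

Two speed profiles are supported: constant, ``v(x) = vbar``, and oscillatory,

    v(x) = vbar * [1 + delta * cos(omega * x + phi)],

with relative amplitude ``delta < 1`` (so the speed stays positive), spatial
angular frequency ``omega`` (rad/bp) and phase ``phi``. For the constant-speed,
zero-diffusion case every downstream quantity has a closed form; those are
collected here and serve as oracles for the stochastic simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ReplisomeModel",
    "beta_constant_speed",
    "predicted_omega",
    "meeting_region_size",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ReplisomeModel:
    """Parameters of the (possibly oscillatory) replisome speed profile.

    Parameters
    ----------
    vbar:
        Mean speed v̄ in bp/s, > 0.
    delta:
        Relative oscillation amplitude, in [0, 1). ``delta = 0`` is the
        constant-speed model.
    omega:
        Spatial angular frequency of the oscillation in rad/bp (>= 0).
        Use :meth:`from_omega_per_mbp` for the rad/Mbp convention used in
        reports.
    phi:
        Oscillation phase in radians, stored wrapped to [0, 2π).
    diffusion:
        Diffusion coefficient D in bp²/s (>= 0).
    """

    vbar: float
    delta: float = 0.0
    omega: float = 0.0
    phi: float = 0.0
    diffusion: float = 0.0

    def __post_init__(self) -> None:
        if not (self.vbar > 0 and np.isfinite(self.vbar)):
            raise ValueError(f"vbar must be positive, got {self.vbar}")
        if not (0.0 <= self.delta < 1.0):
            raise ValueError(f"delta must lie in [0, 1), got {self.delta}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")
        if self.diffusion < 0:
            raise ValueError(f"diffusion must be >= 0, got {self.diffusion}")
        object.__setattr__(self, "phi", float(np.mod(self.phi, _TWO_PI)))

    @classmethod
    def from_omega_per_mbp(
        cls,
        vbar: float,
        delta: float = 0.0,
        omega_per_mbp: float = 0.0,
        phi: float = 0.0,
        diffusion_kbp2: float = 0.0,
    ) -> "ReplisomeModel":
        """Build a model from report-scale units (rad/Mbp, kbp²/s)."""
        return cls(
            vbar=vbar,
            delta=delta,
            omega=omega_per_mbp * 1e-6,
            phi=phi,
            diffusion=diffusion_kbp2 * 1e6,
        )

    @property
    def omega_per_mbp(self) -> float:
        """Angular frequency in rad/Mbp (reporting convention)."""
        return self.omega * 1e6

    @property
    def diffusion_kbp2(self) -> float:
        """Diffusion coefficient in kbp²/s (reporting convention)."""
        return self.diffusion * 1e-6

    def speed_at(self, x):
        """Speed v(x) at arm position x (bp from the origin), in bp/s."""
        xx = np.asarray(x, dtype=float)
        if np.any(xx < 0):
            raise ValueError("arm position x must be >= 0")
        v = self.vbar * (1.0 + self.delta * np.cos(self.omega * xx + self.phi))
        return v if v.ndim else float(v)

    def with_diffusion(self, diffusion: float) -> "ReplisomeModel":
        return replace(self, diffusion=diffusion)

    def time_to_position(self, x_grid: np.ndarray) -> np.ndarray:
        """Deterministic arrival time T(x) = ∫0^x dx'/v(x') on a grid.

        ``x_grid`` must be sorted and start at 0. Composite trapezoid on the
        supplied grid; exact for the constant-speed model.
        """
        x = np.asarray(x_grid, dtype=float)
        if x[0] != 0 or np.any(np.diff(x) <= 0):
            raise ValueError("x_grid must be strictly increasing and start at 0")
        inv_v = 1.0 / self.speed_at(x)
        t = np.empty_like(x)
        t[0] = 0.0
        np.cumsum(0.5 * (inv_v[1:] + inv_v[:-1]) * np.diff(x), out=t[1:])
        return t


def beta_constant_speed(k: float, vbar: float, length_bp: float) -> float:
    """Replication-completion rate for constant speed and D = 0 (1/s).

    beta = k e^{-c} / (1 - e^{-c}) with c = k L / (2 vbar): forks launched at
    rate k take a deterministic time L/(2 vbar) to meet, and the exponentially
    growing population weights young forks by e^{-k t}.
    """
    if k <= 0 or vbar <= 0 or length_bp <= 0:
        raise ValueError("k, vbar and length_bp must be positive")
    c = k * length_bp / (2.0 * vbar)
    return k * math.exp(-c) / (-math.expm1(-c))


def predicted_omega(k: float, vbar: float) -> float:
    """Oscillation frequency expected if speed is coupled to the cell cycle.

    A factor oscillating with the doubling time tau = ln2 / k, sampled by a
    fork moving at vbar, produces a spatial angular frequency
    omega = 2 pi / (vbar tau) = 2 pi k / (ln2 vbar), in rad/bp.
    """
    if k <= 0 or vbar <= 0:
        raise ValueError("k and vbar must be positive")
    return _TWO_PI * k / (math.log(2.0) * vbar)


def meeting_region_size(model: ReplisomeModel, length_bp: float) -> float:
    """Width lD of the region where the two forks meet, in bp.

    Diffusion accumulates positional uncertainty over the replication time
    tau_C ≈ L / (2 vbar), giving lD ≈ 2 sqrt(2 D tau_C). Zero when D = 0
    (forks always meet at the midpoint).
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    tau_c = length_bp / (2.0 * model.vbar)
    return 2.0 * math.sqrt(2.0 * model.diffusion * tau_c)
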