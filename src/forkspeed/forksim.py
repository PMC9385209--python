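"""Stationary replication-fork distribution by stochastic-resetting simulation.

An incomplete genome is described by the copied portions (x1, x2) of its two
replisomes, each obeying dx/dt = v(x) + sqrt(2 D) xi(t) starting from (0, 0).
The line x1 + x2 = L is absorbing (replication completes and the trajectory is
reset to the origin), and on top of that every trajectory is reset to the
origin at the fork-firing rate k — the stochastic-resetting representation of
the dilution term in the population balance. The long-run occupation density
of this process is the stationary fork distribution p_st(x1, x2), and the
empirical absorption rate estimates the completion rate beta.

For constant speed and D = 0 the stationary law is exactly diagonal,
p_st(x1, x2) = g(x1) delta(x1 - x2) with g exponential in x1; that closed form
is provided here both as an oracle for the simulator and as an exact input for
the abundance forward map.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import GenomeGeometry
from .model import ReplisomeModel, beta_constant_speed

__all__ = [
    "ForkDistribution",
    "pst_constant_speed",
    "simulate_stationary",
    "stationarity_residual",
    "save_fork_distribution",
    "load_fork_distribution",
]


@dataclass
class ForkDistribution:
    """Stationary fork-position density on the triangle x1 + x2 <= L.

    ``grid`` is a dense (n_cells, n_cells) probability density (per bp²) over
    square cells of width ``cell_bp``; mass outside the triangle is zero.
    ``beta`` is the completion rate, estimated from absorptions for simulated
    distributions and exact for analytic ones. An optional ``diagonal`` payload
    (s-grid, density per bp along x1 = x2 = s) carries the exact singular
    representation of the constant-speed, D = 0 law.
    """

    grid: np.ndarray
    cell_bp: float
    length_bp: float
    beta: float
    n_events: int = 0
    total_time: float = 0.0
    seed: object = None
    diagonal: tuple[np.ndarray, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be a square 2-D array")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def n_cells(self) -> int:
        return self.grid.shape[0]

    def cell_masses(self) -> np.ndarray:
        """Per-cell probability mass (grid density × cell area)."""
        return self.grid * self.cell_bp**2

    def marginal_x1(self) -> tuple[np.ndarray, np.ndarray]:
        """(cell midpoints, marginal density of x1 per bp)."""
        if self.diagonal is not None:
            return self.diagonal
        mass = self.cell_masses().sum(axis=1)
        mids = (np.arange(self.n_cells) + 0.5) * self.cell_bp
        return mids, mass / self.cell_bp


def pst_constant_speed(
    k: float,
    vbar: float,
    length_bp: float,
    grid_bp: float = 250.0,
    cell_bp: float | None = None,
) -> ForkDistribution:
    """Exact stationary fork distribution for constant speed and D = 0.

    The two forks move in lockstep, so the density lives on the diagonal
    x1 = x2 = s with g(s) = (k / vbar) e^{-k s / vbar} / (1 - e^{-k L / 2 vbar})
    for s in [0, L/2]. The diagonal is stored exactly on a fine s-grid
    (spacing ``grid_bp``); a coarse 2-D histogram of the same mass is filled
    for plotting and residual checks.
    """
    if min(k, vbar, length_bp) <= 0:
        raise ValueError("k, vbar and length_bp must be positive")
    half = length_bp / 2.0
    n_s = int(math.ceil(half / grid_bp)) + 1
    s = np.linspace(0.0, half, n_s)
    norm = -math.expm1(-k * length_bp / (2.0 * vbar))
    g = (k / vbar) * np.exp(-k * s / vbar) / norm

    if cell_bp is None:
        cell_bp = length_bp / 50.0
    n_cells = int(math.ceil(length_bp / cell_bp))
    grid = np.zeros((n_cells, n_cells))
    # project diagonal mass into diagonal cells
    edges = np.arange(n_cells + 1) * cell_bp
    cell_mass = np.exp(-k * np.minimum(edges[:-1], half) / vbar) - np.exp(
        -k * np.minimum(edges[1:], half) / vbar
    )
    cell_mass /= norm
    np.fill_diagonal(grid, cell_mass / cell_bp**2)

    beta = beta_constant_speed(k, vbar, length_bp)
    return ForkDistribution(
        grid=grid,
        cell_bp=cell_bp,
        length_bp=length_bp,
        beta=beta,
        diagonal=(s, g),
        meta={"k": k, "vbar": vbar, "analytic": True},
    )


def simulate_stationary(
    model: ReplisomeModel,
    k: float,
    geometry: GenomeGeometry,
    *,
    seed,
    dt: float | None = None,
    n_trajectories: int = 2000,
    burn_in: float | None = None,
    horizon: float | None = None,
    cell_bp: float = 50_000.0,
) -> ForkDistribution:
    """Euler–Maruyama simulation of the resetting process of the fork pair.

    Trajectories advance with a midpoint-rule drift step plus Gaussian noise
    of variance 2 D dt (Euler–Maruyama in the noise); they are reset
    to (0, 0) upon absorption at x1 + x2 >= L (a completion event) and,
    independently, with probability 1 - e^{-k dt} per step (dilution). The
    occupation histogram after ``burn_in`` estimates p_st on cells of width
    ``cell_bp``; beta is absorptions / (trajectories × accumulated time).

    ``dt`` defaults to cell_bp / (5 v_max); larger values than cell_bp / v_max
    are rejected. The boundaries x = 0 are reflecting. ``seed`` is required
    and recorded in the output; identical seeds give identical output.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    L = geometry.length_bp
    vmax = model.vbar * (1.0 + model.delta)
    if dt is None:
        dt = 0.2 * cell_bp / vmax
    if vmax * dt > cell_bp:
        raise ValueError(
            f"dt={dt} too large: v_max*dt={vmax * dt:.1f} bp exceeds the "
            f"{cell_bp:.0f} bp grid cell"
        )
    if burn_in is None:
        # relaxation to stationarity is governed by the resetting rate k, not
        # by the completion time; synchronized starts decay only as e^{-kt}
        burn_in = 4.0 / k + L / model.vbar
    if horizon is None:
        horizon = 5.0 * max(1.0 / k, L / (2.0 * model.vbar))

    n_cells = int(math.ceil(L / cell_bp))
    rng = np.random.default_rng(seed)
    x1 = np.zeros(n_trajectories)
    x2 = np.zeros(n_trajectories)
    hist = np.zeros(n_cells * n_cells)
    burn_steps = int(math.ceil(burn_in / dt))
    n_steps = burn_steps + int(math.ceil(horizon / dt))
    p_reset = -math.expm1(-k * dt)
    sigma = math.sqrt(2.0 * model.diffusion * dt)
    vbar, delta, omega, phi = model.vbar, model.delta, model.omega, model.phi
    diffusive = model.diffusion > 0

    events = 0
    accum_steps = 0
    inv_cell = 1.0 / cell_bp
    for step in range(n_steps):
        # midpoint rule for the drift: O(dt^2) deterministic flow, so the
        # occupation density is unbiased at the histogram resolution even for
        # strongly position-dependent speeds
        m1 = x1 + 0.5 * dt * vbar * (1.0 + delta * np.cos(omega * x1 + phi))
        m2 = x2 + 0.5 * dt * vbar * (1.0 + delta * np.cos(omega * x2 + phi))
        x1 += vbar * (1.0 + delta * np.cos(omega * m1 + phi)) * dt
        x2 += vbar * (1.0 + delta * np.cos(omega * m2 + phi)) * dt
        if diffusive:
            x1 += sigma * rng.standard_normal(n_trajectories)
            x2 += sigma * rng.standard_normal(n_trajectories)
            np.abs(x1, out=x1)  # reflect at x = 0
            np.abs(x2, out=x2)
        absorbed = x1 + x2 >= L
        reset = absorbed | (rng.random(n_trajectories) < p_reset)
        x1[reset] = 0.0
        x2[reset] = 0.0
        if step >= burn_steps:
            events += int(np.count_nonzero(absorbed))
            accum_steps += 1
            i1 = np.minimum((x1 * inv_cell).astype(np.int64), n_cells - 1)
            i2 = np.minimum((x2 * inv_cell).astype(np.int64), n_cells - 1)
            np.add.at(hist, i1 * n_cells + i2, 1.0)

    accum_time = accum_steps * dt
    total = hist.sum()
    if total == 0 or events == 0:
        raise RuntimeError("no samples/absorptions accumulated; increase horizon")
    density = hist.reshape(n_cells, n_cells) / (total * cell_bp**2)
    beta = events / (n_trajectories * accum_time)
    return ForkDistribution(
        grid=density,
        cell_bp=cell_bp,
        length_bp=L,
        beta=beta,
        n_events=events,
        total_time=n_trajectories * accum_time,
        seed=seed,
        meta={
            "k": k,
            "vbar": vbar,
            "delta": delta,
            "omega": omega,
            "phi": phi,
            "diffusion": model.diffusion,
            "dt": dt,
            "n_trajectories": n_trajectories,
            "burn_in": burn_in,
            "horizon": horizon,
        },
    )


def stationarity_residual(
    dist: ForkDistribution,
    model: ReplisomeModel,
    k: float,
) -> float:
    """Integrated |residual| of the stationary transport equation.

    Evaluates -div(v p) + D lap(p) - k p by central finite differences and
    returns the integral of its absolute value. For a converged simulation the
    residual is dominated by sampling noise and shrinks as total_time grows.
    Distributions carrying an exact diagonal payload are checked along the
    diagonal, where the operator reduces to -(d/ds)[v(s) g(s)] - k g(s).
    """
    if dist.diagonal is not None:
        s, g = dist.diagonal
        flux = model.speed_at(s) * g
        resid = -np.gradient(flux, s) - k * g
        return float(np.trapezoid(np.abs(resid), s))

    if dist.n_cells < 5:
        raise ValueError("grid too coarse for the finite-difference stencil")
    h = dist.cell_bp
    p = dist.grid
    mids = (np.arange(dist.n_cells) + 0.5) * h
    v = model.speed_at(mids)
    fx1 = v[:, None] * p
    fx2 = v[None, :] * p
    div = np.zeros_like(p)
    div[1:-1, :] += (fx1[2:, :] - fx1[:-2, :]) / (2 * h)
    div[:, 1:-1] += (fx2[:, 2:] - fx2[:, :-2]) / (2 * h)
    resid = -div - k * p
    if model.diffusion > 0:
        lap = np.zeros_like(p)
        lap[1:-1, :] += (p[2:, :] - 2 * p[1:-1, :] + p[:-2, :]) / h**2
        lap[:, 1:-1] += (p[:, 2:] - 2 * p[:, 1:-1] + p[:, :-2]) / h**2
        resid += model.diffusion * lap
    # interior cells strictly inside the triangle only
    interior = np.zeros_like(p, dtype=bool)
    interior[1:-1, 1:-1] = True
    i, j = np.indices(p.shape)
    interior &= (i + j + 2) * h < dist.length_bp
    return float(np.sum(np.abs(resid[interior])) * h**2)


def save_fork_distribution(dist: ForkDistribution, path) -> None:
    """Write the grid as TSV with a ``#key=value`` metadata header."""
    path = Path(path)
    lines = [
        f"# cell_bp={dist.cell_bp!r}",
        f"# length_bp={dist.length_bp!r}",
        f"# beta={dist.beta!r}",
        f"# n_events={dist.n_events!r}",
        f"# total_time={dist.total_time!r}",
        f"# seed={dist.seed!r}",
    ]
    for key, value in sorted(dist.meta.items()):
        lines.append(f"# meta.{key}={value!r}")
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, dist.grid, delimiter="\t")


def load_fork_distribution(path) -> ForkDistribution:
    path = Path(path)
    header: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = value
            pos = fh.tell()
        grid = np.loadtxt(fh, delimiter="\t")
    meta = {
        key[5:]: value for key, value in header.items() if key.startswith("meta.")
    }
    seed = header.get("seed", "None")
    return ForkDistribution(
        grid=grid,
        cell_bp=float(header["cell_bp"]),
        length_bp=float(header["length_bp"]),
        beta=float(header["beta"]),
        n_events=int(header.get("n_events", 0)),
        total_time=float(header.get("total_time", 0.0)),
        seed=None if seed == "None" else ast.literal_eval(seed),
        meta=meta,
    )
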