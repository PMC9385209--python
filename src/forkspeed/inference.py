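"""Maximum-likelihood fitting of replisome-speed models to coverage tracks.

Reads falling into genome bins are modelled as a multinomial draw from the
model's per-bin abundance fractions (equivalently, independent Poisson counts
conditioned on the total), so the log-likelihood is sum_j c_j log f_j over
unmasked bins, with the model fractions renormalized over the same mask as the
data. The growth rate k is never fitted — it is measured independently from
optical-density curves — so the constant-speed model has a single free
parameter (vbar) and the oscillatory model four (vbar, delta, omega, phi),
plus optionally a diffusion coefficient D profiled with a simulation-based
likelihood. Model choice uses the Akaike information criterion.

The likelihood is multimodal in omega; fitting therefore combines a coarse
spectral scan of the residuals against the constant-speed fit (which localizes
the oscillation frequency) with multi-start Nelder–Mead refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .abundance import abundance_varspeed_D0, probability_contains
from .coverage import CoverageTrack
from .forksim import simulate_stationary
from .geometry import GenomeGeometry
from .model import ReplisomeModel

__all__ = [
    "FitResult",
    "CosineFit",
    "loglik_multinomial",
    "fit_constant",
    "fit_oscillatory",
    "select_model",
    "fit_cosine_profile",
    "correlate_profiles",
]

_TWO_PI = 2.0 * math.pi
#: arm-grid spacing (bp) used inside the fitting hot path; 1 kbp keeps the
#: quadrature error orders of magnitude below counting noise at any realistic
#: read depth.
_FIT_ARM_STEP = 1000.0


def loglik_multinomial(counts, model_fractions, mask=None) -> float:
    """Multinomial log-likelihood sum_j c_j log f_j (constants dropped).

    ``model_fractions`` are renormalized over the mask before use. A zero or
    negative model fraction on an unmasked bin with nonzero count is an error
    rather than a silent -inf.
    """
    counts = np.asarray(counts, dtype=float)
    fractions = np.asarray(model_fractions, dtype=float)
    if mask is None:
        mask = np.ones_like(counts, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    c = counts[mask]
    f = fractions[mask]
    if np.any((f <= 0) & (c > 0)):
        raise ValueError("model fraction is zero on a bin with observed reads")
    f = f / f.sum()
    keep = c > 0
    return float(np.sum(c[keep] * np.log(f[keep])))


@dataclass
class FitResult:
    """Outcome of a model fit to one corrected coverage track."""

    model_kind: str
    model: ReplisomeModel
    k_fixed: float
    loglik: float
    n_params: int
    mask: np.ndarray
    geometry: GenomeGeometry
    seed: object = None
    extra: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def parameters(self) -> dict:
        p = {"vbar": self.model.vbar}
        if self.model_kind != "constant":
            p.update(
                delta=self.model.delta,
                omega_per_mbp=self.model.omega_per_mbp,
                phi=self.model.phi,
                diffusion_kbp2=self.model.diffusion_kbp2,
            )
        return p


class _BinFractionCache:
    """Precomputed geometry arrays for fast model-fraction evaluation.

    Bins are aggregated by differencing a trapezoid cumulative on a fixed
    linear fine grid; P on the fine grid is linearly interpolated from the
    uniform arm grid, for which the interpolation indices and weights depend
    on the geometry only and are computed once.
    """

    def __init__(self, geometry: GenomeGeometry, arm_step: float = _FIT_ARM_STEP):
        L = geometry.length_bp
        half = L / 2.0
        n_arm = int(math.ceil(half / arm_step)) + 1
        self.x_arm = np.linspace(0.0, half, n_arm)
        self.arm_h = self.x_arm[1] - self.x_arm[0]

        sub = max(min(geometry.bin_bp / 10.0, 2000.0), 1.0)
        antipode = (geometry.origin_bp + L / 2.0) % L
        s = np.union1d(
            np.union1d(np.arange(0.0, L, sub), geometry.bin_edges()),
            np.array([geometry.origin_bp, antipode]),
        )
        s = s[(s >= 0.0) & (s <= L)]
        d = np.abs(np.mod(s - geometry.origin_bp + half, L) - half)
        idx = np.minimum((d / self.arm_h).astype(np.int64), n_arm - 2)
        self.w = d / self.arm_h - idx
        self.idx = idx
        self.trap_w = 0.5 * np.diff(s)
        self.edge_idx = np.searchsorted(s, geometry.bin_edges())

    def fractions_from_p_arm(self, p_arm: np.ndarray) -> np.ndarray:
        p_fine = p_arm[self.idx] * (1.0 - self.w) + p_arm[self.idx + 1] * self.w
        seg = (p_fine[1:] + p_fine[:-1]) * self.trap_w
        cum = np.concatenate(([0.0], np.cumsum(seg)))
        masses = np.diff(cum[self.edge_idx])
        return masses / masses.sum()

    def fractions(self, model: ReplisomeModel, k: float) -> np.ndarray:
        inv_v = 1.0 / (
            model.vbar * (1.0 + model.delta * np.cos(model.omega * self.x_arm + model.phi))
        )
        t = np.concatenate(
            ([0.0], np.cumsum(0.5 * (inv_v[1:] + inv_v[:-1]) * np.diff(self.x_arm)))
        )
        return self.fractions_from_p_arm(np.exp(-k * t))


def fit_constant(
    track: CoverageTrack,
    k: float,
    geometry: GenomeGeometry | None = None,
) -> FitResult:
    """Fit the constant-speed model; vbar is the single free parameter.

    Deterministic bounded 1-D optimization of the multinomial likelihood in
    log(vbar). k and vbar enter only through k/vbar, so the fit depends on the
    supplied k purely as a scale.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    geometry = geometry or track.geometry
    cache = _BinFractionCache(geometry)
    counts, mask = track.counts, track.mask

    def neg_ll(log_v: float) -> float:
        model = ReplisomeModel(vbar=math.exp(log_v))
        return -loglik_multinomial(counts, cache.fractions(model, k), mask)

    res = optimize.minimize_scalar(
        neg_ll, bounds=(math.log(5.0), math.log(50_000.0)), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:  # pragma: no cover - bounded Brent essentially always converges
        raise RuntimeError(f"constant-speed fit failed: {res.message}")
    vbar = math.exp(res.x)
    return FitResult(
        model_kind="constant",
        model=ReplisomeModel(vbar=vbar),
        k_fixed=k,
        loglik=-res.fun,
        n_params=1,
        mask=mask,
        geometry=geometry,
        extra={"optimizer": "bounded-brent"},
    )


def _omega_scan(
    abs_y: np.ndarray,
    residual: np.ndarray,
    omega_grid_mbp: np.ndarray,
) -> pd.DataFrame:
    """Least-squares amplitude of a sinusoid in |y| at each candidate omega."""
    rows = []
    r = residual - residual.mean()
    for om in omega_grid_mbp:
        w = om * 1e-6
        design = np.column_stack(
            [np.ones_like(abs_y), np.sin(w * abs_y), np.cos(w * abs_y)]
        )
        coef, sse, *_ = np.linalg.lstsq(design, r, rcond=None)
        sse = float(sse[0]) if len(sse) else float(np.sum((design @ coef - r) ** 2))
        rows.append((om, coef[1], coef[2], sse))
    return pd.DataFrame(rows, columns=["omega_mbp", "a_sin", "b_cos", "sse"])


def fit_oscillatory(
    track: CoverageTrack,
    k: float,
    geometry: GenomeGeometry | None = None,
    allow_diffusion: bool = False,
    sim_settings: dict | None = None,
    seed=None,
    omega_grid_mbp: np.ndarray | None = None,
) -> FitResult:
    """Fit the oscillatory-speed model v(x) = vbar [1 + delta cos(omega x + phi)].

    The D = 0 likelihood is analytic (P = exp(-k T(|y|))). Starting points come
    from the constant-speed fit plus a spectral scan of the log-residuals: for
    small delta the log-abundance deviation is
    (k delta / vbar omega) [sin(omega |y| + phi) - sin(phi)], so the scan's
    best frequencies seed (delta, omega, phi) for Nelder–Mead refinement and
    the best of several starts wins. phi is reported wrapped to [0, 2pi).

    With ``allow_diffusion`` the fitted (vbar, delta, omega, phi) are kept
    fixed while D is profiled on a grid using a common-random-number
    simulation likelihood (the D = 0 grid member is evaluated by simulation
    too, so the comparison is like-for-like); D is deemed significant only if
    it improves the AIC by at least 2.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    geometry = geometry or track.geometry
    cache = _BinFractionCache(geometry)
    counts, mask = track.counts, track.mask

    base = fit_constant(track, k, geometry)
    vbar0 = base.model.vbar

    freq = track.frequencies()
    model_freq = cache.fractions(base.model, k)
    model_freq = np.where(mask, model_freq, 0.0)
    model_freq = model_freq / model_freq[mask].sum()
    good = mask & (freq > 0)
    abs_y = np.abs(geometry.bin_y_mid())[good]
    residual = np.log(freq[good] / model_freq[good])

    if omega_grid_mbp is None:
        omega_grid_mbp = np.arange(0.5, 8.001, 0.05)
    scan = _omega_scan(abs_y, residual, omega_grid_mbp)
    scan = scan.sort_values("sse").reset_index(drop=True)

    starts: list[np.ndarray] = []
    for _, row in scan.head(3).iterrows():
        om = row["omega_mbp"]
        amp = math.hypot(row["a_sin"], row["b_cos"])
        phi0 = math.atan2(row["b_cos"], row["a_sin"]) % _TWO_PI
        delta0 = min(max(amp * vbar0 * om * 1e-6 / k, 1e-3), 0.8)
        starts.append(np.array([vbar0, delta0, om, phi0]))
    starts.append(np.array([vbar0, 0.05, scan.loc[0, "omega_mbp"], 0.0]))

    def neg_ll(theta: np.ndarray) -> float:
        vbar, delta, om_mbp, phi = theta
        if not (0.0 < vbar < 1e5):
            return 1e13
        if not (0.0 <= delta < 0.95):
            return 1e12 * (1.0 + abs(delta))
        # identifiability bound: oscillations with periods much longer than
        # the arm are degenerate with a rescaled constant model
        if not (0.4 <= om_mbp <= 10.0):
            return 1e12 * (1.0 + abs(om_mbp))
        model = ReplisomeModel(vbar=vbar, delta=delta, omega=om_mbp * 1e-6, phi=phi)
        return -loglik_multinomial(counts, cache.fractions(model, k), mask)

    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9, "adaptive": True},
        )
        if best is None or res.fun < best.fun:
            best = res
    vbar, delta, om_mbp, phi = best.x
    model = ReplisomeModel(
        vbar=float(vbar), delta=float(delta), omega=float(om_mbp) * 1e-6,
        phi=float(phi) % _TWO_PI,
    )
    result = FitResult(
        model_kind="oscillatory",
        model=model,
        k_fixed=k,
        loglik=-float(best.fun),
        n_params=4,
        mask=mask,
        geometry=geometry,
        seed=seed,
        extra={
            "constant_vbar": vbar0,
            "n_starts": len(starts),
            "delta_at_bound": bool(delta >= 0.94),
        },
    )
    if allow_diffusion:
        result = _profile_diffusion(result, track, cache, sim_settings, seed)
    return result


def _profile_diffusion(
    result: FitResult,
    track: CoverageTrack,
    cache: _BinFractionCache,
    sim_settings: dict | None,
    seed,
) -> FitResult:
    """Profile D on a grid with a common-random-number simulation likelihood."""
    if seed is None:
        raise ValueError("allow_diffusion requires an explicit seed")
    settings = {
        "n_trajectories": 400,
        "cell_bp": max(track.geometry.bin_bp, track.geometry.length_bp / 100.0),
        "d_grid_kbp2": (0.0, 0.25, 0.5, 1.0, 2.0, 4.0),
    }
    settings.update(sim_settings or {})
    d_grid = np.asarray(settings.pop("d_grid_kbp2"), dtype=float) * 1e6
    geometry = track.geometry
    k = result.k_fixed
    lls = []
    for d in d_grid:
        model_d = replace(result.model, diffusion=float(d))
        dist = simulate_stationary(
            model_d, k, geometry, seed=seed, **settings
        )
        profile = probability_contains(dist, dist.beta, k, geometry)
        frac = profile.bin_fractions(geometry)
        lls.append(loglik_multinomial(track.counts, frac, track.mask))
    lls = np.asarray(lls)
    i_best = int(np.argmax(lls))
    d_best = float(d_grid[i_best])
    # D = 0 has 4 free parameters, D > 0 has 5
    aic0 = 2 * 4 - 2 * lls[0]
    aic_best = (2 * 5 - 2 * lls[i_best]) if d_best > 0 else aic0
    significant = d_best > 0 and (aic0 - aic_best) >= 2.0
    extra = dict(result.extra)
    extra["diffusion_profile"] = pd.DataFrame(
        {"diffusion_kbp2": d_grid / 1e6, "loglik_sim": lls}
    )
    extra["diffusion_best_kbp2"] = d_best / 1e6
    extra["diffusion_significant"] = bool(significant)
    model = replace(result.model, diffusion=d_best if significant else 0.0)
    return replace(result, model=model, seed=seed, extra=extra)


def select_model(fits: list[FitResult]) -> tuple[FitResult, pd.DataFrame]:
    """Pick the minimum-AIC fit; returns (best fit, delta-AIC table)."""
    if not fits:
        raise ValueError("no fits supplied")
    mask0 = fits[0].mask
    for f in fits[1:]:
        if not np.array_equal(f.mask, mask0):
            raise ValueError("fits were not computed on the same mask")
    aics = np.array([f.aic for f in fits])
    table = pd.DataFrame(
        {
            "model_kind": [f.model_kind for f in fits],
            "n_params": [f.n_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": aics,
            "delta_aic": aics - aics.min(),
        }
    )
    return fits[int(np.argmin(aics))], table


@dataclass(frozen=True)
class CosineFit:
    """Least-squares fit of m [1 + delta cos(omega x + phi)] to a 1-D profile."""

    mean: float
    delta: float
    omega: float
    phi: float
    omega_defined: bool = True


def fit_cosine_profile(
    x,
    values,
    weights=None,
    omega_grid: np.ndarray | None = None,
) -> CosineFit:
    """Fit a mean-plus-cosine to a genomic profile (e.g. a mutation-rate track).

    A grid scan over omega with linear profiling of the remaining parameters
    seeds a bounded nonlinear refinement. A constant input returns delta = 0
    with ``omega_defined=False``.
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(values, dtype=float)
    if x.shape != v.shape or x.size < 4:
        raise ValueError("need >= 4 matched (x, value) points")
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    mean0 = float(np.average(v, weights=w))
    if np.ptp(v) <= 1e-12 * max(abs(mean0), 1.0):
        return CosineFit(mean=mean0, delta=0.0, omega=float("nan"), phi=0.0,
                         omega_defined=False)

    span = float(np.ptp(x))
    if omega_grid is None:
        dx = float(np.median(np.diff(np.sort(x))))
        omega_grid = np.linspace(0.5 * _TWO_PI / span, 0.8 * math.pi / dx, 400)
    sw = np.sqrt(w)
    best = None
    for om in omega_grid:
        design = np.column_stack([np.ones_like(x), np.cos(om * x), np.sin(om * x)])
        coef, *_ = np.linalg.lstsq(design * sw[:, None], v * sw, rcond=None)
        sse = float(np.sum(w * (design @ coef - v) ** 2))
        if best is None or sse < best[0]:
            best = (sse, om, coef)
    _, om0, (m0, a0, b0) = best
    delta0 = math.hypot(a0, b0) / abs(m0)
    phi0 = math.atan2(-b0, a0) % _TWO_PI

    def resid(theta):
        m, delta, om, phi = theta
        return sw * (m * (1.0 + delta * np.cos(om * x + phi)) - v)

    sol = optimize.least_squares(
        resid,
        x0=[m0, min(delta0, 5.0), om0, phi0],
        bounds=([-np.inf, 0.0, omega_grid[0] * 0.5, -_TWO_PI],
                [np.inf, 10.0, omega_grid[-1] * 2.0, 2 * _TWO_PI]),
    )
    m, delta, om, phi = sol.x
    return CosineFit(
        mean=float(m), delta=float(delta), omega=float(om),
        phi=float(phi) % _TWO_PI, omega_defined=True,
    )


def correlate_profiles(a, b) -> float:
    """Pearson correlation of two profiles on shared bins (NaNs dropped jointly)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share their bins")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need >= 3 shared bins")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a zero-variance profile")
    return float(stats.pearsonr(a, b).statistic)
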