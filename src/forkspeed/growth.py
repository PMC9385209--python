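"""Growth-rate extraction from optical density and Arrhenius temperature fits.

The population growth rate k doubles as the fork-firing rate in the replisome
model and is measured independently of sequencing: each replicate OD curve is
fit with a logistic a / (1 + b e^{-k t}) and the per-temperature k is the mean
over replicates. Temperature dependence of rates and speeds is summarized by
an Arrhenius law value = A exp(-Delta / R T), fitted by least squares in
log space with T in kelvin and Delta reported in kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize

__all__ = [
    "R_GAS",
    "GrowthCurve",
    "LogisticFit",
    "ArrheniusFit",
    "logistic_fit",
    "mean_growth_rate",
    "arrhenius_fit",
    "read_growth_curve",
]

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate optical-density time series."""

    times: np.ndarray
    od: np.ndarray
    temperature: float | None = None
    replicate_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "od", np.asarray(self.od, dtype=float))
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be matched 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od <= 0):
            raise ValueError("optical density must be positive")


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic a / (1 + b e^{-k t}) with parameter covariance."""

    a: float
    b: float
    k: float
    covariance: np.ndarray


@dataclass(frozen=True)
class ArrheniusFit:
    """value = prefactor * exp(-activation / (R T)); activation in kJ/mol."""

    prefactor: float
    activation_kj_mol: float
    covariance: np.ndarray  # 2x2 in (ln prefactor, activation J/mol)


def logistic_fit(curve: GrowthCurve) -> LogisticFit:
    """Nonlinear least-squares logistic fit of one OD curve.

    Needs at least 5 points spanning both sides of the inflection to pin all
    three parameters. Initial values come from the data (a: plateau, k:
    early-time log-linear slope, b: intercept); failures raise with the
    residual norm in the message.
    """
    t, od = curve.times, curve.od
    if t.size < 5:
        raise ValueError("need >= 5 time points for a logistic fit")
    a0 = float(od.max())
    early = od < 0.5 * a0
    if early.sum() >= 2:
        slope, _ = np.polyfit(t[early], np.log(od[early]), 1)
        k0 = max(float(slope), 1.0 / (t[-1] - t[0]))
    else:
        k0 = 1.0 / (t[-1] - t[0])
    b0 = max(a0 / od[0] - 1.0, 1e-6)

    def f(tt, a, b, k):
        return a / (1.0 + b * np.exp(-k * tt))

    try:
        popt, pcov = optimize.curve_fit(
            f, t, od, p0=[a0, b0, k0],
            bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        resid = float(np.linalg.norm(f(t, a0, b0, k0) - od))
        raise RuntimeError(
            f"logistic fit did not converge (initial residual norm {resid:.3g})"
        ) from exc
    return LogisticFit(a=float(popt[0]), b=float(popt[1]), k=float(popt[2]),
                       covariance=pcov)


def mean_growth_rate(fits) -> tuple[float, float]:
    """Mean and standard deviation of k across replicate logistic fits.

    Accepts LogisticFit instances or plain (a, b, k) triples.
    """
    ks = [f.k if isinstance(f, LogisticFit) else float(f[2]) for f in fits]
    if not ks:
        raise ValueError("need at least one fit")
    ks = np.asarray(ks, dtype=float)
    return float(ks.mean()), float(ks.std(ddof=0 if ks.size == 1 else 1))


def arrhenius_fit(
    temperatures_c,
    values,
    exclude=(),
) -> ArrheniusFit:
    """Least-squares Arrhenius fit ln(value) = ln A - Delta / (R T).

    ``temperatures_c`` in Celsius (converted with T[K] = T + 273.15 exactly);
    ``exclude`` lists Celsius temperatures to drop (e.g. an off-trend cold
    point). Unweighted regression in log space; Delta reported in kJ/mol.
    """
    temps = np.asarray(temperatures_c, dtype=float)
    vals = np.asarray(values, dtype=float)
    if temps.shape != vals.shape:
        raise ValueError("temperatures and values must be matched")
    if np.any(vals <= 0):
        raise ValueError("Arrhenius fit requires positive values")
    keep = ~np.isin(temps, np.asarray(list(exclude), dtype=float))
    temps, vals = temps[keep], vals[keep]
    if temps.size < 2:
        raise ValueError("need >= 2 included points")
    x = 1.0 / (R_GAS * (temps + 273.15))
    y = np.log(vals)
    if temps.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        cov = np.full((2, 2), np.nan)
    else:
        (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
        cov = cov[::-1, ::-1]  # reorder to (intercept, slope)
    return ArrheniusFit(
        prefactor=math.exp(intercept),
        activation_kj_mol=-slope / 1000.0,
        covariance=np.asarray(cov),
    )


def read_growth_curve(path, temperature=None, replicate_id="") -> GrowthCurve:
    """Read a 2-column (time_s, od) tab-separated growth curve."""
    data = np.loadtxt(Path(path), delimiter="\t")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected two tab-separated columns: time_s, od")
    return GrowthCurve(times=data[:, 0], od=data[:, 1], temperature=temperature,
                       replicate_id=replicate_id)
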