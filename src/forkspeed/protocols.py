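"""Self-calibration protocols: generate synthetic data, fit it back, tabulate.

These are the experiments the package uses to validate itself: multinomial
coverage is drawn from a known oscillatory-speed ground truth at full MG1655
scale, pushed through bias correction and maximum likelihood, and the fitted
parameters are compared with the generating ones. The same routines back the
test suite and the reproduction script, so the published protocol lives in
exactly one place.
"""

from __future__ import annotations

import pandas as pd

from .coverage import bias_correct
from .geometry import GenomeGeometry
from .inference import fit_constant, fit_oscillatory, select_model
from .model import ReplisomeModel
from .presets import (
    REFERENCE_CONDITIONS,
    default_geometry,
    reference_k,
    reference_model,
)
from .synthetic import SyntheticSpec, generate_coverage

__all__ = ["recovery_experiment", "recovery_summary", "model_selection_experiment"]


def _fit_one(
    geometry: GenomeGeometry,
    model: ReplisomeModel,
    k: float,
    n_reads: int,
    bias_sd: float,
    seed,
):
    spec = SyntheticSpec(
        geometry=geometry,
        model=model,
        k=k,
        n_reads_exponential=n_reads,
        n_reads_stationary=n_reads,
        bias_sd=bias_sd,
        seed=seed,
    )
    exp_track, stat_track, _ = generate_coverage(spec)
    corrected = bias_correct(exp_track, stat_track)
    constant = fit_constant(corrected, k)
    oscillatory = fit_oscillatory(corrected, k)
    return corrected, constant, oscillatory


def recovery_experiment(
    temperature_c: int,
    n_seeds: int = 20,
    base_seed: int = 0,
    n_reads: int = 5_000_000,
    bias_sd: float = 0.2,
    geometry: GenomeGeometry | None = None,
) -> pd.DataFrame:
    """Generate-and-refit at one reference temperature, one row per seed.

    Ground truth is the reference oscillatory model (D = 0) at the requested
    temperature with k fixed from the matching doubling time. Columns hold
    the fitted (vbar, delta, omega, phi) of the oscillatory fit plus the
    constant-model vbar; medians over seeds are the headline estimates.
    """
    geometry = geometry or default_geometry()
    truth = reference_model(temperature_c)
    k = reference_k(temperature_c)
    rows = []
    for i in range(n_seeds):
        _, constant, osc = _fit_one(
            geometry, truth, k, n_reads, bias_sd, seed=(base_seed, temperature_c, i)
        )
        rows.append(
            dict(
                temperature_c=temperature_c,
                seed_index=i,
                vbar=osc.model.vbar,
                delta=osc.model.delta,
                omega_mbp=osc.model.omega_per_mbp,
                phi=osc.model.phi,
                vbar_constant=constant.model.vbar,
                loglik=osc.loglik,
            )
        )
    return pd.DataFrame(rows)


def recovery_summary(table: pd.DataFrame) -> dict[str, float]:
    """Median fitted parameters of a recovery experiment."""
    return {
        "vbar": float(table["vbar"].median()),
        "delta": float(table["delta"].median()),
        "omega_mbp": float(table["omega_mbp"].median()),
        "phi": float(table["phi"].median()),
        "vbar_constant": float(table["vbar_constant"].median()),
    }


def model_selection_experiment(
    delta: float,
    n_seeds: int = 20,
    base_seed: int = 0,
    temperature_c: int = 37,
    n_reads: int = 5_000_000,
    bias_sd: float = 0.2,
    geometry: GenomeGeometry | None = None,
) -> pd.DataFrame:
    """AIC contest between constant and oscillatory fits on known truth.

    Truth is the reference model at ``temperature_c`` with its oscillation
    amplitude replaced by ``delta`` (``delta = 0`` probes the false-selection
    rate). One row per seed with the chosen model kind and the AIC gap.
    """
    geometry = geometry or default_geometry()
    cond = REFERENCE_CONDITIONS[temperature_c]
    truth = ReplisomeModel.from_omega_per_mbp(
        vbar=cond["vbar"],
        delta=delta,
        omega_per_mbp=cond["omega_mbp"],
        phi=cond["phi"],
    )
    k = reference_k(temperature_c)
    rows = []
    for i in range(n_seeds):
        _, constant, osc = _fit_one(
            geometry, truth, k, n_reads, bias_sd, seed=(base_seed, 1000 + i)
        )
        best, table = select_model([constant, osc])
        rows.append(
            dict(
                seed_index=i,
                truth_delta=delta,
                chosen=best.model_kind,
                aic_constant=float(table.loc[table.model_kind == "constant", "aic"].iloc[0]),
                aic_oscillatory=float(
                    table.loc[table.model_kind == "oscillatory", "aic"].iloc[0]
                ),
            )
        )
    frame = pd.DataFrame(rows)
    frame["delta_aic"] = frame["aic_constant"] - frame["aic_oscillatory"]
    return frame
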