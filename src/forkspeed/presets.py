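"""Reference study conditions for *E. coli* MG1655 grown in LB.

Oscillatory-speed parameters (mean ± sd over replicates) estimated by
marker-frequency analysis at five growth temperatures, together with the
doubling times used to fix the fork-firing rate k = ln2 / t_double. The 22 °C
and 37 °C doubling times are the values the synthetic-recovery protocol is
defined with; the remaining ones derive from the Arrhenius temperature law of
the growth rate (B = 6.0e12 hr^-1, activation 74 kJ/mol), except 17 °C, which
sits off that law and below the multi-fork regime and is set to 3 h.

These values parameterize synthetic ground truth for self-calibration
experiments; nothing in the inference machinery depends on them.
"""

from __future__ import annotations

import math

from .geometry import MG1655, GenomeGeometry
from .model import ReplisomeModel

__all__ = [
    "REFERENCE_CONDITIONS",
    "SPEED_ACTIVATION_KJ_MOL",
    "GROWTH_ACTIVATION_KJ_MOL",
    "reference_model",
    "reference_k",
]

#: Per-temperature oscillatory-speed parameters and adopted doubling times.
#: vbar in bp/s, omega in rad/Mbp, phi in rad, D in kbp²/s.
REFERENCE_CONDITIONS: dict[int, dict[str, float]] = {
    17: dict(vbar=246.0, vbar_sd=33.0, delta=0.22, delta_sd=0.13,
             omega_mbp=0.7, omega_sd=0.5, phi=3.3, phi_sd=1.0,
             diffusion_kbp2=0.39, diffusion_sd=0.43, doubling_time_s=10_800.0),
    22: dict(vbar=351.0, vbar_sd=30.0, delta=0.20, delta_sd=0.06,
             omega_mbp=2.7, omega_sd=0.6, phi=3.4, phi_sd=0.6,
             diffusion_kbp2=0.81, diffusion_sd=1.18, doubling_time_s=4_000.0),
    27: dict(vbar=541.0, vbar_sd=30.0, delta=0.18, delta_sd=0.03,
             omega_mbp=4.7, omega_sd=0.1, phi=2.1, phi_sd=0.1,
             diffusion_kbp2=0.35, diffusion_sd=0.49, doubling_time_s=3_100.0),
    32: dict(vbar=821.0, vbar_sd=66.0, delta=0.11, delta_sd=0.04,
             omega_mbp=5.5, omega_sd=0.2, phi=1.5, phi_sd=0.1,
             diffusion_kbp2=1.15, diffusion_sd=1.23, doubling_time_s=1_900.0),
    37: dict(vbar=970.0, vbar_sd=51.0, delta=0.17, delta_sd=0.03,
             omega_mbp=4.3, omega_sd=0.2, phi=3.0, phi_sd=0.2,
             diffusion_kbp2=2.90, diffusion_sd=2.48, doubling_time_s=1_500.0),
}

#: Arrhenius activation energy of the mean replisome speed (kJ/mol), 22-37 °C.
SPEED_ACTIVATION_KJ_MOL = (50.0, 5.0)
#: Arrhenius activation energy of the growth rate (kJ/mol), 22-37 °C.
GROWTH_ACTIVATION_KJ_MOL = (74.0, 10.0)


def reference_model(temperature_c: int, diffusion: bool = False) -> ReplisomeModel:
    """Oscillatory-speed model at one reference temperature (D = 0 by default)."""
    cond = REFERENCE_CONDITIONS[temperature_c]
    return ReplisomeModel.from_omega_per_mbp(
        vbar=cond["vbar"],
        delta=cond["delta"],
        omega_per_mbp=cond["omega_mbp"],
        phi=cond["phi"],
        diffusion_kbp2=cond["diffusion_kbp2"] if diffusion else 0.0,
    )


def reference_k(temperature_c: int) -> float:
    """Fork-firing/growth rate k = ln2 / doubling time at one temperature (1/s)."""
    return math.log(2.0) / REFERENCE_CONDITIONS[temperature_c]["doubling_time_s"]


def default_geometry() -> GenomeGeometry:
    """The MG1655-scale geometry the reference conditions refer to."""
    return MG1655
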