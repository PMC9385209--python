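"""End-to-end inference demo: synthesize coverage, correct bias, fit models.

Generates sequencing-like coverage from a known oscillatory-speed ground
truth (fast growth at 37 degC), removes the shared per-bin bias with a
stationary reference, fits the constant- and oscillatory-speed models by
multinomial maximum likelihood, and selects between them with AIC.
"""

from forkspeed import (
    MG1655,
    SyntheticSpec,
    bias_correct,
    fit_constant,
    fit_oscillatory,
    generate_coverage,
    select_model,
)
from forkspeed.presets import reference_k, reference_model

truth = reference_model(37)         # vbar=970 bp/s, delta=0.17, omega=4.3, phi=3.0
k = reference_k(37)

spec = SyntheticSpec(geometry=MG1655, model=truth, k=k,
                     n_reads_exponential=5_000_000,
                     n_reads_stationary=5_000_000, bias_sd=0.2, seed=7)
exponential, stationary, _ = generate_coverage(spec)
corrected = bias_correct(exponential, stationary)

constant = fit_constant(corrected, k)
oscillatory = fit_oscillatory(corrected, k)
best, table = select_model([constant, oscillatory])

print("ground truth : vbar=970.0  delta=0.170  omega=4.30 rad/Mbp  phi=3.00 rad")
m = oscillatory.model
print(f"oscillatory  : vbar={m.vbar:.1f}  delta={m.delta:.3f}  "
      f"omega={m.omega_per_mbp:.2f} rad/Mbp  phi={m.phi:.2f} rad")
print(f"constant     : vbar={constant.model.vbar:.1f}")
print()
print(table.to_string(index=False))
print(f"\nselected model: {best.model_kind}")
print("\nThe oscillatory model recovers the generating parameters and wins")
print("the AIC comparison decisively: speed waves of ~17% amplitude leave a")
print("clear imprint on the abundance distribution at this read depth.")
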