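"""Compare a speed wave with a second genomic profile (e.g. mutation rate).

Fits the mean-plus-cosine model m [1 + delta cos(omega x + phi)] to a noisy
1-D genomic profile and computes the Pearson correlation between two wave-like
profiles, the analysis used to compare speed oscillations with mutation-rate
oscillations along the genome.
"""

import numpy as np

from forkspeed import correlate_profiles, fit_cosine_profile

rng = np.random.default_rng(11)
x = np.linspace(0.0, 4.0e6, 400)            # genome positions, bp

# wave-like "mutation rate" profile: 2.4 /kbp/generation mean, 18% amplitude
truth = dict(mean=2.4, delta=0.18, omega=4.9e-6, phi=1.93)
profile = truth["mean"] * (1 + truth["delta"] * np.cos(truth["omega"] * x
                                                       + truth["phi"]))
noisy = profile * (1 + rng.normal(0, 0.05, x.size))

fit = fit_cosine_profile(x, noisy)
print("cosine fit to the noisy profile:")
print(f"  mean  = {fit.mean:.3f}   (truth {truth['mean']})")
print(f"  delta = {fit.delta:.3f}   (truth {truth['delta']})")
print(f"  omega = {fit.omega * 1e6:.2f} rad/Mbp (truth {truth['omega'] * 1e6:.2f})")
print(f"  phi   = {fit.phi:.2f} rad  (truth {truth['phi']})")

# a second wave, slightly phase-shifted: high but imperfect correlation
speed_wave = 1 + 0.17 * np.cos(4.9e-6 * x + truth["phi"] - 0.5)
r = correlate_profiles(noisy, speed_wave)
print(f"\nPearson r between the two profiles: {r:.2f}")
print("\nIn-phase waves of similar frequency correlate strongly; a phase shift")
print("of half a radian still leaves most of the correlation intact.")
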