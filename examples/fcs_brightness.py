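"""FCS correlation fitting and molecular brightness.

Simulates correlation curves from the published internal/external oligo
complex parameter sets (3-D Gaussian focus, two dark-state terms), fits them
back with all seven free parameters (omega0 fixed from calibration), and
derives counts-per-molecule brightness.
"""

import numpy as np

import musicflow as mf
from musicflow.presets import EXT_FCS, INT_FCS, OMEGA_0
from musicflow.simulate import FcsSimSpec, simulate_fcs_curve

rng = np.random.default_rng(3)

for label, truth, count_rate in (("ext", EXT_FCS, 4.0), ("int", INT_FCS, 6.75)):
    curve = simulate_fcs_curve(FcsSimSpec(params=truth, sd_scale=0.5), rng)
    fit = mf.fit_fcs(curve, omega_fixed=OMEGA_0, n_starts=8, seed=0)
    p = fit.params
    brightness = mf.molecular_brightness(count_rate, 0.0, p.n)
    print(f"{label}. oligo complex:")
    print(f"  N = {p.n:.3f} (true {truth.n}), t_diff = {p.t_diff:.3f} ms "
          f"(true {truth.t_diff})")
    print(f"  dark states: A_T1 = {p.a_t1:.3f} @ {p.t_t1:.2f} us, "
          f"A_T2 = {p.a_t2:.3f} @ {p.t_t2:.3f} ms")
    print(f"  reduced chi2 = {fit.red_chi2:.2f}")
    print(f"  molecular brightness at {count_rate} kHz count rate: "
          f"{brightness:.1f} kHz/molecule")
    print()

print("G(0) = G_inf + 1/N; the dark-state fractions lift the short-lag")
print("correlation above the pure-diffusion envelope. A larger brightness")
print("for the int. complex at equal N means more photons per bright molecule.")
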