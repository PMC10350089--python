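"""Lifetime/anisotropy fitting and the static-quenching decomposition.

Simulates polarized TCSPC decay pairs for the internal and external oligo
complexes (IRF-convolved bi-exponential decays, Poisson counting noise),
fits the lifetimes by iterative reconvolution with chi-square model
selection, computes the species-average lifetime and rotational time, and
decomposes the steady-state intensity gap into dynamic and static quenching.
"""

import numpy as np

import musicflow as mf
from musicflow.presets import (
    EXT_BRIGHTNESS_KHZ, EXT_DECAY, EXT_ROTATIONAL_TIME_PS, G_FACTOR,
    INT_BRIGHTNESS_KHZ, INT_DECAY, INT_ROTATIONAL_TIME_PS,
    INTENSITY_FOLD_INT_VS_EXT,
)
from musicflow.simulate import DecaySimSpec, simulate_decay_pair

rng = np.random.default_rng(4)
columns = {}
for label, decay, rot_ps, brightness in (
    ("ext", EXT_DECAY, EXT_ROTATIONAL_TIME_PS, EXT_BRIGHTNESS_KHZ),
    ("int", INT_DECAY, INT_ROTATIONAL_TIME_PS, INT_BRIGHTNESS_KHZ),
):
    spec = DecaySimSpec(
        params=decay,
        anisotropy=mf.AnisotropyParams(r0=0.3, tau_r=rot_ps, g_factor=G_FACTOR),
        irf_center_ns=2.0, irf_width_ns=0.1, total_counts=5e6, n_bins=500,
    )
    par, perp = simulate_decay_pair(spec, rng)
    combined = mf.DecayTrace(par.time, par.counts + 2 * G_FACTOR * perp.counts,
                             "combined")
    fit = mf.fit_decay(combined, irf_center=2.0, irf_width=0.1, max_components=3)
    series = mf.anisotropy_compute(par, perp, g_factor=G_FACTOR, count_floor=100)
    # start the anisotropy fit past the IRF smear (center + 3 sigma)
    aniso = mf.fit_anisotropy(series, t_start=2.3)
    columns[label] = {"decay": fit, "anisotropy": aniso, "brightness_khz": brightness}
    tau_x = mf.species_average_lifetime(fit.params)
    print(f"{label}. oligo complex: {fit.n_components} lifetimes selected")
    for a, tau in fit.params.components:
        print(f"    A = {a:.2f}, tau = {tau:.2f} ns")
    print(f"    species-average lifetime <tau>_x = {tau_x:.2f} ns "
          f"(true {mf.species_average_lifetime(decay):.2f})")
    print(f"    rotational time = {aniso.params.tau_r:.0f} ps (true {rot_ps:.0f})")
    print()

print(mf.parameter_table(columns).round(3))
print()
d = mf.quenching_decomposition(INTENSITY_FOLD_INT_VS_EXT,
                               INT_BRIGHTNESS_KHZ / EXT_BRIGHTNESS_KHZ)
print(f"intensity fold (int/ext): {d.intensity_ratio:.1f}")
print(f"brightness fold (int/ext): {d.brightness_ratio:.2f}")
print(f"static quenching factor: {d.static_factor:.2f}  "
      f"dark fraction: {d.dark_fraction:.2f}")
print("The ~6-fold intensity gap with < 2-fold brightness gap implies that a")
print("~3.6-fold factor comes from static (ground-state dark complex)")
print("quenching of the external configuration.")
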