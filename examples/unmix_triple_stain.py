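"""Spectral unmixing of a three-probe panel (two single dyes + one tandem).

Simulates unstained, singly-stained and triple-stained samples on a
22-channel panel, builds reference spectra from the data (per-channel
medians of gated positives; autofluorescence from unstained cells), unmixes
every event by non-negative least squares, and prints the single-stain
specificity matrix and %-positive estimates.
"""

import numpy as np

import musicflow as mf
from musicflow.simulate import (
    NoiseModel, PopulationSpec, make_autofluorescence_endmember, make_endmember,
    simulate_event_table,
)

panel = mf.default_panel()
rng = np.random.default_rng(1)

a488 = make_endmember("Atto488", 1, panel)
a647 = make_endmember("Atto647", 15, panel)
tandem = make_endmember("Atto488_647", -1, panel,
                        donor_acceptor_mix=0.5, parents=(a488, a647))
ems = [a488, a647, tandem]
af = make_autofluorescence_endmember(panel)
noise = NoiseModel(multiplicative_cv=0.25, additive_sd=10.0)
fractions = {"Atto488": 0.2, "Atto647": 0.4, "Atto488_647": 0.6}

unstained, _ = simulate_event_table(
    ems, af, PopulationSpec(n_events=5000, noise=noise), "unstained", rng)
singles = []
for em in ems:
    t, _ = simulate_event_table(
        ems, af,
        PopulationSpec(n_events=5000,
                       fraction_positive={em.probe_id: fractions[em.probe_id]},
                       noise=noise),
        f"single:{em.probe_id}", rng)
    singles.append((t, em.probe_id))
triple, truth = simulate_event_table(
    ems, af, PopulationSpec(n_events=5000, fraction_positive=fractions, noise=noise),
    "multi:Atto488+Atto647+Atto488_647", rng)

# references from the data, exactly as one would from real exports
af_ref = mf.build_autofluorescence_reference(unstained)
probe_refs = []
for t, pid in singles:
    med = np.clip(np.median(t.intensities, axis=0) - af_ref.values, 0, None)
    chan = panel.channel_ids[int(np.argmax(med))]
    gate = mf.gate_positive(t, unstained, channel=chan)
    probe_refs.append(mf.build_reference_spectrum(t, gate, pid))
refs = mf.build_reference_matrix(probe_refs, af_ref)

spec = mf.specificity_matrix(singles, refs, unstained)
print("Single-stain specificity (median relative unmixed abundance):")
print(spec.round(3))
print(f"diagonal dominance margin: {mf.diagonal_dominance(spec):.3f}")
print()
print("% positive per probe (singly-stained, intensity gate vs unmixed gate):")
um_u = mf.unmix_events(unstained, refs)
for j, (t, pid) in enumerate(singles):
    gate = mf.gate_positive(t, unstained, channel="peak_channel",
                            reference=refs.column(pid))
    pct_um = mf.percent_positive_unmixed(mf.unmix_events(t, refs), pid, um_u)
    print(f"  {pid:<12} intensity {gate.percent_positive:5.2f}%   "
          f"unmixed {pct_um:5.2f}%   (simulated {100*fractions[pid]:.0f}%)")
print()
print("A diagonal-dominant matrix means each singly-stained sample's unmixed")
print("signal lands on its own probe; the tandem's unmixed gate reads low")
print("because its spectrum is a combination of its parents' spectra.")
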