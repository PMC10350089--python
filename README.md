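# musicflow

Spectral flow cytometry unmixing and fluorescence photophysics for
combination tandem-dye (MuSIC) probes.

Full-spectrum flow cytometry records an entire emission spectrum per cell,
so probes are identified by spectral *unmixing* rather than compensation.
Combination probes — two dyes on one oligonucleotide scaffold attached to an
antibody — promise many new spectrally unique labels, but they raise two
computational problems that this package solves for experimentalists and
analysts working with such panels:

1. **Deconvolution**: given per-cell channel intensities and reference
   spectra built from singly-stained and unstained controls, recover each
   cell's probe abundances, gate positive cells, and quantify specificity
   and % positive across single- and multi-stained samples.
2. **Photophysics**: given solution measurements of a probe (FCS
   correlation curves, polarized TCSPC decays), fit molecule number,
   diffusion and dark-state kinetics, fluorescence lifetimes and rotational
   times, and decompose an observed intensity difference between probe
   architectures into dynamic vs static quenching.

## The core models

Per event `y` (one vector of channel intensities), unmixing solves

```
min_x ||R x − y||₂   subject to x ≥ 0
```

where `R` stacks one reference spectrum per probe plus an autofluorescence
column (per-channel medians of gated-positive singly-stained cells and of
unstained cells, respectively).

FCS correlation curves are fitted to a 3-D Gaussian diffusion model with two
dark-state terms,

```
G(t) = G∞ + (1/N) · [1/(1+t/t_diff)] · [1/(1+t/(ω₀·t_diff))]
            · (1−A_T1+A_T1·e^(−t/t_T1)) · (1−A_T2+A_T2·e^(−t/t_T2))
```

and molecular brightness is (count rate − background)/N. TCSPC decays are
IRF-convolved multi-exponentials I(t) = Σ Aₙ e^(−t/τₙ) with χ²-based
selection of the component count; the species-average lifetime is
⟨τ⟩ₓ = Σ Aₙ·τₙ. Time-resolved anisotropy is
r(t) = (I∥ − G·I⊥)/(I∥ + 2G·I⊥), fitted to r(t) = r∞ + (r0−r∞)e^(−t/τᵣ).
The fold of an intensity ratio not explained by the brightness ratio is the
static-quenching factor. See `docs/methods.md` for assumptions, numerical
choices, and known limitations.

A synthetic-data layer (`musicflow.simulate`) generates all three input
classes — event tables, correlation curves, polarized decay pairs — with
known ground truth and seeded reproducibility.

## Worked example

`examples/lifetime_quenching.py` simulates polarized decay pairs for the
internal ("int.", internally labeled oligo) and external ("ext.",
end-labeled oligo) probe configurations from their published
characterization parameters, refits them, and runs the quenching
decomposition:

```
ext. oligo complex: 2 lifetimes selected
    A = 0.57, tau = 4.00 ns
    A = 0.43, tau = 0.77 ns
    species-average lifetime <tau>_x = 2.61 ns (true 2.61)
    rotational time = 289 ps (true 280)

int. oligo complex: 2 lifetimes selected
    A = 0.68, tau = 3.99 ns
    A = 0.32, tau = 0.91 ns
    species-average lifetime <tau>_x = 3.01 ns (true 3.01)
    rotational time = 330 ps (true 350)

intensity fold (int/ext): 6.0
brightness fold (int/ext): 1.67
static quenching factor: 3.60  dark fraction: 0.72
```

Reading: the χ² rule selects two lifetime components per configuration and
recovers the generating amplitudes/lifetimes; the internal configuration's
longer species-average lifetime (3.01 vs 2.61 ns) means the external one
suffers more dynamic quenching, but dynamic effects (brightness fold 1.67)
explain only part of its 6-fold intensity deficit — the remaining 3.6-fold
is static quenching, i.e. ~72% of external-configuration fluorophores sit in
non-emitting ground-state complexes.

The other examples cover unmixing a three-probe panel with a tandem dye
(`examples/unmix_triple_stain.py`), gating/SNR and docking-strand fold
changes (`examples/gate_and_snr.py`), and FCS fitting with brightness
(`examples/fcs_brightness.py`). An end-to-end simulate→gate→reference→
unmix→report pipeline with a run manifest is available as
`musicflow.run_pipeline(config, out_dir)` plus `musicflow.render_reports`.

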