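# Methods

`musicflow` implements the computational analysis used to characterize and
deploy oligo-scaffolded combination (tandem-dye) fluorescent probes: spectral
unmixing of full-spectrum flow cytometry events, positivity gating and
%-positive estimation, and the solution photophysics (FCS, TCSPC lifetime,
time-resolved anisotropy) that separates static from dynamic quenching
between probe architectures. This note records the models, their
assumptions, the numerical choices, and what the synthetic-data layer does
and does not emulate.

## Spectral model and unmixing

Each cytometry event is a vector `y` of per-channel fluorescence intensities
("scale" values as exported from the acquisition software; they may be
negative after baseline subtraction, and raw events are never clipped). The
signal model is linear:

    y ≈ R x,   x ≥ 0

where the columns of `R` are endmember reference spectra — one per probe,
plus an autofluorescence (AF) column, always last. Per event we solve the
non-negative least-squares problem

    min_x ‖R x − y‖₂   s.t.  x ≥ 0

independently for every cell (no shrinkage across cells), via the
Lawson–Hanson NNLS solver (`scipy.optimize.nnls`). The per-event residual
norm is reported as a QC diagnostic for events poorly explained by the
panel. Collinear or ill-conditioned reference columns produce a warning with
the condition number rather than an error, because near-collinearity
degrades abundances without invalidating the solve itself.

Reference spectra are built from controls:

- **probe column**: per-channel median over *positive* events of the
  singly-stained sample for that probe;
- **AF column**: per-channel median over *all* unstained events.

Negative channel medians are clipped to zero so the design matrix is
non-negative. Positivity for reference building uses the same marker-gate
rule as everywhere else: threshold = the `gate_quantile` quantile (default
0.999) of the unstained distribution at the gating channel, with events
strictly above it positive. The gating channel defaults to the probe's peak
channel. The 0.999 default approximates a manual marker gate placed just
beyond the unstained cloud; on null data the false-positive rate is
1 − gate_quantile by construction, which the tests verify.

Downstream analyses mirror the standard single- vs multi-stain workflow:

- **normalized comparison**: each cell's raw value at the probe's peak
  channel divided by the positive group's median fluorescence intensity
  (MFI) at that channel, against its unmixed value divided by the positive
  group's median unmixed value; on noiseless single-probe data the two
  coincide exactly (correlation 1, slope 1).
- **specificity matrix**: rows = stained probe, columns = reported
  endmember; entry (i, j) is the median over probe-i positive events of
  endmember j's relative unmixed abundance (share of the summed non-AF
  signal). Perfect unmixing gives the identity matrix; the summary statistic
  is the worst-row margin min_i [diag(i) − max off-diag(i)].
- **unmixed positivity**: % of events whose unmixed abundance for an
  endmember exceeds the `gate_quantile` quantile of the unstained sample's
  unmixed abundances for that endmember (the same quantile rule as
  intensity gating, for comparability).
- **single vs multi-stain comparison**: Welch two-sample t-tests on
  replicate %-positive values per probe, reporting means ± SE and two-sided
  p-values. Replicates with exactly zero variance in both conditions are
  handled as a degenerate perfect null (p = 1 when means agree).

SNR is median positive stained intensity ÷ median unstained intensity at the
gating channel by default; a robust-sd variant (median ÷ 1.4826·MAD) is
selectable. The median/median definition is used because it is scale-robust;
it is a configuration enum because no single definition is canonical.

## Photophysics

**FCS.** Correlation curves are modeled as diffusion through a 3-D Gaussian
focus with two reversible dark ("triplet-like") states:

    G(t) = G∞ + (1/N) · 1/(1 + t/t_diff) · 1/(1 + t/(ω₀·t_diff))
               · (1 − A_T1 + A_T1 e^(−t/t_T1)) · (1 − A_T2 + A_T2 e^(−t/t_T2))

with N the mean number of bright molecules in the focus, `t_diff` the
diffusion time (ms), ω₀ the calibrated geometry parameter (fixed during
fits, default 4.73 from a Rhodamine 110 calibration), dark fractions
A_T1/A_T2 and dark times t_T1 (µs) / t_T2 (ms). Two printed-form ambiguities
are resolved explicitly and exposed as flags:

- the two dark-state factors **multiply** by default (independent blinking
  processes); an additive variant (1 − A₁ − A₂ + A₁e₁ + A₂e₂) is available
  via `additive_triplets=True` — the two coincide whenever one amplitude is
  zero, which the tests check;
- the axial factor carries **no square root** by default; the conventional
  sqrt form is available via `axial_sqrt=True`.

Fits minimize Σ[(G_obs − G_model)/σ]² with per-lag σ when available
(uniform otherwise), via Levenberg–Marquardt (lmfit), multi-started from
log-normally perturbed initial guesses (default 5 starts, deterministic for
a given seed); the best χ² wins, reduced χ² = χ²/(points − free parameters)
is reported, and parameters pinned at bounds are flagged. The analytic
identities G(0) = G∞ + 1/N and G(∞) = G∞ hold exactly in the model
evaluation. Molecular brightness is the standard counts-per-molecule
definition (count rate − background)/N in kHz/molecule; the formula is
adopted because no alternative is in common use. The diffusion-coefficient
conversion D = w²/(4·t_diff) requires a user-supplied beam waist and is
deliberately not validated against any published value.

**TCSPC lifetimes.** Decays are multi-exponential,
I(t) = Σ A_n e^(−t/τ_n), convolved with the instrument response (a measured
trace or a Gaussian of configurable width; width 0 means a delta). Linear,
non-periodic discrete convolution is used on a default 25 ns window — one
period of a 40 MHz excitation laser — so pile-up from preceding pulses is
ignored by design. Fits are iterative reconvolution with Poisson weights
1/√max(counts, 1), parameterized by absolute per-component amplitudes (this
avoids the sloppy scale/fraction degeneracy of a normalized
parameterization; fractions A_n are normalized afterward for reporting,
longest lifetime first). Model selection fits n = 1..max_components and
keeps the smallest n beyond which reduced χ² improves by ≤ 5% — a pragmatic
reading of "minimum number of free parameters that minimizes χ²" that avoids
an arbitrary F-test; two lifetimes within 5% of each other collapse to the
reduced model, and a χ² floor guards the noiseless case where ratios of
near-zero χ² are meaningless. The species-average lifetime is the
amplitude-weighted mean ⟨τ⟩ₓ = Σ A_n τ_n (requires Σ A_n = 1; always lies
between the extreme component lifetimes).

**Anisotropy.** The polarized pair gives
r(t) = (I∥ − G·I⊥)/(I∥ + 2G·I⊥) with the G-factor correcting
detection-channel sensitivity (default 1.04). Bins whose denominator falls
below a count floor are masked rather than reported as noise-dominated
ratios. r(t) is fitted to r(t) = r∞ + (r0 − r∞)e^(−t/τ_r) (τ_r in ps), with
r∞ optionally pinned at 0; the fit should start at or after the excitation
pulse (`t_start` ≈ IRF position + a few σ) because earlier bins carry an
IRF-dominated ratio. A constant series leaves τ_r unidentifiable and is
returned flagged degenerate instead of fitted.

**Quenching decomposition.** FCS sees only bright molecules, so the
molecular-brightness ratio between two probe configurations bounds the
dynamic-quenching contribution to their steady-state intensity ratio. The
residual fold, static_factor = intensity_ratio / brightness_ratio, is
attributed to static quenching (ground-state dark complexes removing
molecules from the bright pool), and dark_fraction = 1 −
brightness_ratio/intensity_ratio is the implied non-observable fraction in
the dimmer configuration. The identity static_factor × brightness_ratio =
intensity_ratio holds by construction. With the characterized values — a
6-fold intensity gap and a 13.5/8.1 ≈ 1.67-fold brightness gap — the static
factor is 3.6 with a 72% dark fraction.

## Synthetic data

Every input class is generated with known ground truth so the full pipeline
is testable without instrument data; all randomness flows through one
explicit `numpy.random.Generator`, and the same seed is bit-reproducible.

- **Endmembers**: discretized log-normal peak over channel index (unit peak,
  asymmetric red tail resembling dye emission), peak placed exactly at the
  requested channel; default shape width 0.18 in log-channel units.
  Combination (tandem) probes are convex combinations of their two parents
  with an acceptor-weight mix parameter, renormalized to unit peak — a
  FRET-mixing abstraction; explicit donor-quenching/acceptor-sensitization
  kinetics are not modeled.
- **Events**: abundance per probe drawn log-normal (median = the probe's
  brightness scale, default cv 0.4) for the Bernoulli-positive subset,
  zero otherwise; AF abundance log-normal for every cell (median 50, cv
  0.3); clean intensities Σ a_p S_p + a_AF S_AF are then multiplied by a
  median-1 log-normal factor per channel (cv 0.25) and given additive
  Gaussian detector noise (default 1% of the positive peak brightness).
  This reproduces broad log-scale cytometry histograms without modeling
  detector electronics, spillover physics, doublets, or scatter gating.
- **FCS curves**: the model evaluated on a log-spaced lag grid (default 120
  lags, 10⁻⁴–10² ms) plus Gaussian noise with a multi-tau-like
  heteroscedastic proxy sd = s·(1 + G)·√(lag/T), T = 120 s (a 2-minute
  acquisition); no photon-by-photon diffusion simulation.
- **Polarized decays**: the isotropic decay is split as I∥ = I(1 + 2r)/3,
  I⊥ = I(1 − r)/3 *before* IRF convolution, the detected perpendicular
  channel is attenuated by 1/G so the anisotropy estimator with that
  G-factor recovers r(t), and photon counts are Poisson per bin.

Because the acquisition noise magnitudes were never published, these
defaults are stand-ins chosen once as plausible study conditions; all are
configurable. Passing tests therefore demonstrate correctness of the
algorithms under a realistic noise family, not performance on any particular
instrument.

## Known limitations

- **Tandem-probe identifiability.** A combination endmember that is an
  exact convex combination of its parents lies in their span, so when both
  parents are also panel columns the per-event NNLS split between "tandem"
  and "parents" is decided by noise, not signal. With reference spectra
  estimated from data, the tandem's unmixed-gate %-positive systematically
  undercounts (order 5–15% of its events split onto the parents at default
  noise) while intensity gating on the same sample is unbiased; in
  multi-stained samples the parent dyes correspondingly overcount. This is
  a property of the linear model, not of the solver — real tandem-stained
  samples show the analogous single- vs multi-stain discrepancy — and it is
  asserted as expected behavior in the test suite.
- FCS fitting with two dark states whose slow time approaches the diffusion
  time is weakly identified at high noise; the multi-start budget and the
  at-bounds flags surface this rather than hide it.
- No FCS-file (binary .fcs) writer, no vendor project-file parsing, no
  compensation/spillover handling (full-spectrum unmixing only), no
  quantum-yield estimation, and no time-tagged photon-stream correlation;
  CSV is the canonical interchange and binary FCS ingestion can be layered
  behind the same `EventTable` contract by an optional third-party parser.

## Problem sizes in the shipped tests

The test suite runs the full statistical checks at deliberately compact
sizes chosen as the package's reference conditions: 5 000 events per
simulated cytometry sample (10 000 where a binomial CI is the object under
test), 120-lag correlation curves, 500-bin decay histograms at 10⁶ counts,
50 Monte-Carlo replicates for noisy parameter-recovery medians, and 100
random problems for the NNLS-vs-grid-search oracle equivalence. The
end-to-end pipeline demo uses three probes (two singles plus one tandem) at
2 000–5 000 events per sample.
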