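"""Synthetic-data generators with known ground truth for every input class.

Three input classes are emulated: spectral cytometry event tables
(non-negative combinations of probe endmember spectra plus autofluorescence,
with positive/negative subpopulations and multiplicative log-normal +
additive Gaussian detector noise), FCS correlation curves (the correlation
model plus heteroscedastic noise), and polarized TCSPC decay histograms
(IRF-convolved multi-exponentials with Poisson counting noise).

All randomness flows through an explicit :class:`numpy.random.Generator`;
the same seed reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ChannelPanel, EventTable
from .gating import AUTOFLUORESCENCE_ID
from .photophysics import (
    AnisotropyParams,
    CorrelationCurve,
    DecayParams,
    DecayTrace,
    FcsParams,
    decay_model_eval,
    fcs_model_eval,
    gaussian_irf_kernel,
)

__all__ = [
    "ProbeEndmember",
    "NoiseModel",
    "PopulationSpec",
    "FcsSimSpec",
    "DecaySimSpec",
    "make_endmember",
    "combine_endmembers",
    "make_autofluorescence_endmember",
    "simulate_event_table",
    "simulate_fcs_curve",
    "simulate_decay_pair",
]


# --------------------------------------------------------------------------
# spectral events
# --------------------------------------------------------------------------

@dataclass
class ProbeEndmember:
    """Unit-peak emission signature of one probe over a channel panel.

    ``brightness_scale`` is the expected peak-channel intensity of a positive
    cell carrying this probe.
    """

    probe_id: str
    spectrum: np.ndarray
    panel: ChannelPanel
    brightness_scale: float = 1000.0

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if self.spectrum.shape != (self.panel.n_channels,):
            raise ValueError("spectrum length must match panel")
        if np.any(self.spectrum < 0):
            raise ValueError("endmember spectrum must be non-negative")
        if not np.isclose(self.spectrum.max(), 1.0):
            raise ValueError("endmember spectrum must be normalized to unit peak")


def make_endmember(
    probe_id: str,
    peak_channel_index: int,
    panel: ChannelPanel,
    shape_width: float = 0.18,
    brightness_scale: float = 1000.0,
    donor_acceptor_mix: float | None = None,
    parents: tuple[ProbeEndmember, ProbeEndmember] | None = None,
) -> ProbeEndmember:
    """Build a probe endmember spectrum.

    Single probes get a discretized log-normal peak over channel index (an
    asymmetric shape with a red tail, like real dye emission); the peak sits
    exactly at ``peak_channel_index``. A combination (tandem) probe is the
    convex combination of its two ``parents`` with acceptor weight
    ``donor_acceptor_mix`` (0 reproduces the donor parent exactly),
    renormalized to unit peak.
    """
    if donor_acceptor_mix is not None:
        if parents is None:
            raise ValueError("combination probes need their two parent endmembers")
        return combine_endmembers(
            probe_id, parents[0], parents[1], donor_acceptor_mix, brightness_scale
        )
    if not 0 <= peak_channel_index < panel.n_channels:
        raise ValueError(
            f"peak channel index {peak_channel_index} out of range for "
            f"{panel.n_channels}-channel panel"
        )
    x = np.arange(1, panel.n_channels + 1, dtype=float)
    x0 = float(peak_channel_index + 1)
    spectrum = np.exp(-np.log(x / x0) ** 2 / (2.0 * shape_width**2))
    spectrum = spectrum / spectrum.max()
    return ProbeEndmember(probe_id, spectrum, panel, brightness_scale)


def combine_endmembers(
    probe_id: str,
    donor: ProbeEndmember,
    acceptor: ProbeEndmember,
    mix: float,
    brightness_scale: float | None = None,
) -> ProbeEndmember:
    """Convex combination of two parent spectra (a tandem-probe abstraction).

    ``mix`` is the acceptor weight in [0, 1]; explicit donor-quenching /
    acceptor-sensitization kinetics are not modeled.
    """
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must lie in [0, 1]")
    if donor.panel.channel_ids != acceptor.panel.channel_ids:
        raise ValueError("parent endmembers must share the panel")
    spectrum = (1.0 - mix) * donor.spectrum + mix * acceptor.spectrum
    spectrum = spectrum / spectrum.max()
    if brightness_scale is None:
        brightness_scale = (1.0 - mix) * donor.brightness_scale + mix * acceptor.brightness_scale
    return ProbeEndmember(probe_id, spectrum, donor.panel, brightness_scale)


def make_autofluorescence_endmember(
    panel: ChannelPanel, decay_rate: float = 0.12
) -> ProbeEndmember:
    """Broad, blue-weighted autofluorescence signature (unit peak at channel 0)."""
    x = np.arange(panel.n_channels, dtype=float)
    spectrum = np.exp(-decay_rate * x)
    return ProbeEndmember(AUTOFLUORESCENCE_ID, spectrum / spectrum.max(), panel, 1.0)


@dataclass
class NoiseModel:
    """Detector noise: per-channel multiplicative log-normal (median 1) plus
    additive Gaussian in intensity units."""

    multiplicative_cv: float = 0.25
    additive_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0 or self.additive_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass
class PopulationSpec:
    """Stained-cell population: which probes are present, at what abundance.

    Per probe: ``fraction_positive`` in [0, 1] and a log-normal abundance
    distribution with median ``abundance_median`` (defaults to the
    endmember's brightness_scale) and coefficient of variation
    ``abundance_cv``. Every cell carries autofluorescence with median
    ``autofluorescence_level``.
    """

    n_events: int
    fraction_positive: dict[str, float] = field(default_factory=dict)
    abundance_median: dict[str, float] = field(default_factory=dict)
    abundance_cv: float = 0.4
    autofluorescence_level: float = 50.0
    autofluorescence_cv: float = 0.3
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        for pid, f in self.fraction_positive.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction_positive[{pid!r}] must lie in [0, 1]")
        if self.abundance_cv < 0 or self.autofluorescence_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")


def _lognormal(rng: np.random.Generator, median: float, cv: float, size: int) -> np.ndarray:
    """Log-normal draws parameterized by median and coefficient of variation."""
    if median <= 0:
        return np.zeros(size)
    if cv == 0:
        return np.full(size, median)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(np.log(median), sigma, size=size))


def simulate_event_table(
    endmembers: list[ProbeEndmember],
    autofluorescence: ProbeEndmember,
    population: PopulationSpec,
    condition: str,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> tuple[EventTable, np.ndarray]:
    """Simulate an event table; returns ``(table, ground_truth)``.

    Each event's clean intensity vector is sum_p a_p * S_p + a_AF * S_AF;
    negative cells draw a_p = 0. The noise model then multiplies each channel
    by a median-1 log-normal factor and adds Gaussian detector noise.
    ``ground_truth`` has one abundance column per probe plus a final
    autofluorescence column, ordered like ``endmembers``.
    """
    panel = autofluorescence.panel
    for em in endmembers:
        if em.panel.channel_ids != panel.channel_ids:
            raise ValueError("all endmembers must share the panel")
    n = population.n_events
    k = len(endmembers)
    truth = np.zeros((n, k + 1))
    for j, em in enumerate(endmembers):
        frac = population.fraction_positive.get(em.probe_id, 0.0)
        positive = rng.random(n) < frac
        median = population.abundance_median.get(em.probe_id, em.brightness_scale)
        amounts = _lognormal(rng, median, population.abundance_cv, n)
        truth[:, j] = np.where(positive, amounts, 0.0)
    truth[:, k] = _lognormal(
        rng, population.autofluorescence_level, population.autofluorescence_cv, n
    )
    shapes = np.vstack([em.spectrum for em in endmembers] + [autofluorescence.spectrum])
    clean = truth @ shapes
    noise = population.noise
    if noise.multiplicative_cv > 0:
        sigma = np.sqrt(np.log1p(noise.multiplicative_cv**2))
        clean = clean * np.exp(rng.normal(0.0, sigma, size=clean.shape))
    if noise.additive_sd > 0:
        clean = clean + rng.normal(0.0, noise.additive_sd, size=clean.shape)
    table = EventTable(panel=panel, intensities=clean, condition=condition, sample_id=sample_id)
    return table, truth


# --------------------------------------------------------------------------
# FCS curves
# --------------------------------------------------------------------------

@dataclass
class FcsSimSpec:
    """FCS simulation: model parameters, log-spaced lag grid (ms) and a
    multi-tau-like heteroscedastic noise proxy.

    The per-lag noise sd is ``sd_scale * (1 + G(lag)) * sqrt(lag / total_time)``
    — fewer independent averaging intervals at long lags means more noise
    there. ``sd_scale = 0`` gives a noiseless curve. ``total_time_ms``
    defaults to a 2-minute acquisition.
    """

    params: FcsParams
    lag_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-4, 1e2, 120)
    )
    sd_scale: float = 1.0
    total_time_ms: float = 120_000.0

    def __post_init__(self) -> None:
        self.lag_grid = np.asarray(self.lag_grid, dtype=float)
        if np.any(self.lag_grid <= 0) or not np.all(np.diff(self.lag_grid) > 0):
            raise ValueError("lag grid must be positive and strictly increasing")

    def noise_sd(self, g: np.ndarray) -> np.ndarray:
        return self.sd_scale * (1.0 + g) * np.sqrt(self.lag_grid / self.total_time_ms)


def simulate_fcs_curve(spec: FcsSimSpec, rng: np.random.Generator) -> CorrelationCurve:
    """Model curve on the lag grid plus zero-mean Gaussian noise with the
    spec's per-lag sd; noiseless when ``sd_scale = 0``."""
    g = fcs_model_eval(spec.lag_grid, spec.params)
    sd = spec.noise_sd(g)
    noisy = g + rng.normal(0.0, 1.0, size=g.shape) * sd if spec.sd_scale > 0 else g
    return CorrelationCurve(lag=spec.lag_grid.copy(), g=noisy, sd=sd if spec.sd_scale > 0 else None)


# --------------------------------------------------------------------------
# polarized decays
# --------------------------------------------------------------------------

@dataclass
class DecaySimSpec:
    """Polarized TCSPC simulation.

    Defaults: 25 ns window (one period of a 40 MHz pulsed laser; pile-up from
    preceding pulses is ignored), Gaussian IRF, Poisson counting noise split
    between the parallel and perpendicular detection channels with the
    perpendicular channel attenuated by the G-factor.
    """

    params: DecayParams
    anisotropy: AnisotropyParams | None = None
    irf_center_ns: float = 2.0
    irf_width_ns: float = 0.1
    window_ns: float = 25.0
    n_bins: int = 500
    total_counts: float = 1e6
    g_factor: float = 1.04
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.total_counts <= 0:
            raise ValueError("total_counts must be positive")
        if self.n_bins < 2 or self.window_ns <= 0:
            raise ValueError("need a positive window with at least 2 bins")

    @property
    def time(self) -> np.ndarray:
        dt = self.window_ns / self.n_bins
        return np.arange(self.n_bins) * dt


def simulate_decay_pair(
    spec: DecaySimSpec, rng: np.random.Generator
) -> tuple[DecayTrace, DecayTrace]:
    """Simulate the (parallel, perpendicular) polarized decay pair.

    The isotropic decay I(t) is split as Ipar = I(t)(1 + 2r(t))/3 and
    Iperp = I(t)(1 − r(t))/3 before IRF convolution; the detected
    perpendicular channel is attenuated by 1/G so that the anisotropy
    estimator with the spec's G-factor recovers r(t). Photon counts are drawn
    Poisson per bin (expectations returned when ``poisson`` is off).
    """
    t = spec.time
    iso = np.zeros_like(t)
    for a, tau in spec.params.components:
        iso += a * np.exp(-t / tau)
    if spec.anisotropy is not None:
        p = spec.anisotropy
        tau_ns = p.tau_r * 1e-3
        r = p.r_inf + (p.r0 - p.r_inf) * np.exp(-t / tau_ns)
    else:
        r = np.zeros_like(t)
    par = iso * (1.0 + 2.0 * r) / 3.0
    perp = iso * (1.0 - r) / 3.0
    if np.any(par < 0) or np.any(perp < 0):
        raise ValueError("anisotropy magnitude drives a polarized component negative")
    kernel = gaussian_irf_kernel(t, spec.irf_center_ns, spec.irf_width_ns)
    par = np.convolve(par, kernel)[: t.size]
    perp = np.convolve(perp, kernel)[: t.size] / spec.g_factor
    scale = spec.total_counts / (par.sum() + perp.sum())
    par_exp, perp_exp = par * scale, perp * scale
    if spec.poisson:
        par_counts = rng.poisson(par_exp).astype(float)
        perp_counts = rng.poisson(perp_exp).astype(float)
    else:
        par_counts, perp_counts = par_exp, perp_exp
    return (
        DecayTrace(time=t.copy(), counts=par_counts, polarization="parallel"),
        DecayTrace(time=t.copy(), counts=perp_counts, polarization="perpendicular"),
    )
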