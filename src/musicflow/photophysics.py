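"""Fluorescence photophysics: FCS correlation, TCSPC lifetime and anisotropy.

Models
------
FCS autocorrelation of freely diffusing emitters through a 3-D Gaussian
focus with two reversible dark (triplet-like) states::

    G(tc) = G_inf + (1/N) * 1/(1 + tc/t_diff) * 1/(1 + tc/(omega0*t_diff))
                  * (1 - A_T1 + A_T1*exp(-tc/t_T1))
                  * (1 - A_T2 + A_T2*exp(-tc/t_T2))

with N the mean number of bright molecules in the focus, t_diff the
diffusion time and omega0 the calibrated axial/lateral geometry parameter.
The two dark-state factors multiply (independent blinking processes); an
additive variant and a square-root axial term are available as flags.

Fluorescence decay is a sum of exponentials convolved with the instrument
response, I(t) = sum_n A_n exp(-t/tau_n) (x) IRF, with the species-average
lifetime <tau>_x = sum_n A_n tau_n (amplitude-weighted, sum A_n = 1).

Time-resolved anisotropy from the polarized decay pair:
r(t) = (Ipar - G*Iperp) / (Ipar + 2*G*Iperp), fitted to
r(t) = r_inf + (r0 - r_inf) exp(-t/tau_r).

Steady-state intensity ratios in excess of the molecular-brightness ratio
are attributed to static quenching (ground-state dark complexes remove
molecules from the bright pool without shortening the lifetime of the
remainder).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

__all__ = [
    "CorrelationCurve",
    "FcsParams",
    "FcsFitResult",
    "DecayTrace",
    "DecayParams",
    "DecayFitResult",
    "AnisotropySeries",
    "AnisotropyParams",
    "AnisotropyFitResult",
    "QuenchingDecomposition",
    "fcs_model_eval",
    "fit_fcs",
    "molecular_brightness",
    "decay_model_eval",
    "gaussian_irf_kernel",
    "anisotropy_compute",
    "fit_anisotropy",
    "fit_decay",
    "species_average_lifetime",
    "quenching_decomposition",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class CorrelationCurve:
    """FCS correlation curve: lag (ms, strictly increasing, > 0) vs G."""

    lag: np.ndarray
    g: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lag.shape != self.g.shape or self.lag.ndim != 1:
            raise ValueError("lag and g must be 1-D arrays of equal length")
        if np.any(self.lag <= 0) or not np.all(np.diff(self.lag) > 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not (np.all(np.isfinite(self.lag)) and np.all(np.isfinite(self.g))):
            raise ValueError("curve values must be finite")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.lag.shape:
                raise ValueError("sd must match lag length")


@dataclass(frozen=True)
class FcsParams:
    """FCS model parameters.

    n: mean bright molecules in the focus; t_diff: diffusion time (ms);
    omega: geometric parameter omega0; g_inf: long-lag baseline;
    a_t1/a_t2: dark-state fractions; t_t1: fast dark time (us);
    t_t2: slow dark time (ms).
    """

    n: float
    t_diff: float
    omega: float = 4.73
    g_inf: float = 0.0
    a_t1: float = 0.0
    a_t2: float = 0.0
    t_t1: float = 1.0
    t_t2: float = 0.1

    def __post_init__(self) -> None:
        if self.n <= 0 or self.t_diff <= 0 or self.omega <= 0:
            raise ValueError("n, t_diff and omega must be positive")
        if not (0 <= self.a_t1 < 1 and 0 <= self.a_t2 < 1):
            raise ValueError("dark-state fractions must lie in [0, 1)")
        if self.t_t1 <= 0 or self.t_t2 <= 0:
            raise ValueError("dark times must be positive")


@dataclass
class DecayTrace:
    """TCSPC decay histogram: uniform time bins (ns) vs photon counts."""

    time: np.ndarray
    counts: np.ndarray
    polarization: str = "combined"  # parallel | perpendicular | combined

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.time.shape != self.counts.shape or self.time.ndim != 1:
            raise ValueError("time and counts must be 1-D arrays of equal length")
        dt = np.diff(self.time)
        if self.time.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time bins must be uniform and increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.polarization not in ("parallel", "perpendicular", "combined"):
            raise ValueError(f"unknown polarization {self.polarization!r}")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class DecayParams:
    """Multi-exponential decay: normalized amplitude fractions and lifetimes (ns)."""

    components: tuple[tuple[float, float], ...]  # (A_n, tau_n)

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("need at least one decay component")
        a = np.array([c[0] for c in self.components])
        tau = np.array([c[1] for c in self.components])
        if np.any(a < 0):
            raise ValueError("amplitude fractions must be non-negative")
        if np.any(tau <= 0):
            raise ValueError("lifetimes must be positive")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def lifetimes(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def species_avg_lifetime(self) -> float:
        return species_average_lifetime(self)


@dataclass(frozen=True)
class AnisotropyParams:
    """Single-exponential anisotropy decay with residual offset.

    r0: initial anisotropy; r_inf: residual anisotropy; tau_r: rotational
    correlation time (ps); g_factor: detection-channel sensitivity ratio.
    """

    r0: float
    tau_r: float
    r_inf: float = 0.0
    g_factor: float = 1.04

    def __post_init__(self) -> None:
        if self.tau_r <= 0:
            raise ValueError("rotational time must be positive")
        if abs(self.r0) > 1:
            raise ValueError("|r0| must be <= 1")


@dataclass
class AnisotropySeries:
    """Pointwise anisotropy r(t) with a validity mask (count-floor filtered bins)."""

    time: np.ndarray
    r: np.ndarray
    valid: np.ndarray


@dataclass
class FcsFitResult:
    params: FcsParams
    chi2: float
    red_chi2: float
    n_points: int
    n_free: int
    at_bounds: list[str]
    success: bool


@dataclass
class DecayFitResult:
    params: DecayParams
    scale: float
    chi2: float
    red_chi2: float
    n_components: int
    red_chi2_by_n: dict[int, float]


@dataclass
class AnisotropyFitResult:
    params: AnisotropyParams
    chi2: float
    red_chi2: float
    degenerate: bool = False


@dataclass(frozen=True)
class QuenchingDecomposition:
    """Split of a steady-state intensity fold change into static and dynamic parts.

    intensity_ratio: steady-state intensity fold (e.g. int/ext);
    brightness_ratio: per-bright-molecule brightness fold from FCS;
    static_factor: the residual fold attributable to static (dark-complex)
    quenching, intensity_ratio / brightness_ratio;
    dark_fraction: fraction of the dimmer configuration's molecules rendered
    non-observable, 1 - brightness_ratio/intensity_ratio.
    """

    intensity_ratio: float
    brightness_ratio: float

    def __post_init__(self) -> None:
        if self.intensity_ratio <= 0 or self.brightness_ratio <= 0:
            raise ValueError("ratios must be positive")

    @property
    def static_factor(self) -> float:
        return self.intensity_ratio / self.brightness_ratio

    @property
    def dark_fraction(self) -> float:
        return 1.0 - self.brightness_ratio / self.intensity_ratio


# --------------------------------------------------------------------------
# FCS
# --------------------------------------------------------------------------

def fcs_model_eval(
    lag: np.ndarray | float,
    p: FcsParams,
    axial_sqrt: bool = False,
    additive_triplets: bool = False,
) -> np.ndarray | float:
    """Evaluate the FCS correlation model at lag times (ms).

    ``lag = 0`` gives the analytic limit G(0) = G_inf + 1/N. The default
    triplet handling multiplies the two dark-state factors; with
    ``additive_triplets`` they form 1 - A1 - A2 + A1 e1 + A2 e2. With
    ``axial_sqrt`` the axial factor is 1/sqrt(1 + tc/(omega0^2 ... )) — here
    simply the square root of the default axial term, for sensitivity checks.
    """
    t = np.asarray(lag, dtype=float)
    if np.any(t < 0):
        raise ValueError("lag times must be non-negative")
    diff = 1.0 / (1.0 + t / p.t_diff)
    axial = 1.0 / (1.0 + t / (p.omega * p.t_diff))
    if axial_sqrt:
        axial = np.sqrt(axial)
    t_t1_ms = p.t_t1 * 1e-3  # fast dark time is specified in microseconds
    e1 = np.exp(-t / t_t1_ms)
    e2 = np.exp(-t / p.t_t2)
    if additive_triplets:
        dark = 1.0 - p.a_t1 - p.a_t2 + p.a_t1 * e1 + p.a_t2 * e2
    else:
        dark = (1.0 - p.a_t1 + p.a_t1 * e1) * (1.0 - p.a_t2 + p.a_t2 * e2)
    g = p.g_inf + (1.0 / p.n) * diff * axial * dark
    return g if np.ndim(lag) else float(g)


def _fcs_default_init(curve: CorrelationCurve, omega: float) -> FcsParams:
    g_inf = float(np.median(curve.g[-max(3, curve.g.size // 20):]))
    amp = max(float(curve.g[0]) - g_inf, 1e-6)
    half = g_inf + amp / 2.0
    below = np.nonzero(curve.g <= half)[0]
    t_diff = float(curve.lag[below[0]]) if below.size else float(curve.lag[-1] / 10)
    return FcsParams(
        n=1.0 / amp, t_diff=max(t_diff, float(curve.lag[0])), omega=omega,
        g_inf=g_inf, a_t1=0.15, a_t2=0.05, t_t1=1.0, t_t2=0.1,
    )


def fit_fcs(
    curve: CorrelationCurve,
    omega_fixed: float = 4.73,
    init: FcsParams | None = None,
    n_starts: int = 5,
    seed: int = 0,
    axial_sqrt: bool = False,
    additive_triplets: bool = False,
) -> FcsFitResult:
    """Weighted least-squares fit of the FCS model with multiple restarts.

    Free parameters: N, t_diff, G_inf, A_T1, A_T2, t_T1, t_T2; omega0 is
    fixed from calibration. Weights come from the per-lag sd when present
    (uniform otherwise). Starts are log-normally perturbed around the
    initial guess; the best chi-square wins. Deterministic for a given seed.
    """
    if curve.lag.size < 20:
        raise ValueError("need at least 20 lag points spanning dark-state and diffusion regimes")
    if init is None:
        init = _fcs_default_init(curve, omega_fixed)
    weights = None
    if curve.sd is not None and np.all(curve.sd > 0):
        weights = 1.0 / curve.sd

    def residual(params: lmfit.Parameters) -> np.ndarray:
        p = FcsParams(
            n=params["n"].value, t_diff=params["t_diff"].value, omega=omega_fixed,
            g_inf=params["g_inf"].value, a_t1=params["a_t1"].value,
            a_t2=params["a_t2"].value, t_t1=params["t_t1"].value,
            t_t2=params["t_t2"].value,
        )
        r = curve.g - fcs_model_eval(curve.lag, p, axial_sqrt, additive_triplets)
        return r * weights if weights is not None else r

    rng = np.random.default_rng(seed)
    lag_min, lag_max = float(curve.lag[0]), float(curve.lag[-1])
    best = None
    for start in range(max(1, n_starts)):
        factors = np.ones(7) if start == 0 else np.exp(rng.normal(0.0, 0.35, size=7))
        params = lmfit.Parameters()
        params.add("n", value=init.n * factors[0], min=1e-6, max=1e6)
        params.add("t_diff", value=init.t_diff * factors[1], min=lag_min / 10, max=lag_max * 10)
        params.add("g_inf", value=init.g_inf, min=-1.0, max=1.0)
        params.add("a_t1", value=min(init.a_t1 * factors[2], 0.9), min=0.0, max=0.999)
        params.add("a_t2", value=min(init.a_t2 * factors[3], 0.9), min=0.0, max=0.999)
        params.add("t_t1", value=init.t_t1 * factors[4], min=1e-3, max=1e3)  # us
        params.add("t_t2", value=init.t_t2 * factors[5], min=1e-5, max=lag_max)  # ms
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("FCS fit failed to converge in the multi-start budget")

    v = best.params.valuesdict()
    fitted = FcsParams(
        n=v["n"], t_diff=v["t_diff"], omega=omega_fixed, g_inf=v["g_inf"],
        a_t1=v["a_t1"], a_t2=v["a_t2"], t_t1=v["t_t1"], t_t2=v["t_t2"],
    )
    at_bounds = [
        name for name, par in best.params.items()
        if par.vary and (
            (par.min is not None and np.isfinite(par.min) and abs(par.value - par.min) <= 1e-9 * max(1, abs(par.min)))
            or (par.max is not None and np.isfinite(par.max) and abs(par.value - par.max) <= 1e-9 * max(1, abs(par.max)))
        )
    ]
    if at_bounds:
        warnings.warn(f"FCS fit parameters pinned at bounds: {at_bounds}", RuntimeWarning)
    n_free = best.nvarys
    red = best.chisqr / max(curve.lag.size - n_free, 1)
    return FcsFitResult(
        params=fitted, chi2=float(best.chisqr), red_chi2=float(red),
        n_points=curve.lag.size, n_free=n_free, at_bounds=at_bounds,
        success=bool(best.success),
    )


def molecular_brightness(count_rate: float, background_rate: float, n: float) -> float:
    """Counts per bright molecule (kHz/molecule): (count rate − background) / N."""
    if n <= 0:
        raise ValueError("molecule number must be positive")
    signal = count_rate - background_rate
    if signal <= 0:
        raise ValueError("count rate must exceed background")
    return signal / n


# --------------------------------------------------------------------------
# decay / anisotropy
# --------------------------------------------------------------------------

def gaussian_irf_kernel(time: np.ndarray, center: float, width: float) -> np.ndarray:
    """Discrete Gaussian instrument-response kernel on the trace's time grid.

    Normalized to unit sum; width is the Gaussian sigma in ns. A width of 0
    returns a delta kernel.
    """
    time = np.asarray(time, dtype=float)
    if width <= 0:
        k = np.zeros_like(time)
        k[int(np.argmin(np.abs(time - center)))] = 1.0
        return k
    k = np.exp(-0.5 * ((time - center) / width) ** 2)
    s = k.sum()
    if s <= 0:
        raise ValueError("IRF kernel vanishes on this time grid")
    return k / s


def decay_model_eval(
    time: np.ndarray,
    params: DecayParams,
    irf_kernel: np.ndarray | None = None,
    scale: float = 1.0,
    background: float = 0.0,
) -> np.ndarray:
    """Multi-exponential decay, optionally convolved with a discrete IRF.

    Linear (non-periodic) discrete convolution on the uniform grid; the
    default window of one laser period ignores pile-up from earlier pulses.
    """
    time = np.asarray(time, dtype=float)
    d = np.zeros_like(time)
    for a, tau in params.components:
        d += a * np.exp(-time / tau)
    if irf_kernel is not None:
        d = np.convolve(d, irf_kernel)[: time.size]
    return scale * d + background


def anisotropy_compute(
    parallel: DecayTrace,
    perpendicular: DecayTrace,
    g_factor: float = 1.04,
    count_floor: float = 10.0,
) -> AnisotropySeries:
    """Pointwise anisotropy r(t) = (Ipar − G·Iperp)/(Ipar + 2G·Iperp).

    Bins whose total (denominator) falls below ``count_floor`` are masked
    invalid rather than reported as noise-dominated ratios.
    """
    if parallel.time.shape != perpendicular.time.shape or not np.allclose(
        parallel.time, perpendicular.time
    ):
        raise ValueError("parallel and perpendicular traces must share the time axis")
    denom = parallel.counts + 2.0 * g_factor * perpendicular.counts
    valid = denom > count_floor
    r = np.zeros_like(denom)
    r[valid] = (parallel.counts[valid] - g_factor * perpendicular.counts[valid]) / denom[valid]
    return AnisotropySeries(time=parallel.time.copy(), r=r, valid=valid)


def fit_anisotropy(
    series: AnisotropySeries,
    init: AnisotropyParams | None = None,
    fix_r_inf: float | None = None,
    g_factor: float = 1.04,
    t_start: float | None = None,
) -> AnisotropyFitResult:
    """Least-squares fit of r(t) = r_inf + (r0 − r_inf)·exp(−t/tau_r).

    ``fix_r_inf`` pins the residual anisotropy (0 recovers the pure
    single-exponential reduction). ``t_start`` discards bins before the
    excitation pulse (set it at the IRF position — earlier bins carry an
    IRF-dominated ratio); the exponential clock starts at the first fitted
    bin. A constant series leaves tau_r unidentifiable and is returned
    flagged ``degenerate``.
    """
    keep = series.valid.copy()
    if t_start is not None:
        keep &= series.time >= t_start
    t = series.time[keep]
    r = series.r[keep]
    if t.size < 10:
        raise ValueError("need at least 10 usable anisotropy bins")
    if np.ptp(r) < 1e-12:
        c = float(r[0])
        return AnisotropyFitResult(
            params=AnisotropyParams(r0=c, tau_r=1.0, r_inf=c, g_factor=g_factor),
            chi2=0.0, red_chi2=0.0, degenerate=True,
        )
    if init is None:
        r0_guess = float(np.clip(r[0], -1, 1))
        tail = float(np.median(r[-max(3, r.size // 10):]))
        # crude 1/e crossing for the rotational time, in ps
        target = tail + (r0_guess - tail) / np.e
        sgn = 1.0 if r0_guess >= tail else -1.0
        below = np.nonzero(sgn * (r - target) <= 0)[0]
        tau_ns = float(t[below[0]] - t[0]) if below.size else float((t[-1] - t[0]) / 5)
        init = AnisotropyParams(
            r0=r0_guess, tau_r=max(tau_ns, 1e-3) * 1e3, r_inf=tail, g_factor=g_factor
        )
    params = lmfit.Parameters()
    params.add("r0", value=init.r0, min=-1.0, max=1.0)
    params.add("tau_r", value=init.tau_r, min=1e-2, max=1e7)  # ps
    if fix_r_inf is None:
        params.add("r_inf", value=init.r_inf, min=-1.0, max=1.0)
    else:
        params.add("r_inf", value=fix_r_inf, vary=False)

    t0 = t[0]

    def residual(p: lmfit.Parameters) -> np.ndarray:
        tau_ns = p["tau_r"].value * 1e-3
        model = p["r_inf"].value + (p["r0"].value - p["r_inf"].value) * np.exp(-(t - t0) / tau_ns)
        return r - model

    res = lmfit.minimize(residual, params, method="leastsq")
    v = res.params.valuesdict()
    red = res.chisqr / max(t.size - res.nvarys, 1)
    return AnisotropyFitResult(
        params=AnisotropyParams(r0=v["r0"], tau_r=v["tau_r"], r_inf=v["r_inf"], g_factor=g_factor),
        chi2=float(res.chisqr), red_chi2=float(red), degenerate=False,
    )


def _fit_decay_fixed_n(
    time: np.ndarray,
    counts: np.ndarray,
    weights: np.ndarray,
    irf_kernel: np.ndarray | None,
    n_components: int,
    fit_background: bool,
) -> tuple[DecayParams, float, float, float]:
    """One reconvolution fit at a fixed component count; returns (params, scale, chi2, red_chi2)."""
    t_span = time[-1] - time[0]
    peak = float(counts.max())
    # crude mean lifetime from the histogram's centroid seeds the tau spread
    centroid = float(np.sum(time * counts) / max(counts.sum(), 1.0))
    tau_mean = min(max(centroid, t_span / 100), t_span / 2)
    if n_components == 1:
        tau_guesses = np.array([tau_mean])
    else:
        tau_guesses = np.geomspace(tau_mean / 3, tau_mean * 3, n_components)
    params = lmfit.Parameters()
    # absolute per-component amplitudes (counts at t=0) avoid the
    # scale/fraction degeneracy of a normalized parameterization
    for i in range(n_components):
        params.add(f"amp{i}", value=peak / n_components, min=0.0)
        params.add(f"tau{i}", value=float(tau_guesses[::-1][i]), min=1e-4, max=10 * t_span)
    params.add("bg", value=0.0, min=0.0, vary=fit_background)

    def model_of(p: lmfit.Parameters) -> np.ndarray:
        d = np.zeros_like(time)
        for i in range(n_components):
            d += p[f"amp{i}"].value * np.exp(-time / p[f"tau{i}"].value)
        if irf_kernel is not None:
            d = np.convolve(d, irf_kernel)[: time.size]
        return d + p["bg"].value

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return (counts - model_of(p)) * weights

    res = lmfit.minimize(residual, params, method="leastsq")
    v = res.params.valuesdict()
    amps = np.array([v[f"amp{i}"] for i in range(n_components)])
    taus = np.array([v[f"tau{i}"] for i in range(n_components)])
    s = amps.sum()
    fracs = amps / s if s > 0 else np.full(n_components, 1.0 / n_components)
    order = np.argsort(-taus)  # longest lifetime first, matching convention
    dp = DecayParams(tuple((float(fracs[i]), float(taus[i])) for i in order))
    red = res.chisqr / max(time.size - res.nvarys, 1)
    return dp, float(s), float(res.chisqr), float(red)


def fit_decay(
    trace: DecayTrace,
    irf: DecayTrace | None = None,
    irf_center: float = 0.0,
    irf_width: float = 0.0,
    max_components: int = 3,
    improvement_threshold: float = 0.05,
    fit_background: bool = False,
    collapse_rtol: float = 0.05,
) -> DecayFitResult:
    """Iterative-reconvolution multi-exponential fit with chi-square model selection.

    Fits n = 1..max_components and keeps the smallest n beyond which the
    reduced chi-square (Poisson weights, 1/sqrt(max(counts, 1))) improves by
    less than ``improvement_threshold`` (fraction). Two lifetimes closer than
    ``collapse_rtol`` (relative) collapse to the reduced model. The IRF is a
    measured trace or a Gaussian (center/width in ns); width 0 means a delta.
    """
    if trace.counts.sum() < 1e3:
        warnings.warn("decay histogram has few counts; fit may be unstable", RuntimeWarning)
    if irf is not None:
        if not np.allclose(irf.time, trace.time):
            raise ValueError("measured IRF must share the trace's time axis")
        s = irf.counts.sum()
        if s <= 0:
            raise ValueError("IRF trace is empty")
        kernel = irf.counts / s
    elif irf_width > 0 or irf_center != 0.0:
        kernel = gaussian_irf_kernel(trace.time, irf_center, irf_width)
    else:
        kernel = None

    weights = 1.0 / np.sqrt(np.maximum(trace.counts, 1.0))
    fits: dict[int, tuple[DecayParams, float, float, float]] = {}
    red_by_n: dict[int, float] = {}
    selected = 1
    for n in range(1, max_components + 1):
        fits[n] = _fit_decay_fixed_n(trace.time, trace.counts, weights, kernel, n, fit_background)
        red_by_n[n] = fits[n][3]
        if n == 1:
            continue
        prev = red_by_n[n - 1]
        improvement = (prev - red_by_n[n]) / prev if prev > 0 else 0.0
        taus = fits[n][0].lifetimes
        collapsed = np.any(
            np.abs(np.diff(np.sort(taus))) < collapse_rtol * np.sort(taus)[1:]
        )
        if prev <= 1e-12 or improvement <= improvement_threshold or collapsed:
            break
        selected = n
    dp, scale, chi2, red = fits[selected]
    return DecayFitResult(
        params=dp, scale=scale, chi2=chi2, red_chi2=red,
        n_components=selected, red_chi2_by_n=red_by_n,
    )


def species_average_lifetime(params: DecayParams) -> float:
    """Amplitude-weighted species-average lifetime <tau>_x = sum A_n tau_n (ns).

    Requires normalized amplitude fractions (sum to 1 within 1e-6); always
    lies between the shortest and longest component lifetime.
    """
    a = params.amplitudes
    if abs(a.sum() - 1.0) > 1e-6:
        raise ValueError(f"amplitude fractions must sum to 1 (got {a.sum():.6g})")
    return float(np.sum(a * params.lifetimes))


def quenching_decomposition(
    intensity_ratio: float, brightness_ratio: float
) -> QuenchingDecomposition:
    """Decompose a steady-state intensity fold change into static vs dynamic parts.

    The molecular-brightness ratio (from FCS, which sees only bright
    molecules) bounds the dynamic contribution; the excess fold,
    intensity_ratio / brightness_ratio, is attributed to static quenching
    (ground-state dark complexes). The identity static_factor ×
    brightness_ratio == intensity_ratio holds by construction.
    """
    return QuenchingDecomposition(
        intensity_ratio=float(intensity_ratio), brightness_ratio=float(brightness_ratio)
    )
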