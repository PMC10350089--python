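"""Per-event non-negative least-squares spectral unmixing and downstream analyses.

Each cell's channel vector y is expressed as a non-negative combination of
endmember reference spectra (probes plus autofluorescence): solve
min ||R x - y||_2 subject to x >= 0 independently per event. Downstream:
intensity/unmixed normalization, single-stain specificity matrices,
unmixed-positivity percentages and single- vs triple-stain comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .datamodel import EventTable
from .gating import AUTOFLUORESCENCE_ID, GateResult, ReferenceMatrix, gate_positive

__all__ = [
    "UnmixResult",
    "NormalizedAbundance",
    "unmix_events",
    "normalize_abundances",
    "specificity_matrix",
    "diagonal_dominance",
    "percent_positive_unmixed",
    "compare_single_vs_triple",
]


@dataclass
class UnmixResult:
    """Per-event non-negative abundances against an endmember panel."""

    abundances: np.ndarray  # events × endmembers, >= 0
    residual_norm: np.ndarray  # per event, ||R x - y||
    endmember_ids: list[str]

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.residual_norm = np.asarray(self.residual_norm, dtype=float)
        if self.abundances.shape[1] != len(self.endmember_ids):
            raise ValueError("abundance columns must match endmember ids")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")

    def column(self, endmember_id: str) -> np.ndarray:
        try:
            j = self.endmember_ids.index(endmember_id)
        except ValueError:
            raise KeyError(f"endmember {endmember_id!r} not in unmix result") from None
        return self.abundances[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.abundances, columns=self.endmember_ids)
        df["residual_norm"] = self.residual_norm
        return df


@dataclass
class NormalizedAbundance:
    """The two per-cell normalizations used to compare raw intensity with
    unmixed signal.

    ``normalized_intensity``: the cell's raw value at the probe's peak
    channel divided by the positive group's MFI at that channel.
    ``normalized_unmixed``: the cell's unmixed value divided by the positive
    group's median unmixed value. Both have median 1 over the positive
    population by construction.
    """

    normalized_intensity: np.ndarray
    normalized_unmixed: np.ndarray
    peak_channel: str
    positive_mask: np.ndarray


def unmix_events(
    events: EventTable,
    refs: ReferenceMatrix,
    include_autofluorescence: bool = True,
    condition_warn: float = 1e6,
) -> UnmixResult:
    """Non-negative least-squares unmixing of every event against the references.

    Events are unmixed independently (no shrinkage across cells); the result
    is deterministic. Collinear or ill-conditioned reference columns trigger
    a warning with the condition number rather than a failure.
    """
    if events.panel.channel_ids != refs.panel.channel_ids:
        raise ValueError("event table and reference matrix use different panels")
    spectra = refs.spectra if include_autofluorescence else refs.spectra[:-1]
    ids = [s.probe_id for s in spectra]
    R = np.column_stack([s.values for s in spectra])
    if np.any(np.all(R == 0, axis=0)):
        raise ValueError("all-zero reference column")
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > condition_warn:
        warnings.warn(
            f"reference matrix is ill-conditioned (condition number {cond:.3g}); "
            "unmixed abundances for near-collinear endmembers are unreliable",
            RuntimeWarning,
        )
    n = events.n_events
    x = np.empty((n, R.shape[1]))
    rnorm = np.empty(n)
    for i in range(n):
        x[i], rnorm[i] = nnls(R, events.intensities[i])
    return UnmixResult(abundances=x, residual_norm=rnorm, endmember_ids=ids)


def normalize_abundances(
    events: EventTable,
    unmix: UnmixResult,
    gate: GateResult,
    probe_id: str,
    refs: ReferenceMatrix,
) -> NormalizedAbundance:
    """Normalize raw peak-channel intensity and unmixed signal by their
    positive-population medians.

    On noiseless single-probe data the two normalized quantities coincide
    exactly (the idealized intensity-vs-unmixed relation).
    """
    if gate.positive_mask.shape[0] != events.n_events:
        raise ValueError("gate was computed on a different event table")
    peak = refs.column(probe_id).peak_channel
    raw = events.channel(peak)
    unmixed = unmix.column(probe_id)
    pos = gate.positive_mask
    if not np.any(pos):
        raise ValueError("no positive events to normalize against")
    mfi = float(np.median(raw[pos]))
    med_unmixed = float(np.median(unmixed[pos]))
    if mfi == 0 or med_unmixed == 0:
        raise ValueError("zero positive-population median; no positive signal")
    return NormalizedAbundance(
        normalized_intensity=raw / mfi,
        normalized_unmixed=unmixed / med_unmixed,
        peak_channel=peak,
        positive_mask=pos,
    )


def specificity_matrix(
    singly_stained: list[tuple[EventTable, str]],
    refs: ReferenceMatrix,
    unstained: EventTable,
    gate_quantile: float = 0.999,
) -> pd.DataFrame:
    """Single-stain specificity: true probe (rows) × reported endmember (columns).

    Each singly-stained table is gated positive at its probe's peak channel
    against the unstained sample; entry (i, j) is the median, over probe-i
    positive events, of endmember j's relative unmixed abundance (its share
    of the summed non-autofluorescence signal). Perfectly specific unmixing
    gives the identity matrix.
    """
    probe_ids = [pid for pid in refs.endmember_ids if pid != AUTOFLUORESCENCE_ID]
    stained_ids = [pid for _, pid in singly_stained]
    missing = [pid for pid in probe_ids if pid not in stained_ids]
    if missing:
        raise ValueError(f"missing singly-stained sample for probe(s) {missing}")
    rows = {}
    for table, pid in singly_stained:
        gate = gate_positive(
            table, unstained, channel="peak_channel",
            gate_quantile=gate_quantile, reference=refs.column(pid),
        )
        if gate.n_positive == 0:
            raise ValueError(f"no positive events in the {pid!r} singly-stained sample")
        um = unmix_events(table, refs)
        probe_cols = np.column_stack([um.column(p) for p in probe_ids])
        totals = probe_cols.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(totals > 0, probe_cols / totals, 0.0)
        rows[pid] = np.median(share[gate.positive_mask], axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=probe_ids).loc[probe_ids]


def diagonal_dominance(matrix: pd.DataFrame) -> float:
    """Worst-case specificity margin: min over rows of diag − max off-diagonal."""
    m = matrix.to_numpy()
    margins = []
    for i in range(m.shape[0]):
        off = np.delete(m[i], i)
        margins.append(m[i, i] - (off.max() if off.size else 0.0))
    return float(min(margins))


def percent_positive_unmixed(
    unmix: UnmixResult,
    endmember_id: str,
    unstained_unmix: UnmixResult,
    gate_quantile: float = 0.999,
) -> float:
    """% of events whose unmixed abundance exceeds the unstained-sample quantile.

    The threshold reuses the same quantile rule as intensity gating, applied
    to the unstained sample's unmixed abundances for this endmember.
    """
    stained = unmix.column(endmember_id)
    background = unstained_unmix.column(endmember_id)
    threshold = float(np.quantile(background, gate_quantile))
    return 100.0 * float(np.mean(stained > threshold))


def compare_single_vs_triple(
    single: dict[str, list[float]], triple: dict[str, list[float]]
) -> pd.DataFrame:
    """Welch two-sample t-test of % positive between single- and multi-stain replicates.

    Returns per-probe means ± standard errors for each condition, the
    difference, and the two-sided p-value.
    """
    records = []
    for pid in single:
        a = np.asarray(single[pid], dtype=float)
        b = np.asarray(triple.get(pid, []), dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"need >= 2 replicates per condition for probe {pid!r}")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            # degenerate zero-variance replicates: identical means are a
            # perfect null, different means a certain difference
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        records.append({
            "probe": pid,
            "single_mean": a.mean(),
            "single_se": a.std(ddof=1) / np.sqrt(a.size),
            "triple_mean": b.mean(),
            "triple_se": b.std(ddof=1) / np.sqrt(b.size),
            "difference": b.mean() - a.mean(),
            "t_statistic": float(t),
            "p_value": float(p),
        })
    return pd.DataFrame.from_records(records).set_index("probe")
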