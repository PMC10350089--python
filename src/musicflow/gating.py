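"""Positivity gating, reference-spectrum construction and intensity summaries.

Reference spectra for each probe are the per-channel medians over positive
singly-stained cells; the autofluorescence reference is the per-channel
median over all unstained cells. Positive cells are those whose intensity at
the gating channel exceeds a high quantile (default 0.999) of the unstained
distribution — a marker gate placed just beyond the unstained cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ChannelPanel, EmissionSpectrum, EventTable, peak_intensity

__all__ = [
    "ReferenceSpectrum",
    "ReferenceMatrix",
    "GateResult",
    "gate_positive",
    "build_reference_spectrum",
    "build_autofluorescence_reference",
    "build_reference_matrix",
    "write_reference_matrix",
    "read_reference_matrix",
    "snr",
    "fold_change_with_docking",
]

AUTOFLUORESCENCE_ID = "autofluorescence"


@dataclass
class ReferenceSpectrum:
    """Per-channel median signature of one endmember (probe or autofluorescence).

    Values are clipped at zero so the unmixing design matrix is non-negative;
    raw events are never clipped.
    """

    probe_id: str
    values: np.ndarray
    panel: ChannelPanel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.panel.n_channels,):
            raise ValueError("reference length must match the panel")
        if np.any(self.values < 0):
            raise ValueError("reference values must be non-negative (clip first)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reference values must be finite")

    @property
    def peak_channel(self) -> str:
        return self.panel.channel_ids[int(np.argmax(self.values))]

    @property
    def mfi_at_peak(self) -> float:
        return float(np.max(self.values))


@dataclass
class ReferenceMatrix:
    """Channels × endmembers design matrix for unmixing.

    Columns are probe references in order, with the autofluorescence
    reference always last.
    """

    panel: ChannelPanel
    spectra: list[ReferenceSpectrum]

    def __post_init__(self) -> None:
        if len(self.spectra) < 2:
            raise ValueError("need at least one probe plus the autofluorescence column")
        if self.spectra[-1].probe_id != AUTOFLUORESCENCE_ID:
            raise ValueError("last reference column must be the autofluorescence reference")
        ids = [s.probe_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate endmember ids")
        for s in self.spectra:
            if s.panel.channel_ids != self.panel.channel_ids:
                raise ValueError("reference spectrum panel mismatch")
            if np.all(s.values == 0):
                raise ValueError(f"all-zero reference column {s.probe_id!r}")

    @property
    def endmember_ids(self) -> list[str]:
        return [s.probe_id for s in self.spectra]

    @property
    def matrix(self) -> np.ndarray:
        """Design matrix, shape (n_channels, n_endmembers)."""
        return np.column_stack([s.values for s in self.spectra])

    def column(self, probe_id: str) -> ReferenceSpectrum:
        for s in self.spectra:
            if s.probe_id == probe_id:
                return s
        raise KeyError(f"no endmember {probe_id!r} in reference matrix")


@dataclass
class GateResult:
    """Outcome of a positivity gate against the unstained distribution."""

    threshold: float
    positive_mask: np.ndarray
    channel_id: str

    @property
    def n_positive(self) -> int:
        return int(np.count_nonzero(self.positive_mask))

    @property
    def percent_positive(self) -> float:
        return 100.0 * float(np.mean(self.positive_mask))


def _resolve_channel(
    channel: str | int, panel: ChannelPanel, reference: ReferenceSpectrum | None = None
) -> str:
    if channel == "peak_channel":
        if reference is None:
            raise ValueError("channel rule 'peak_channel' requires a reference spectrum")
        return reference.peak_channel
    if isinstance(channel, int):
        return panel.channel_ids[channel]
    if channel not in panel.channel_ids:
        raise KeyError(f"gating channel {channel!r} not in panel")
    return channel


def gate_positive(
    stained: EventTable,
    unstained: EventTable,
    channel: str | int = "peak_channel",
    gate_quantile: float = 0.999,
    reference: ReferenceSpectrum | None = None,
) -> GateResult:
    """Gate stained events positive above the unstained quantile threshold.

    Parameters
    ----------
    channel
        Explicit channel id, channel index, or ``"peak_channel"`` to gate at
        the peak channel of *reference*.
    gate_quantile
        Quantile of the unstained intensities at the gating channel; stained
        events strictly above it are positive.
    """
    if stained.panel.channel_ids != unstained.panel.channel_ids:
        raise ValueError("stained and unstained tables must share the panel")
    if unstained.n_events == 0:
        raise ValueError("unstained table is empty")
    if not 0.0 < gate_quantile < 1.0:
        raise ValueError("gate_quantile must lie in (0, 1)")
    cid = _resolve_channel(channel, stained.panel, reference)
    threshold = float(np.quantile(unstained.channel(cid), gate_quantile))
    mask = stained.channel(cid) > threshold
    return GateResult(threshold=threshold, positive_mask=mask, channel_id=cid)


def build_reference_spectrum(
    stained: EventTable,
    gate: GateResult,
    probe_id: str,
    min_positive_events: int = 50,
) -> ReferenceSpectrum:
    """Per-channel median over gated-positive singly-stained events.

    Negative channel medians (baseline-subtracted exports) are clipped to
    zero. Fewer than ``min_positive_events`` positives signals a failed stain
    or a misplaced gate and raises.
    """
    if gate.positive_mask.shape[0] != stained.n_events:
        raise ValueError("gate was computed on a different event table")
    if gate.n_positive < min_positive_events:
        raise ValueError(
            f"only {gate.n_positive} positive events for {probe_id!r} "
            f"(need ≥ {min_positive_events}); staining or gating likely failed"
        )
    med = np.median(stained.intensities[gate.positive_mask], axis=0)
    return ReferenceSpectrum(probe_id=probe_id, values=np.clip(med, 0.0, None), panel=stained.panel)


def build_autofluorescence_reference(unstained: EventTable) -> ReferenceSpectrum:
    """Per-channel median over *all* unstained events (no gating), clipped at 0."""
    if unstained.n_events == 0:
        raise ValueError("unstained table is empty")
    med = np.median(unstained.intensities, axis=0)
    return ReferenceSpectrum(
        probe_id=AUTOFLUORESCENCE_ID, values=np.clip(med, 0.0, None), panel=unstained.panel
    )


def build_reference_matrix(
    probe_spectra: list[ReferenceSpectrum], autofluorescence: ReferenceSpectrum
) -> ReferenceMatrix:
    """Assemble the unmixing design matrix: probe columns then autofluorescence."""
    if autofluorescence.probe_id != AUTOFLUORESCENCE_ID:
        autofluorescence = ReferenceSpectrum(
            AUTOFLUORESCENCE_ID, autofluorescence.values, autofluorescence.panel
        )
    panel = autofluorescence.panel
    return ReferenceMatrix(panel=panel, spectra=[*probe_spectra, autofluorescence])


def write_reference_matrix(refs: ReferenceMatrix, path: str | Path) -> None:
    """Write the reference matrix CSV (first column = channel id, last = autofluorescence)."""
    df = pd.DataFrame(refs.matrix, columns=refs.endmember_ids)
    df.insert(0, "channel", list(refs.panel.channel_ids))
    df.to_csv(path, index=False, float_format="%.17g")


def read_reference_matrix(path: str | Path, panel: ChannelPanel) -> ReferenceMatrix:
    """Read a reference matrix CSV and check it against the panel.

    Rows are realigned by channel name; a channel set differing from the
    panel is an error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "channel" not in df.columns:
        raise ValueError(f"{path}: first column must be 'channel'")
    file_channels = list(df["channel"].astype(str))
    if sorted(file_channels) != sorted(panel.channel_ids):
        raise ValueError(
            f"{path}: channel list does not match panel "
            f"({file_channels} vs {list(panel.channel_ids)})"
        )
    df = df.set_index("channel").loc[list(panel.channel_ids)]
    spectra = [
        ReferenceSpectrum(probe_id=str(col), values=df[col].to_numpy(dtype=float), panel=panel)
        for col in df.columns
    ]
    return ReferenceMatrix(panel=panel, spectra=spectra)


def snr(
    stained: EventTable,
    unstained: EventTable,
    gate: GateResult,
    channel: str | int | None = None,
    definition: str = "median_ratio",
) -> float:
    """Signal-to-noise ratio of positive stained events over the unstained background.

    ``median_ratio`` (default): median positive intensity ÷ median unstained
    intensity at the channel. ``robust_sd``: median positive ÷ robust sd
    (1.4826·MAD) of unstained. Both at the gate's channel unless overridden.
    """
    cid = gate.channel_id if channel is None else _resolve_channel(channel, stained.panel)
    if gate.n_positive < 1:
        raise ValueError("no positive events to compute SNR over")
    signal = float(np.median(stained.channel(cid)[gate.positive_mask]))
    u = unstained.channel(cid)
    if definition == "median_ratio":
        noise = float(np.median(u))
    elif definition == "robust_sd":
        noise = 1.4826 * float(np.median(np.abs(u - np.median(u))))
    else:
        raise ValueError(f"unknown SNR definition {definition!r}")
    if noise <= 0:
        raise ValueError("non-positive noise denominator; fixture or export miscalibrated")
    return signal / noise


def fold_change_with_docking(
    with_dock: EmissionSpectrum, without_dock: EmissionSpectrum
) -> float:
    """Peak-intensity fold change of a fluorescent oligo upon docking-strand hybridization.

    Values below 1 indicate a docking-induced signal decrease.
    """
    _, peak_with = peak_intensity(with_dock)
    _, peak_without = peak_intensity(without_dock)
    if peak_without <= 0:
        raise ValueError("zero or negative peak intensity in denominator spectrum")
    return peak_with / peak_without
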