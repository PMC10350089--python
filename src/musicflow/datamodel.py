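"""Core domain types and file I/O shared by the whole pipeline.

The pipeline's canonical interchange formats are plain CSV: per-event
intensity tables (one row per cell, one column per detector channel, header
row of channel names) and two-column wavelength/intensity emission spectra.
Channel order is canonicalized by a :class:`ChannelPanel`, never by file
order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "ChannelPanel",
    "EventTable",
    "EmissionSpectrum",
    "AnalysisConfig",
    "default_panel",
    "parse_condition",
    "read_event_table",
    "write_event_table",
    "peak_intensity",
]


@dataclass(frozen=True)
class ChannelPanel:
    """Ordered set of detector-channel names (e.g. ``B1``..``B14``, ``R1``..``R8``).

    Every event table and reference matrix built against a panel shares its
    channel order; readers realign file columns to it by name.
    """

    channel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.channel_ids) == 0:
            raise ValueError("panel must contain at least one channel")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def index_of(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(
                f"channel {channel_id!r} not in panel {list(self.channel_ids)}"
            ) from None


def default_panel() -> ChannelPanel:
    """22-channel two-laser panel (blue B1..B14, red R1..R8).

    The instrument's true channel count is configurable; this fixture panel is
    the package default for simulations and examples.
    """
    ids = tuple(f"B{i}" for i in range(1, 15)) + tuple(f"R{i}" for i in range(1, 9))
    return ChannelPanel(ids)


_CONDITION_RE = re.compile(r"^(unstained|single:[^,+]+|multi:[^,]+(\+[^,+]+)*)$")


def parse_condition(condition: str) -> tuple[str, list[str]]:
    """Parse a sample-condition label.

    Accepted forms: ``unstained``, ``single:<probe>``, ``multi:<p1>+<p2>+...``.
    Returns ``(kind, probe_ids)``.
    """
    if not isinstance(condition, str) or not _CONDITION_RE.match(condition):
        raise ValueError(
            f"unparseable condition label {condition!r}; expected 'unstained', "
            "'single:<probe>' or 'multi:<p1>+<p2>'"
        )
    if condition == "unstained":
        return "unstained", []
    kind, _, rest = condition.partition(":")
    probes = rest.split("+") if kind == "multi" else [rest]
    return kind, probes


@dataclass
class EventTable:
    """Per-cell × per-channel fluorescence intensities on an arbitrary scale.

    Intensities may be negative (baseline-subtracted "scale" exports);
    non-negativity is enforced on unmixing abundances and reference spectra,
    never on raw events.
    """

    panel: ChannelPanel
    intensities: np.ndarray
    condition: str = "unstained"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D events × channels array")
        if self.intensities.shape[1] != self.panel.n_channels:
            raise ValueError(
                f"intensity matrix has {self.intensities.shape[1]} columns but the "
                f"panel has {self.panel.n_channels} channels"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        parse_condition(self.condition)

    @property
    def n_events(self) -> int:
        return self.intensities.shape[0]

    def channel(self, channel_id: str) -> np.ndarray:
        """Intensity column for one channel."""
        return self.intensities[:, self.panel.index_of(channel_id)]


@dataclass
class EmissionSpectrum:
    """Plate-reader emission spectrum: intensity vs wavelength (nm)."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must be 1-D and equal length")
        if self.wavelengths.size == 0:
            raise ValueError("spectrum is empty")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmissionSpectrum":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (wavelength_nm,intensity)")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "intensity": self.intensities}
        ).to_csv(path, index=False, float_format="%.17g")


@dataclass
class AnalysisConfig:
    """Tunable knobs shared across the pipeline.

    gate_quantile: quantile of the unstained distribution used as the
        positivity threshold (default 0.999 — a marker gate set just beyond
        the unstained cloud).
    positivity_channel_rule: ``"peak_channel"`` (gate at the probe's peak
        channel) or an explicit channel id.
    snr_definition: ``"median_ratio"`` (median positive / median unstained) or
        ``"robust_sd"`` (median positive / 1.4826·MAD of unstained).
    random_seed: threads into every stochastic operation via an explicit
        numpy Generator; no global state.
    """

    gate_quantile: float = 0.999
    positivity_channel_rule: str = "peak_channel"
    snr_definition: str = "median_ratio"
    random_seed: int = 0
    fit_tolerance: float = 1e-8
    max_fit_iterations: int = 20000
    min_positive_events: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.gate_quantile < 1.0:
            raise ValueError("gate_quantile must lie in the open interval (0, 1)")
        if self.snr_definition not in ("median_ratio", "robust_sd"):
            raise ValueError(f"unknown snr_definition {self.snr_definition!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.random_seed)


def read_event_table(
    path: str | Path,
    panel: ChannelPanel,
    condition: str = "unstained",
    sample_id: str | None = None,
) -> EventTable:
    """Read an events CSV (header = channel names) and realign columns to the panel.

    Columns may appear in any order; they are matched by name. A missing
    channel or an unexpected extra column is an error — no silent drops.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: event table is empty")
    file_cols = list(df.columns)
    missing = [c for c in panel.channel_ids if c not in file_cols]
    if missing:
        raise ValueError(f"{path}: missing channel column(s) {missing}")
    extra = [c for c in file_cols if c not in panel.channel_ids]
    if extra:
        raise ValueError(f"{path}: unexpected column(s) {extra} not in panel")
    data = df[list(panel.channel_ids)].to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-numeric or non-finite cell in event table")
    return EventTable(
        panel=panel,
        intensities=data,
        condition=condition,
        sample_id=sample_id if sample_id is not None else path.stem,
    )


def write_event_table(table: EventTable, path: str | Path) -> None:
    """Write an events CSV with the panel's channel order as header."""
    pd.DataFrame(table.intensities, columns=list(table.panel.channel_ids)).to_csv(
        path, index=False, float_format="%.17g"
    )


def peak_intensity(spectrum: EmissionSpectrum) -> tuple[float, float]:
    """Return ``(wavelength, intensity)`` of the emission maximum.

    Ties are broken toward the lowest wavelength (``argmax`` on the
    increasing wavelength grid). The peak intensity is the standard scalar
    summary of a plate-reader spectrum.
    """
    idx = int(np.argmax(spectrum.intensities))
    return float(spectrum.wavelengths[idx]), float(spectrum.intensities[idx])
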