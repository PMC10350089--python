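"""End-to-end pipeline: simulate (optional) → gate → references → unmix → report.

Configuration is a plain dict (typically loaded from YAML). Every run writes
a manifest (config snapshot, seed, input digests, package version) so any
output is regenerable; all stochastic stages draw from one seeded generator,
making reruns with a fixed seed byte-identical on the result CSVs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import ChannelPanel, EventTable, default_panel, read_event_table, write_event_table
from .gating import (
    build_autofluorescence_reference,
    build_reference_matrix,
    build_reference_spectrum,
    gate_positive,
    write_reference_matrix,
)
from .simulate import (
    NoiseModel,
    PopulationSpec,
    ProbeEndmember,
    make_autofluorescence_endmember,
    make_endmember,
    simulate_event_table,
)
from .unmixing import (
    compare_single_vs_triple,
    diagonal_dominance,
    normalize_abundances,
    percent_positive_unmixed,
    specificity_matrix,
    unmix_events,
)

__all__ = ["PipelineError", "RunManifest", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for actionable errors."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class RunManifest:
    """Record of one pipeline run: enough to reproduce it exactly."""

    config: dict
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    package_version: str = __version__
    timestamp: str = ""

    def write(self, path: Path) -> None:
        payload = asdict(self)
        payload["timestamp"] = datetime.now(timezone.utc).isoformat()
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} did not parse to a mapping")
    return cfg


def _build_panel(cfg: dict) -> ChannelPanel:
    panel_cfg = cfg.get("panel")
    if panel_cfg is None:
        return default_panel()
    if isinstance(panel_cfg, int):
        return ChannelPanel(tuple(f"C{i}" for i in range(1, panel_cfg + 1)))
    return ChannelPanel(tuple(panel_cfg))


def _build_endmembers(
    sim_cfg: dict, panel: ChannelPanel
) -> list[ProbeEndmember]:
    ems: dict[str, ProbeEndmember] = {}
    for probe in sim_cfg["probes"]:
        pid = probe["id"]
        brightness = float(probe.get("brightness", 1000.0))
        if "parents" in probe:
            parents = tuple(ems[p] for p in probe["parents"])
            ems[pid] = make_endmember(
                pid, -1, panel, brightness_scale=brightness,
                donor_acceptor_mix=float(probe.get("mix", 0.5)), parents=parents,
            )
        else:
            ems[pid] = make_endmember(
                pid, int(probe["peak_channel"]), panel,
                shape_width=float(probe.get("shape_width", 0.18)),
                brightness_scale=brightness,
            )
    return list(ems.values())


def _simulate_inputs(
    cfg: dict, panel: ChannelPanel, rng: np.random.Generator, out: Path
) -> tuple[EventTable, list[tuple[EventTable, str]], EventTable | None]:
    sim = cfg["simulation"]
    endmembers = _build_endmembers(sim, panel)
    af = make_autofluorescence_endmember(panel)
    n = int(sim.get("n_events", 5000))
    af_level = float(sim.get("autofluorescence_level", 50.0))
    noise_cfg = sim.get("noise", {})
    noise = NoiseModel(
        multiplicative_cv=float(noise_cfg.get("multiplicative_cv", 0.25)),
        additive_sd=float(
            noise_cfg.get("additive_sd", 0.01 * max(e.brightness_scale for e in endmembers))
        ),
    )
    fractions = sim.get("fraction_positive", 0.3)

    def frac_of(pid: str) -> float:
        return float(fractions[pid]) if isinstance(fractions, dict) else float(fractions)

    def pop(frac_map: dict[str, float]) -> PopulationSpec:
        return PopulationSpec(
            n_events=n, fraction_positive=frac_map,
            autofluorescence_level=af_level, noise=noise,
        )

    unstained, _ = simulate_event_table(
        endmembers, af, pop({}), "unstained", rng, sample_id="unstained"
    )
    write_event_table(unstained, out / "events_unstained.csv")
    singles = []
    for em in endmembers:
        table, _ = simulate_event_table(
            endmembers, af, pop({em.probe_id: frac_of(em.probe_id)}),
            f"single:{em.probe_id}", rng, sample_id=f"single_{em.probe_id}",
        )
        write_event_table(table, out / f"events_single_{em.probe_id}.csv")
        singles.append((table, em.probe_id))
    multi = None
    if sim.get("multi_stain", True):
        ids = [e.probe_id for e in endmembers]
        multi, _ = simulate_event_table(
            endmembers, af, pop({pid: frac_of(pid) for pid in ids}),
            "multi:" + "+".join(ids), rng, sample_id="multi",
        )
        write_event_table(multi, out / "events_multi.csv")
    return unstained, singles, multi


def _load_inputs(
    cfg: dict, panel: ChannelPanel, digests: dict[str, str]
) -> tuple[EventTable, list[tuple[EventTable, str]], EventTable | None]:
    inputs = cfg["inputs"]
    if "unstained" not in inputs:
        raise PipelineError("gating", "config provides no unstained sample; the gate "
                            "threshold cannot be placed")
    upath = Path(inputs["unstained"])
    digests[str(upath)] = _sha256(upath)
    unstained = read_event_table(upath, panel, condition="unstained")
    singles = []
    for pid, spath in inputs.get("singles", {}).items():
        spath = Path(spath)
        digests[str(spath)] = _sha256(spath)
        singles.append((read_event_table(spath, panel, condition=f"single:{pid}"), pid))
    multi = None
    if "multi" in inputs:
        mpath = Path(inputs["multi"])
        digests[str(mpath)] = _sha256(mpath)
        ids = [pid for _, pid in singles]
        multi = read_event_table(mpath, panel, condition="multi:" + "+".join(ids))
    return unstained, singles, multi


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the full analysis chain and write results under ``out_dir``.

    Stages: simulate inputs (or load them from ``inputs``), gate positives
    against the unstained sample, build the reference matrix, unmix every
    sample, and emit the specificity matrix plus %-positive tables. Raises
    :class:`PipelineError` naming the failing stage.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    rng = np.random.default_rng(seed)
    gate_q = float(cfg.get("gate_quantile", 0.999))
    panel = _build_panel(cfg)
    digests: dict[str, str] = {}

    if "simulation" in cfg:
        unstained, singles, multi = _simulate_inputs(cfg, panel, rng, out)
    elif "inputs" in cfg:
        unstained, singles, multi = _load_inputs(cfg, panel, digests)
    else:
        raise PipelineError("config", "need either a 'simulation' or an 'inputs' block")
    if not singles:
        raise PipelineError("references", "no singly-stained samples; reference spectra "
                            "cannot be built")

    # references ------------------------------------------------------------
    try:
        af_ref = build_autofluorescence_reference(unstained)
        probe_refs = []
        prelim_peak = {}
        for table, pid in singles:
            # gate first at the sample's brightest channel relative to AF,
            # then rebuild at the reference's true peak
            med = np.clip(np.median(table.intensities, axis=0) - af_ref.values, 0, None)
            chan = table.panel.channel_ids[int(np.argmax(med))]
            gate = gate_positive(table, unstained, channel=chan, gate_quantile=gate_q)
            probe_refs.append(build_reference_spectrum(table, gate, pid))
            prelim_peak[pid] = chan
        refs = build_reference_matrix(probe_refs, af_ref)
        write_reference_matrix(refs, out / "reference_matrix.csv")
    except (ValueError, KeyError) as exc:
        raise PipelineError("references", str(exc)) from exc

    # gating + unmixing -----------------------------------------------------
    try:
        unstained_um = unmix_events(unstained, refs)
        spec_df = specificity_matrix(singles, refs, unstained, gate_quantile=gate_q)
        spec_df.to_csv(out / "specificity_matrix.csv", float_format="%.17g")
        rows = []
        norm_frames = []
        for table, pid in singles:
            gate = gate_positive(table, unstained, channel="peak_channel",
                                 gate_quantile=gate_q, reference=refs.column(pid))
            um = unmix_events(table, refs)
            um.to_frame().to_csv(out / f"unmix_single_{pid}.csv", index=False,
                                 float_format="%.17g")
            norm = normalize_abundances(table, um, gate, pid, refs)
            norm_frames.append(pd.DataFrame({
                "probe": pid,
                "normalized_intensity": norm.normalized_intensity,
                "normalized_unmixed": norm.normalized_unmixed,
                "positive": norm.positive_mask,
            }))
            rows.append({
                "probe": pid, "condition": "single",
                "percent_positive_intensity": gate.percent_positive,
                "percent_positive_unmixed": percent_positive_unmixed(
                    um, pid, unstained_um, gate_quantile=gate_q),
            })
        pd.concat(norm_frames, ignore_index=True).to_csv(
            out / "normalized_abundances.csv", index=False, float_format="%.17g")
        if multi is not None:
            um_multi = unmix_events(multi, refs)
            um_multi.to_frame().to_csv(out / "unmix_multi.csv", index=False,
                                       float_format="%.17g")
            for _, pid in singles:
                gate = gate_positive(multi, unstained, channel="peak_channel",
                                     gate_quantile=gate_q, reference=refs.column(pid))
                rows.append({
                    "probe": pid, "condition": "multi",
                    "percent_positive_intensity": gate.percent_positive,
                    "percent_positive_unmixed": percent_positive_unmixed(
                        um_multi, pid, unstained_um, gate_quantile=gate_q),
                })
        pct = pd.DataFrame.from_records(rows)
        pct.to_csv(out / "percent_positive.csv", index=False, float_format="%.17g")
        summary = {
            "seed": seed,
            "n_probes": len(singles),
            "diagonal_dominance": diagonal_dominance(spec_df),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    except (ValueError, KeyError) as exc:
        raise PipelineError("unmixing", str(exc)) from exc

    RunManifest(config=cfg, seed=seed, input_digests=digests).write(out / "manifest.json")
    return out
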