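"""Report rendering: summary tables and figures from completed pipeline outputs."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .photophysics import (
    AnisotropyFitResult,
    DecayFitResult,
    FcsFitResult,
    species_average_lifetime,
)

__all__ = ["parameter_table", "render_reports"]

_PARAM_ROWS = [
    "Molecular Brightness (kHz/molecule)",
    "Species Average Lifetime (ns)",
    "A_1",
    "t_1 (ns)",
    "A_2",
    "t_2 (ns)",
    "decay chi2",
    "Rotational Time (ps)",
    "N",
    "t_diff (ms)",
    "omega_0",
    "A_T1",
    "t_T1 (us)",
    "A_T2",
    "t_T2 (ms)",
    "FCS chi2",
]


def parameter_table(
    columns: dict[str, dict],
) -> pd.DataFrame:
    """Assemble the canonical characterization table (one column per sample).

    Each sample dict may hold ``fcs`` (:class:`FcsFitResult`), ``decay``
    (:class:`DecayFitResult`), ``anisotropy`` (:class:`AnisotropyFitResult`)
    and ``brightness_khz`` (float); missing entries render as NaN.
    """
    out = {}
    for label, parts in columns.items():
        col = dict.fromkeys(_PARAM_ROWS, np.nan)
        if "brightness_khz" in parts:
            col["Molecular Brightness (kHz/molecule)"] = parts["brightness_khz"]
        decay: DecayFitResult | None = parts.get("decay")
        if decay is not None:
            col["Species Average Lifetime (ns)"] = species_average_lifetime(decay.params)
            for i, (a, tau) in enumerate(decay.params.components[:2], start=1):
                col[f"A_{i}"] = a
                col[f"t_{i} (ns)"] = tau
            col["decay chi2"] = decay.red_chi2
        aniso: AnisotropyFitResult | None = parts.get("anisotropy")
        if aniso is not None:
            col["Rotational Time (ps)"] = aniso.params.tau_r
        fcs: FcsFitResult | None = parts.get("fcs")
        if fcs is not None:
            p = fcs.params
            col.update({
                "N": p.n, "t_diff (ms)": p.t_diff, "omega_0": p.omega,
                "A_T1": p.a_t1, "t_T1 (us)": p.t_t1,
                "A_T2": p.a_t2, "t_T2 (ms)": p.t_t2,
                "FCS chi2": fcs.red_chi2,
            })
        out[label] = col
    return pd.DataFrame(out).reindex(_PARAM_ROWS)


def render_reports(results_dir: str | Path) -> list[Path]:
    """Render figures and derived tables from a completed pipeline directory.

    Produces a reference-spectra plot, a specificity heatmap, and the
    intensity-vs-unmixed scatter (with its fitted slope recorded in the PNG
    metadata). Raises if an upstream artifact is missing.
    """
    results = Path(results_dir)
    written: list[Path] = []
    refs_path = results / "reference_matrix.csv"
    if not refs_path.exists():
        raise FileNotFoundError(
            f"[stage: report] missing upstream artifact {refs_path.name}; run the "
            "pipeline first"
        )
    manifest = {}
    if (results / "manifest.json").exists():
        manifest = json.loads((results / "manifest.json").read_text())
    meta = {
        "Software": f"musicflow {manifest.get('package_version', '')}".strip(),
        "Comment": f"seed={manifest.get('seed')}",
    }

    refs = pd.read_csv(refs_path).set_index("channel")
    fig, ax = plt.subplots(figsize=(7, 4))
    for col in refs.columns:
        ax.plot(range(len(refs)), refs[col] / refs[col].max(), label=col, marker="o", ms=3)
    ax.set_xticks(range(len(refs)))
    ax.set_xticklabels(refs.index, rotation=90, fontsize=6)
    ax.set_xlabel("detector channel")
    ax.set_ylabel("normalized reference intensity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = results / "reference_spectra.png"
    fig.savefig(p, dpi=150, metadata=meta)
    plt.close(fig)
    written.append(p)

    spec_path = results / "specificity_matrix.csv"
    if spec_path.exists():
        spec = pd.read_csv(spec_path, index_col=0)
        if spec.size == 0:
            raise ValueError("[stage: report] specificity matrix is empty")
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(spec.to_numpy(), cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(spec.shape[1]), spec.columns, rotation=45, ha="right")
        ax.set_yticks(range(spec.shape[0]), spec.index)
        ax.set_xlabel("reported endmember")
        ax.set_ylabel("stained probe")
        fig.colorbar(im, ax=ax, label="median relative unmixed abundance")
        fig.tight_layout()
        p = results / "specificity_heatmap.png"
        fig.savefig(p, dpi=150, metadata=meta)
        plt.close(fig)
        written.append(p)

    norm_path = results / "normalized_abundances.csv"
    if norm_path.exists():
        norm = pd.read_csv(norm_path)
        if norm.empty:
            raise ValueError("[stage: report] normalized-abundance table is empty")
        fig, ax = plt.subplots(figsize=(5, 5))
        slopes = {}
        for pid, grp in norm.groupby("probe"):
            pos = grp[grp["positive"]]
            ax.plot(pos["normalized_intensity"], pos["normalized_unmixed"],
                    ".", ms=2, alpha=0.4, label=pid)
            if len(pos) > 1:
                x = pos["normalized_intensity"].to_numpy()
                y = pos["normalized_unmixed"].to_numpy()
                slopes[pid] = float(np.sum(x * y) / np.sum(x * x))
        lim = np.nanquantile(norm[["normalized_intensity", "normalized_unmixed"]], 0.995)
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlim(0, lim)
        ax.set_ylim(0, lim)
        ax.set_xlabel("normalized peak-channel intensity")
        ax.set_ylabel("normalized unmixed abundance")
        ax.legend(markerscale=4, fontsize=8)
        fig.tight_layout()
        p = results / "intensity_vs_unmixed.png"
        scatter_meta = dict(meta)
        scatter_meta["Description"] = "fitted slopes: " + json.dumps(slopes, sort_keys=True)
        fig.savefig(p, dpi=150, metadata=scatter_meta)
        plt.close(fig)
        written.append(p)
    return written
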