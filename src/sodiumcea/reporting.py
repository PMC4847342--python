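"""Tabular and graphical outputs.

Shapes the incremental results into the two standard tables (population
totals per intervention x mode; per-adult figures by socio-demographic
group) and draws the cost-effectiveness plane and tornado bars.  Full
precision is kept in the CSVs; rounding to a few meaningful digits is a
display concern only.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .economics import IncrementalResult
from .uncertainty import PsaResult, TornadoResult


def results_table(results: list[IncrementalResult]) -> pd.DataFrame:
    """Population-level incremental results, one row per intervention x mode."""
    return pd.DataFrame([
        {
            "intervention": r.spec.id,
            "name": r.spec.name,
            "mode": r.spec.mode,
            "qalys_gained": r.qalys_gained,
            "net_cost": r.net_cost,
            "intervention_cost": r.intervention_cost,
        }
        for r in results
    ])


def subgroup_table(results: list[IncrementalResult]) -> pd.DataFrame:
    """Per-adult incremental results by sex, ethnicity and baseline age."""
    frames = []
    for r in results:
        df = r.per_adult.copy()
        df.insert(0, "intervention", r.spec.id)
        df.insert(1, "name", r.spec.name)
        df.insert(2, "mode", r.spec.mode)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def ceplane_summary(psa: PsaResult) -> dict:
    """Quadrant shares of the PSA cloud on the cost-effectiveness plane."""
    d = psa.draws
    n = len(d)
    if n == 0:
        raise ValueError("no PSA draws to summarise")
    return {
        "intervention": psa.spec.id,
        "mode": psa.spec.mode,
        "n_draws": n,
        "gain_and_save": float(((d.dqaly > 0) & (d.dcost < 0)).mean()),
        "gain_and_cost": float(((d.dqaly > 0) & (d.dcost >= 0)).mean()),
        "lose_and_save": float(((d.dqaly <= 0) & (d.dcost < 0)).mean()),
        "lose_and_cost": float(((d.dqaly <= 0) & (d.dcost >= 0)).mean()),
        "fraction_cost_saving": psa.fraction_cost_saving,
    }


def plot_ce_plane(psas: list[PsaResult], path: str | Path) -> None:
    """Scatter of (QALYs gained, net cost) draws per intervention."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for psa in psas:
        ax.scatter(psa.draws["dqaly"], psa.draws["dcost"] / 1e6, s=4,
                   alpha=0.4, label=psa.spec.label)
        ax.scatter([psa.point[0]], [psa.point[1] / 1e6], marker="x", c="k")
    ax.axhline(0, lw=0.8, c="grey")
    ax.axvline(0, lw=0.8, c="grey")
    ax.set_xlabel("Health gain (QALYs)")
    ax.set_ylabel("Net health-system cost (currency, millions)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(res: TornadoResult, path: str | Path) -> None:
    """Horizontal tornado bars, widest on top."""
    tab = res.table.iloc[::-1]
    lo = tab[f"{res.output}_low"]
    hi = tab[f"{res.output}_high"]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(tab) + 1.5))
    left = pd.concat([lo, hi], axis=1).min(axis=1)
    width = (hi - lo).abs()
    ax.barh(tab["param"], width, left=left, color="steelblue")
    unit = "QALYs" if res.output == "qaly" else "currency"
    ax.set_xlabel(f"Incremental {res.output} range ({unit})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def config_hash(paths: list[str | Path], extra: dict | None = None) -> str:
    """SHA-256 over input files (and config values) for the run manifest."""
    h = hashlib.sha256()
    for p in sorted(str(p) for p in paths):
        h.update(Path(p).read_bytes())
    if extra:
        h.update(json.dumps(extra, sort_keys=True, default=str).encode())
    return h.hexdigest()


def write_manifest(outdir: str | Path, *, inputs_hash: str, seed: int | None,
                   settings: dict) -> None:
    from . import __version__

    manifest = {
        "package_version": __version__,
        "inputs_hash": inputs_hash,
        "seed": seed,
        "settings": settings,
    }
    Path(outdir, "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str),
        encoding="utf-8",
    )
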