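"""Tidy CSV outputs, run manifests and optional weekly plots.

A simulation run directory holds ``summary.csv`` (weekly mean and quantile
bands), ``replications.csv`` (per-replication weekly series) and
``manifest.json`` (config hash, seeds, package version) -- enough to
reproduce and to reload the run for comparisons.
"""

from __future__ import annotations

import hashlib
import json
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import MEASURES, ExperimentSummary, ResultSeries

SUMMARY_FILE = "summary.csv"
REPLICATIONS_FILE = "replications.csv"
MANIFEST_FILE = "manifest.json"
COMPARISON_FILE = "comparison.csv"


def config_hash(payload: dict) -> str:
    """Stable sha256 over a JSON-serialisable configuration payload."""
    canonical = json.dumps(payload, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_manifest(out_dir: str | Path, *, config: dict, seeds: list[int], extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "careflow",
        "version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        "seeds": [int(s) for s in seeds],
    }
    if extra:
        manifest.update(extra)
    path = out_dir / MANIFEST_FILE
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def read_manifest(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / MANIFEST_FILE).read_text())


# ---------------------------------------------------------------------------
# summaries and replications
# ---------------------------------------------------------------------------


def summary_to_frame(summary: ExperimentSummary, scenario: str = "") -> pd.DataFrame:
    frame = summary.to_frame()
    frame.insert(0, "scenario", scenario)
    frame.insert(1, "replication", "summary")
    return frame


def replications_to_frame(reps: list[ResultSeries], scenario: str = "") -> pd.DataFrame:
    frames = []
    for r, rep in enumerate(reps):
        f = rep.to_frame()
        f.insert(0, "scenario", scenario)
        f.insert(1, "replication", r)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def write_run(
    out_dir: str | Path,
    summary: ExperimentSummary,
    reps: list[ResultSeries] | None = None,
    *,
    scenario: str = "",
    config: dict | None = None,
) -> Path:
    """Write a run directory: summary, optional replications, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_to_frame(summary, scenario).to_csv(out_dir / SUMMARY_FILE, index=False)
    if reps:
        replications_to_frame(reps, scenario).to_csv(out_dir / REPLICATIONS_FILE, index=False)
    write_manifest(
        out_dir,
        config=config or {},
        seeds=summary.seeds,
        extra={
            "scenario": scenario,
            "start_date": summary.start_date.isoformat(),
            "horizon_days": summary.horizon_days,
            "warmup_weeks": summary.warmup_weeks,
            "n_replications": summary.n_replications,
            "services": summary.services,
        },
    )
    return out_dir


def read_run(out_dir: str | Path) -> ExperimentSummary:
    """Reload a run directory's summary into an :class:`ExperimentSummary`."""
    out_dir = Path(out_dir)
    manifest = read_manifest(out_dir)
    frame = pd.read_csv(out_dir / SUMMARY_FILE)
    services = list(manifest["services"])
    s_index = {s: i for i, s in enumerate(services)}
    n_weeks = int(frame["week"].max()) + 1
    measures: dict[str, dict[str, np.ndarray]] = {}
    for m in MEASURES:
        measures[m] = {}
        sub_m = frame[frame["measure"] == m]
        for stat in ("mean", "q2.5", "q97.5"):
            arr = np.zeros((len(services), n_weeks))
            sub = sub_m[sub_m["stat"] == stat]
            arr[
                sub["service"].map(s_index).to_numpy(),
                sub["week"].to_numpy(dtype=int),
            ] = sub["value"].to_numpy()
            measures[m][stat] = arr
    return ExperimentSummary(
        services=services,
        start_date=date.fromisoformat(manifest["start_date"]),
        horizon_days=int(manifest["horizon_days"]),
        warmup_weeks=int(manifest["warmup_weeks"]),
        n_replications=int(manifest["n_replications"]),
        seeds=[int(s) for s in manifest["seeds"]],
        measures=measures,
    )


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def plot_experiment(
    summary: ExperimentSummary,
    out_dir: str | Path,
    *,
    measures=MEASURES,
    fmt: str = "png",
    label: str = "",
) -> list[Path]:
    """One figure per measure: weekly mean line and 95% band per service.

    Headless-safe (Agg backend); returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    weeks = np.arange(summary.n_weeks)
    for m in measures:
        n = len(summary.services)
        ncols = 2
        nrows = (n + ncols - 1) // ncols
        fig, axes = plt.subplots(nrows, ncols, figsize=(10, 2.2 * nrows), sharex=True)
        axes = np.atleast_1d(axes).ravel()
        for i, sid in enumerate(summary.services):
            ax = axes[i]
            mean = summary.series(m, "mean")[i]
            lo = summary.series(m, "q2.5")[i]
            hi = summary.series(m, "q97.5")[i]
            ax.fill_between(weeks, lo, hi, alpha=0.3, linewidth=0)
            ax.plot(weeks, mean, linewidth=1.2)
            if summary.warmup_weeks:
                ax.axvline(summary.warmup_weeks, linestyle="--", linewidth=0.8, color="grey")
            ax.set_title(sid, fontsize=8)
        for ax in axes[n:]:
            ax.set_visible(False)
        fig.suptitle(f"{label} {m}".strip())
        fig.supxlabel("week")
        fig.tight_layout()
        path = out_dir / f"{m}.{fmt}"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
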