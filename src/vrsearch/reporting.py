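"""Case reports, raycast 2-D histograms, and the end-to-end pipeline.

Figure outputs are data exports (histogram grids, summary tables) rather
than styled plots.  Case reports use neutral, strengths-first language:
they describe *atypicality* relative to the reference cohorts and never a
clinical label.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atypicality import SummaryMatrix, build_summary_matrix
from .metrics import ALL_METRICS, compute_metric_vector, metrics_table
from .model import ANALYSIS_LEVELS, PlayerSession
from .stats import group_stats
from .tukey import DEFAULT_QUARTILE_METHOD

HIST_BOUND = 50.0  # degrees; histogram window is [−50, +50)
HIST_BIN = 1.0  # degrees


@dataclass
class RaycastHistogram:
    """2-D orientation histogram over search-array frames.

    100×100 grid of 1° bins spanning −50° to +50° on both axes (lateral ×
    vertical); ``excluded`` counts in-phase frames falling outside the
    window.  Bins are half-open [edge, edge + 1°).
    """

    source: str
    level: str
    edges: np.ndarray
    counts: np.ndarray
    excluded: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def raycast_histogram(frames: pd.DataFrame, source: str, level: str) -> RaycastHistogram:
    """Histogram the array-phase raycasts of one source over one level."""
    lat_col, vert_col = ("head_lat", "head_vert") if source == "headset" else ("ctrl_lat", "ctrl_vert")
    if source not in ("headset", "controller"):
        raise ValueError(f"unknown raycast source {source!r}")
    sel = (frames["phase"] == "array") & (frames["level"] == level)
    lat = frames.loc[sel, lat_col].to_numpy(dtype=float)
    vert = frames.loc[sel, vert_col].to_numpy(dtype=float)
    edges = np.arange(-HIST_BOUND, HIST_BOUND + HIST_BIN, HIST_BIN)
    in_bounds = (lat >= -HIST_BOUND) & (lat < HIST_BOUND) & (vert >= -HIST_BOUND) & (vert < HIST_BOUND)
    counts, _, _ = np.histogram2d(lat[in_bounds], vert[in_bounds], bins=[edges, edges])
    return RaycastHistogram(
        source=source,
        level=level,
        edges=edges,
        counts=counts.astype(int),
        excluded=int((~in_bounds).sum()),
    )


def case_report(
    session: PlayerSession,
    matrix: SummaryMatrix,
    include_histograms: bool = True,
) -> dict:
    """Structured per-player report: metrics, fences, flags, histograms.

    The narrative fields describe observed orientation and performance in
    neutral terms; flagged metrics are listed as "atypical relative to the
    reference groups".
    """
    pid = session.player_id
    if pid not in matrix.cells.index:
        raise KeyError(f"player {pid!r} is not in the summary matrix")
    row = matrix.cells.loc[pid]
    flagged = matrix.flagged_metrics(pid)
    flags = matrix.flags
    detail = flags[flags["player_id"] == pid][["metric", "level", "value", "flag"]]
    report = {
        "player_id": pid,
        "group": session.group,
        "n_trials": len(session.trials),
        "levels_played": session.levels_played,
        "mean_atypicality": matrix.mean_atypicality(pid),
        "atypical_metrics": flagged,
        "cells": {m: (None if np.isnan(row[m]) else float(row[m])) for m in matrix.cells.columns},
        "metric_values": detail.replace({np.nan: None}).to_dict(orient="records"),
        "fences": matrix.fences.replace({np.nan: None}).to_dict(orient="records"),
        "narrative": (
            f"Player {pid} completed {len(session.trials)} trials across "
            f"{len(session.levels_played)} levels. "
            + (
                "All metrics fell within the typical range of both reference groups."
                if not flagged
                else "Gameplay was atypical relative to both reference groups on: "
                + ", ".join(flagged) + "."
            )
        ),
    }
    if include_histograms:
        hists = []
        for source in ("headset", "controller"):
            for level in session.levels_played:
                h = raycast_histogram(session.frames, source, level)
                if h.total + h.excluded == 0:
                    continue
                ii, jj = np.nonzero(h.counts)
                hists.append(
                    {
                        "source": h.source,
                        "level": h.level,
                        "total": h.total,
                        "excluded": h.excluded,
                        "bin_width_deg": HIST_BIN,
                        # sparse encoding: [lateral bin edge, vertical bin
                        # edge, count] for non-zero bins only
                        "nonzero_bins": [
                            [float(h.edges[i]), float(h.edges[j]), int(h.counts[i, j])]
                            for i, j in zip(ii, jj)
                        ],
                    }
                )
        report["histograms"] = hists
    return report


def run_pipeline(
    sessions: list[PlayerSession],
    out_dir: str | Path,
    quartile_method: str = DEFAULT_QUARTILE_METHOD,
    leave_one_out: bool = False,
    count_grain: str = "boolean",
    seed: int | None = None,
    write_reports: bool = True,
) -> dict:
    """Metrics → atypicality → group statistics → per-player reports.

    Writes ``metrics.csv``, ``summary_matrix.csv``, ``fences.csv``,
    ``atypicality_summary.json``, ``group_stats.json`` and (optionally)
    ``reports/<player>.json`` under ``out_dir``, plus ``run_log.json`` with
    the options used.  Deterministic given sessions + options.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    vectors = [compute_metric_vector(s, quartile_method) for s in sessions]
    long = metrics_table(vectors)
    long.to_csv(out / "metrics.csv", index=False)

    matrix = build_summary_matrix(vectors, quartile_method, leave_one_out)
    matrix.cells.to_csv(out / "summary_matrix.csv", na_rep="NA")
    matrix.fences.to_csv(out / "fences.csv", index=False)

    mean_atyp = matrix.mean_atypicality_series()
    summary = {
        pid: {
            "group": matrix.groups[pid],
            "mean_atypicality": None if np.isnan(mean_atyp[pid]) else float(mean_atyp[pid]),
            "atypical_metrics": matrix.flagged_metrics(pid),
        }
        for pid in matrix.player_ids
    }
    (out / "atypicality_summary.json").write_text(json.dumps(summary, indent=2))

    gstats = group_stats(matrix, grain=count_grain)
    (out / "group_stats.json").write_text(json.dumps(gstats, indent=2))

    if write_reports:
        rep_dir = out / "reports"
        rep_dir.mkdir(exist_ok=True)
        for s in sessions:
            rep = case_report(s, matrix, include_histograms=False)
            (rep_dir / f"{s.player_id}.json").write_text(json.dumps(rep, indent=2))

    options = {
        "quartile_method": quartile_method,
        "leave_one_out": leave_one_out,
        "count_grain": count_grain,
        "seed": seed,
        "n_sessions": len(sessions),
        "n_metrics": len(ALL_METRICS),
        "levels": list(ANALYSIS_LEVELS),
    }
    options["config_hash"] = hashlib.sha256(
        json.dumps(options, sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "run_log.json").write_text(json.dumps(options, indent=2))
    return {"matrix": matrix, "group_stats": gstats, "summary": summary, "options": options}
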