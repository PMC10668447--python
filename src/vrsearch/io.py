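"""Reading and writing telemetry tables and game-config JSON.

File dialects: CSV with header, UTF-8, '.' decimal.  Frames may also be
written as JSON-lines (one frame object per line) for streaming-friendly
storage.  Schemas:

``trials.csv``
    player_id, group, level, trial_index, target_lateral, target_vertical,
    target_ecc, selected_lateral, selected_vertical, correct, rt_s
``frames.csv`` / ``frames.jsonl``
    player_id, level, trial_index, time_s, phase, head_lat, head_vert,
    ctrl_lat, ctrl_vert
``game.json``
    {"levels": [{name, ring_eccentricities, elements_per_ring,
    min_duration_min, depth_radii, has_trials}, ...], "grid": {...}}

Unknown trial columns are preserved in each session's metadata bag
(``session.demographics['extra_columns']`` is not used for this; see
``read_sessions``'s return contract).  Element arrays are not serialised —
the CSV schema round-trips every analysed field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import AngularPosition
from .model import FRAME_COLUMNS, GameConfig, LevelConfig, PlayerSession, TrialRecord

TRIAL_COLUMNS = [
    "player_id", "group", "level", "trial_index",
    "target_lateral", "target_vertical", "target_ecc",
    "selected_lateral", "selected_vertical", "correct", "rt_s",
]


class SchemaError(ValueError):
    """A telemetry file violates its documented schema."""


def sessions_to_tables(sessions: Sequence[PlayerSession]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten sessions into (trials, frames) DataFrames."""
    trial_rows = []
    frame_tables = []
    for s in sessions:
        for t in s.trials:
            sel = t.selected_position
            trial_rows.append(
                {
                    "player_id": s.player_id,
                    "group": s.group,
                    "level": t.level,
                    "trial_index": t.trial_index,
                    "target_lateral": t.target_position.lateral,
                    "target_vertical": t.target_position.vertical,
                    "target_ecc": t.target_eccentricity,
                    "selected_lateral": sel.lateral if sel else np.nan,
                    "selected_vertical": sel.vertical if sel else np.nan,
                    "correct": bool(t.correct),
                    "rt_s": t.rt,
                }
            )
        if len(s.frames):
            f = s.frames.copy()
            f.insert(0, "player_id", s.player_id)
            frame_tables.append(f)
    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    frames = (
        pd.concat(frame_tables, ignore_index=True)
        if frame_tables
        else pd.DataFrame(columns=["player_id"] + FRAME_COLUMNS)
    )
    return trials, frames


def write_sessions(
    sessions: Sequence[PlayerSession],
    trials_path: str | Path,
    frames_path: str | Path | None = None,
) -> None:
    """Write sessions as trials.csv (+ frames.csv / frames.jsonl)."""
    trials, frames = sessions_to_tables(sessions)
    trials.to_csv(trials_path, index=False)
    if frames_path is not None:
        frames_path = Path(frames_path)
        if frames_path.suffix == ".jsonl":
            with open(frames_path, "w") as fh:
                for rec in frames.to_dict(orient="records"):
                    fh.write(json.dumps(rec) + "\n")
        else:
            frames.to_csv(frames_path, index=False)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_sessions(
    trials_path: str | Path,
    frames_path: str | Path | None = None,
) -> list[PlayerSession]:
    """Read sessions back from trials.csv (+ optional frames file).

    Schema violations raise :class:`SchemaError` naming the offending row
    and column.  Unknown trial columns are carried along in each session's
    ``demographics['extra']`` bag.  An empty trial table yields an empty
    session list.
    """
    trials = pd.read_csv(trials_path, dtype={"player_id": str})
    _require_columns(trials, TRIAL_COLUMNS, trials_path)
    extra_cols = [c for c in trials.columns if c not in TRIAL_COLUMNS]

    if frames_path is not None:
        frames_path = Path(frames_path)
        if frames_path.suffix == ".jsonl":
            frames = pd.read_json(frames_path, lines=True, dtype={"player_id": str})
            if not len(frames):
                frames = pd.DataFrame(columns=["player_id"] + FRAME_COLUMNS)
        else:
            frames = pd.read_csv(frames_path, dtype={"player_id": str})
        _require_columns(frames, ["player_id"] + FRAME_COLUMNS, frames_path)
    else:
        frames = pd.DataFrame(columns=["player_id"] + FRAME_COLUMNS)

    sessions: list[PlayerSession] = []
    frame_groups = dict(tuple(frames.groupby("player_id"))) if len(frames) else {}
    for pid, sub in trials.groupby("player_id", sort=False):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise SchemaError(f"{trials_path}: player {pid} has conflicting group labels")
        recs = []
        for row_idx, row in sub.iterrows():
            try:
                target = AngularPosition(row["target_lateral"], row["target_vertical"])
                if np.isnan(row["selected_lateral"]):
                    selected = None
                else:
                    selected = AngularPosition(row["selected_lateral"], row["selected_vertical"])
                recs.append(
                    TrialRecord(
                        player_id=pid,
                        level=str(row["level"]),
                        trial_index=int(row["trial_index"]),
                        target_position=target,
                        selected_position=selected,
                        correct=bool(row["correct"]),
                        rt=float(row["rt_s"]),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{trials_path}: row {row_idx}: {exc}") from exc
        pf = frame_groups.get(pid)
        pf = pf.drop(columns=["player_id"]).reset_index(drop=True) if pf is not None else pd.DataFrame(columns=FRAME_COLUMNS)
        demo = {"extra": sub[extra_cols].to_dict(orient="list")} if extra_cols else None
        sessions.append(
            PlayerSession(player_id=pid, group=str(groups[0]), trials=recs, frames=pf,
                          demographics=demo)
        )
    # frame-only players (e.g. free viewing without any completed trials)
    for pid, pf in frame_groups.items():
        if not any(s.player_id == pid for s in sessions):
            sessions.append(
                PlayerSession(
                    player_id=pid, group="control",
                    trials=[], frames=pf.drop(columns=["player_id"]).reset_index(drop=True),
                )
            )
    return sessions


def game_to_json(game: GameConfig, path: str | Path) -> None:
    doc = {
        "levels": [
            {
                "name": lv.name,
                "ring_eccentricities": list(lv.ring_eccentricities),
                "elements_per_ring": list(lv.elements_per_ring),
                "min_duration_min": lv.min_duration,
                "depth_radii": list(lv.depth_radii),
                "has_trials": lv.has_trials,
            }
            for lv in game.levels
        ],
        "grid": {
            "radial_spacing": game.radial_spacing,
            "within_ring_spacing": game.within_ring_spacing,
            "radius": game.radius,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def game_from_json(path: str | Path) -> GameConfig:
    doc = json.loads(Path(path).read_text())
    try:
        levels = tuple(
            LevelConfig(
                name=lv["name"],
                ring_eccentricities=tuple(lv["ring_eccentricities"]),
                elements_per_ring=tuple(lv["elements_per_ring"]),
                min_duration=lv["min_duration_min"],
                depth_radii=tuple(lv.get("depth_radii", [2.0])),
                has_trials=lv.get("has_trials", True),
            )
            for lv in doc["levels"]
        )
        grid = doc.get("grid", {})
        return GameConfig(
            levels,
            radial_spacing=grid.get("radial_spacing", 12.5),
            within_ring_spacing=grid.get("within_ring_spacing", 15.0),
            radius=grid.get("radius", 2.0),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed game config: {exc}") from exc


def read_feather_table(path: str | Path) -> pd.DataFrame:
    """Load a deposited feather telemetry table (requires pyarrow)."""
    return pd.read_feather(path)
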