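"""Data model for gameplay telemetry: trials, frames, levels, sessions.

Trials are lightweight records; frame-level telemetry (90 Hz orientation
samples) is kept as a :class:`pandas.DataFrame` per session with one row per
frame and angle columns in degrees.  Times are seconds since level start,
coordinates degrees, trial indices 0-based in files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import AngularPosition, eccentricity

#: Canonical level names, in play order.
LEVEL_NAMES = ("tutorial", "axes", "stimuli", "depth", "full_field", "free_viewing")

#: Levels entering the analysis (tutorial is excluded; free viewing has no
#: trials and contributes orientation metrics only).
ANALYSIS_LEVELS = ("axes", "stimuli", "depth", "full_field", "free_viewing")
TRIAL_LEVELS = ("axes", "stimuli", "depth", "full_field")

FRAME_COLUMNS = [
    "level",
    "trial_index",
    "time_s",
    "phase",
    "head_lat",
    "head_vert",
    "ctrl_lat",
    "ctrl_vert",
]


@dataclass(frozen=True)
class LevelConfig:
    """Configuration of one game level.

    ``min_duration`` is the fixed minimum gameplay duration in minutes; a
    level ends only after it has elapsed and the current selection is made.
    The depth level presents elements on two surfaces (2 m and 4 m).
    """

    name: str
    ring_eccentricities: tuple[float, ...]
    elements_per_ring: tuple[int, ...]
    min_duration: float  # minutes
    depth_radii: tuple[float, ...] = (2.0,)
    has_trials: bool = True

    def __post_init__(self) -> None:
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")
        if self.has_trials and len(self.ring_eccentricities) != len(self.elements_per_ring):
            raise ValueError("one element count per ring is required")
        if self.name == "depth" and set(self.depth_radii) != {2.0, 4.0}:
            raise ValueError("depth level uses exactly the 2 m and 4 m surfaces")

    @property
    def n_elements(self) -> int:
        return int(sum(self.elements_per_ring))


@dataclass(frozen=True)
class GameConfig:
    """An ordered set of levels plus the shared spherical grid parameters."""

    levels: tuple[LevelConfig, ...]
    radial_spacing: float = 12.5  # ring eccentricity step, degrees
    within_ring_spacing: float = 15.0  # polar spacing within a ring, degrees
    radius: float = 2.0  # metres

    @property
    def total_min_duration(self) -> float:
        """Summed per-level minimum durations, minutes."""
        return float(sum(lv.min_duration for lv in self.levels))

    def level(self, name: str) -> LevelConfig:
        for lv in self.levels:
            if lv.name == name:
                return lv
        raise KeyError(f"no level named {name!r}")

    def scaled(self, factor: float) -> "GameConfig":
        """A copy with every level's minimum duration multiplied by ``factor``.

        Used to run the same level structure at reduced problem size.
        """
        levels = tuple(
            LevelConfig(
                name=lv.name,
                ring_eccentricities=lv.ring_eccentricities,
                elements_per_ring=lv.elements_per_ring,
                min_duration=lv.min_duration * factor,
                depth_radii=lv.depth_radii,
                has_trials=lv.has_trials,
            )
            for lv in self.levels
        )
        return GameConfig(levels, self.radial_spacing, self.within_ring_spacing, self.radius)


def default_game() -> GameConfig:
    """The six-level short game preset (total minimum duration 19.5 min).

    Eight-element levels use a single ring at 12.5° eccentricity (the first
    ring of the 12.5°-spaced ring system); the full-field level uses four
    concentric rings at 12.5°, 25°, 37.5° and 50°.
    """
    ring1 = (12.5,)
    levels = (
        LevelConfig("tutorial", ring1, (8,), 0.5),
        LevelConfig("axes", ring1, (8,), 3.0),
        LevelConfig("stimuli", ring1, (8,), 4.5),
        LevelConfig("depth", ring1, (8,), 6.0, depth_radii=(2.0, 4.0)),
        LevelConfig("full_field", (12.5, 25.0, 37.5, 50.0), (8, 8, 8, 8), 4.5),
        LevelConfig("free_viewing", (), (), 1.0, has_trials=False),
    )
    return GameConfig(levels)


@dataclass(frozen=True)
class TrialRecord:
    """One cue/array search trial.

    ``rt`` is the cue-selection to target-selection interval of the array
    phase, seconds.  ``correct`` is true iff the selected element is the
    target.  ``element_positions`` holds the full array as an (n, 2) array
    of (lateral, vertical) degrees when available.
    """

    player_id: str
    level: str
    trial_index: int
    target_position: AngularPosition
    selected_position: Optional[AngularPosition]
    correct: bool
    rt: float
    element_positions: Optional[np.ndarray] = None
    depth_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.trial_index < 0:
            raise ValueError("trial_index must be non-negative")
        if self.rt <= 0:
            raise ValueError("rt must be positive for completed trials")
        if self.selected_position is not None:
            is_target = (
                abs(self.selected_position.lateral - self.target_position.lateral) < 1e-9
                and abs(self.selected_position.vertical - self.target_position.vertical) < 1e-9
            )
            if self.correct != is_target:
                raise ValueError("correct flag inconsistent with selected position")
        elif self.correct:
            raise ValueError("a trial without a selection cannot be correct")

    @property
    def target_eccentricity(self) -> float:
        return eccentricity(self.target_position)


@dataclass(frozen=True)
class FrameRecord:
    """One orientation sample (headset + controller), angles in degrees."""

    player_id: str
    level: str
    trial_index: int
    time: float
    phase: str  # 'cue' or 'array'
    head: AngularPosition
    ctrl: AngularPosition

    def __post_init__(self) -> None:
        if self.phase not in ("cue", "array"):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class PlayerSession:
    """One player's full gameplay: trials, frames, group label, metadata."""

    player_id: str
    group: str  # 'patient' or 'control'
    trials: list[TrialRecord] = field(default_factory=list)
    frames: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=FRAME_COLUMNS))
    demographics: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be 'patient' or 'control', got {self.group!r}")

    def trials_for_level(self, level: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.level == level]

    @property
    def levels_played(self) -> list[str]:
        played = {t.level for t in self.trials}
        if len(self.frames):
            played |= set(self.frames["level"].unique())
        return [lv for lv in LEVEL_NAMES if lv in played]

    def validate(self) -> None:
        """Check frame/trial cross-references and time monotonicity."""
        trial_keys = {(t.level, t.trial_index) for t in self.trials}
        has_trials = {"axes", "stimuli", "depth", "full_field", "tutorial"}
        if len(self.frames):
            for level, grp in self.frames.groupby("level", sort=False):
                times = grp["time_s"].to_numpy()
                if np.any(np.diff(times) < -1e-9):
                    raise ValueError(f"frame times decrease within level {level!r}")
                if level in has_trials:
                    missing = set(
                        zip([level] * len(grp), grp["trial_index"].astype(int))
                    ) - trial_keys
                    if missing:
                        raise ValueError(
                            f"frames reference unknown trials: {sorted(missing)[:3]}"
                        )


def sessions_by_group(sessions: Sequence[PlayerSession]) -> dict[str, list[PlayerSession]]:
    out: dict[str, list[PlayerSession]] = {"control": [], "patient": []}
    for s in sessions:
        out[s.group].append(s)
    return out
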