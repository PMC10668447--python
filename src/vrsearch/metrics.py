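"""The 14 attention metrics of one player.

Six primary metrics are computed per game level: response accuracy (%),
mean correct-trial reaction time after within-player outlier trimming (s),
and the mean headset/controller lateral and vertical raycast angles over
search-array frames (°).  Eight spatial-preference difference scores are
computed from trials pooled across levels: accuracy and RT contrasts of
left vs right quadrants, up vs down quadrants, and the 12.5°/25.0° and
25.0°/37.5° eccentricity pairs.  Sign conventions: positive quadrant scores
= right/up preference; positive eccentricity scores = central preference
(flippable).

Missing data propagate as NaN: a metric cell needs at least one qualifying
observation, otherwise it is missing — never zero-imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AngularPosition
from .model import PlayerSession, TrialRecord, TRIAL_LEVELS, ANALYSIS_LEVELS
from .tukey import DEFAULT_QUARTILE_METHOD, Fences, outlier_mask, tukey_fences

#: The six per-level (primary) metric names.
PRIMARY_METRICS = ("accuracy", "rt", "head_lat", "head_vert", "ctrl_lat", "ctrl_vert")

#: The eight pooled spatial-preference metric names.
POOLED_METRICS = (
    "acc_lr", "acc_ud", "acc_ecc25", "acc_ecc37",
    "rt_lr", "rt_ud", "rt_ecc25", "rt_ecc37",
)

ALL_METRICS = PRIMARY_METRICS + POOLED_METRICS

#: Eccentricity contrast pairs: metric name -> (central ring, peripheral ring).
ECC_PAIRS = {"ecc25": (12.5, 25.0), "ecc37": (25.0, 37.5)}

#: Tolerance (degrees) when matching a target eccentricity to a ring.
ECC_MATCH_TOL = 1.0


@dataclass(frozen=True)
class RTTrim:
    """Result of within-player Tukey trimming of correct-trial RTs."""

    input_rts: np.ndarray
    keep_mask: np.ndarray
    fences: Fences | None

    @property
    def kept(self) -> np.ndarray:
        return self.input_rts[self.keep_mask]


def trim_rt_outliers(rts, quartile_method: str = DEFAULT_QUARTILE_METHOD) -> RTTrim:
    """Single-pass Tukey trimming of a player's own correct-trial RTs.

    A trial RT is an outlier if it lies strictly outside the player's own
    1.5×IQR fences; fences are computed once, never re-estimated on the
    kept set.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        return RTTrim(rts, np.zeros(0, dtype=bool), None)
    fences = tukey_fences(rts, method=quartile_method)
    keep = ~outlier_mask(rts, fences)
    return RTTrim(rts, keep, fences)


def accuracy_for_level(trials: list[TrialRecord]) -> float:
    """Percent correct; NaN for an empty trial list (missing, not zero)."""
    if not trials:
        return float("nan")
    return 100.0 * sum(t.correct for t in trials) / len(trials)


def rt_for_level(trials: list[TrialRecord], quartile_method: str = DEFAULT_QUARTILE_METHOD) -> float:
    """Mean correct-trial RT (s) after within-level outlier trimming."""
    rts = np.array([t.rt for t in trials if t.correct], dtype=float)
    trim = trim_rt_outliers(rts, quartile_method)
    kept = trim.kept
    return float(kept.mean()) if kept.size else float("nan")


def raycast_mean(frames: pd.DataFrame, source: str, axis: str, level: str | None = None) -> float:
    """Mean orientation angle (°) over search-array frames.

    ``source`` is ``'headset'`` or ``'controller'``; ``axis`` ``'lateral'``
    or ``'vertical'``.  Cue-phase frames are excluded; missing (NaN) if no
    qualifying frames exist.
    """
    col = {("headset", "lateral"): "head_lat", ("headset", "vertical"): "head_vert",
           ("controller", "lateral"): "ctrl_lat", ("controller", "vertical"): "ctrl_vert"}[
        (source, axis)
    ]
    if not len(frames):
        return float("nan")
    sel = frames["phase"] == "array"
    if level is not None:
        sel &= frames["level"] == level
    vals = frames.loc[sel, col].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def assign_quadrant(pos: AngularPosition) -> str:
    """Dominant-axis quadrant of an array position.

    |lateral| > |vertical| → left/right by sign; the reverse → up/down;
    exact ties and the origin are 'axis' and excluded from quadrant
    contrasts.
    """
    al, av = abs(pos.lateral), abs(pos.vertical)
    if al > av:
        return "right" if pos.lateral > 0 else "left"
    if av > al:
        return "up" if pos.vertical > 0 else "down"
    return "axis"


def _pooled_trial_table(session: PlayerSession, quartile_method: str) -> pd.DataFrame:
    """Per-trial table over analysis levels, with pooled RT trimming applied.

    Columns: level, correct, rt, rt_kept (correct & survived pooled
    trimming), quadrant, ecc (target eccentricity).
    """
    rows = []
    for t in session.trials:
        if t.level not in TRIAL_LEVELS:
            continue
        rows.append(
            {
                "level": t.level,
                "correct": bool(t.correct),
                "rt": float(t.rt),
                "quadrant": assign_quadrant(t.target_position),
                "ecc": t.target_eccentricity,
            }
        )
    df = pd.DataFrame(rows, columns=["level", "correct", "rt", "quadrant", "ecc"])
    df["rt_kept"] = False
    if len(df):
        correct_idx = df.index[df["correct"]]
        trim = trim_rt_outliers(df.loc[correct_idx, "rt"].to_numpy(), quartile_method)
        df.loc[correct_idx, "rt_kept"] = trim.keep_mask
    return df


def _acc_rt_of(sub: pd.DataFrame) -> tuple[float, float]:
    acc = 100.0 * sub["correct"].mean() if len(sub) else float("nan")
    kept = sub.loc[sub["rt_kept"], "rt"]
    rt = float(kept.mean()) if len(kept) else float("nan")
    return float(acc), rt


def spatial_preference(pooled: pd.DataFrame, contrast: str, measure: str) -> float:
    """Quadrant difference score from the pooled trial table.

    ``contrast`` is ``'lr'`` or ``'ud'``; ``measure`` ``'accuracy'`` or
    ``'rt'``.  Subtraction terms are ordered so positive always means a
    right/up preference: accuracy right−left (up−down), RT left−right
    (down−up).  Missing if either side has no usable trials.
    """
    pos_q, neg_q = {"lr": ("right", "left"), "ud": ("up", "down")}[contrast]
    a_pos, rt_pos = _acc_rt_of(pooled[pooled["quadrant"] == pos_q])
    a_neg, rt_neg = _acc_rt_of(pooled[pooled["quadrant"] == neg_q])
    if measure == "accuracy":
        return a_pos - a_neg
    return rt_neg - rt_pos


def eccentricity_preference(
    pooled: pd.DataFrame, pair: tuple[float, float], measure: str, central_positive: bool = True
) -> float:
    """Eccentricity difference score: positive = central advantage (default).

    ``pair`` is (central ring, peripheral ring) in degrees; targets are
    matched to a ring within ±1°.  Accuracy: central − peripheral; RT:
    peripheral − central; both flipped when ``central_positive`` is False.
    """
    central, peripheral = pair
    sub_c = pooled[np.abs(pooled["ecc"] - central) <= ECC_MATCH_TOL]
    sub_p = pooled[np.abs(pooled["ecc"] - peripheral) <= ECC_MATCH_TOL]
    a_c, rt_c = _acc_rt_of(sub_c)
    a_p, rt_p = _acc_rt_of(sub_p)
    score = (a_c - a_p) if measure == "accuracy" else (rt_p - rt_c)
    return score if central_positive else -score


@dataclass
class MetricVector:
    """All 14 attention metrics of one player.

    ``per_level``: DataFrame indexed by level with the six primary metric
    columns (NaN = missing); ``pooled``: the eight spatial-preference
    scores.
    """

    player_id: str
    group: str
    per_level: pd.DataFrame
    pooled: dict[str, float]

    def __post_init__(self) -> None:
        assert tuple(self.per_level.columns) == PRIMARY_METRICS
        assert tuple(self.pooled) == POOLED_METRICS

    @property
    def n_metrics(self) -> int:
        return len(PRIMARY_METRICS) + len(self.pooled)

    def to_long(self) -> pd.DataFrame:
        """One row per (metric, level-or-pooled) value, NaN where missing."""
        rows = []
        for level, row in self.per_level.iterrows():
            for m in PRIMARY_METRICS:
                rows.append((self.player_id, self.group, m, level, row[m]))
        for m, v in self.pooled.items():
            rows.append((self.player_id, self.group, m, "pooled", v))
        df = pd.DataFrame(rows, columns=["player_id", "group", "metric", "level", "value"])
        df["missing"] = df["value"].isna()
        return df


def compute_metric_vector(
    session: PlayerSession,
    quartile_method: str = DEFAULT_QUARTILE_METHOD,
    central_positive: bool = True,
) -> MetricVector:
    """Assemble the full 14-metric vector for one player.

    The tutorial level is excluded.  Free viewing contributes raycast means
    only.  Per-level cells for levels the player did not play are missing;
    an entirely empty session yields an all-missing vector with a warning.
    """
    played = set(session.levels_played)
    ray_cols = ["head_lat", "head_vert", "ctrl_lat", "ctrl_vert"]
    if len(session.frames):
        ray_means = (
            session.frames.loc[session.frames["phase"] == "array", ["level"] + ray_cols]
            .groupby("level")
            .mean()
        )
    else:
        ray_means = pd.DataFrame(columns=ray_cols)
    rows = {}
    for level in ANALYSIS_LEVELS:
        if level not in played:
            rows[level] = {m: float("nan") for m in PRIMARY_METRICS}
            continue
        trials = session.trials_for_level(level) if level in TRIAL_LEVELS else []
        ray = (
            ray_means.loc[level]
            if level in ray_means.index
            else pd.Series(float("nan"), index=ray_cols)
        )
        rows[level] = {
            "accuracy": accuracy_for_level(trials),
            "rt": rt_for_level(trials, quartile_method),
            "head_lat": float(ray["head_lat"]),
            "head_vert": float(ray["head_vert"]),
            "ctrl_lat": float(ray["ctrl_lat"]),
            "ctrl_vert": float(ray["ctrl_vert"]),
        }
    per_level = pd.DataFrame.from_dict(rows, orient="index").reindex(
        list(ANALYSIS_LEVELS)
    )[list(PRIMARY_METRICS)]

    pooled_tab = _pooled_trial_table(session, quartile_method)
    pooled = {
        "acc_lr": spatial_preference(pooled_tab, "lr", "accuracy"),
        "acc_ud": spatial_preference(pooled_tab, "ud", "accuracy"),
        "acc_ecc25": eccentricity_preference(pooled_tab, ECC_PAIRS["ecc25"], "accuracy", central_positive),
        "acc_ecc37": eccentricity_preference(pooled_tab, ECC_PAIRS["ecc37"], "accuracy", central_positive),
        "rt_lr": spatial_preference(pooled_tab, "lr", "rt"),
        "rt_ud": spatial_preference(pooled_tab, "ud", "rt"),
        "rt_ecc25": eccentricity_preference(pooled_tab, ECC_PAIRS["ecc25"], "rt", central_positive),
        "rt_ecc37": eccentricity_preference(pooled_tab, ECC_PAIRS["ecc37"], "rt", central_positive),
    }
    if per_level.isna().all().all() and all(np.isnan(v) for v in pooled.values()):
        warnings.warn(
            f"session {session.player_id!r} has no analysable levels; all metrics missing",
            stacklevel=2,
        )
    return MetricVector(session.player_id, session.group, per_level, pooled)


def metrics_table(vectors: list[MetricVector]) -> pd.DataFrame:
    """Long-format metrics table for a cohort (one row per player × metric ×
    level-or-pooled)."""
    if not vectors:
        return pd.DataFrame(columns=["player_id", "group", "metric", "level", "value", "missing"])
    return pd.concat([v.to_long() for v in vectors], ignore_index=True)
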