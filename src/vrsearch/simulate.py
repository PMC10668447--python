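"""Generative model of VR visual-search gameplay.

The simulator produces trial- and frame-level telemetry with the
statistical structure the analysis pipeline assumes: a cue/array trial
sequence per level, spherical array grids, 90 Hz orientation traces, and —
for impaired agents — a lateralised orienting bias, a hemifield detection
deficit, slowed responses, and give-up distractor selections.

Behaviour model (the package's own; no claim of biological realism beyond
the statistical structure needed to exercise the pipeline):

* **Inspection choice** — a softmax over negative "biased" angular
  distance: element *i* is inspected next with weight
  ``exp(−(d(i, gaze) + λ·d(i, rest)) / τ)`` where ``rest`` is the agent's
  resting orientation, offset from straight ahead by the lateral/vertical
  bias.  Elements near both the current gaze and the (biased) resting
  direction are favoured, so a rightward bias makes right-hemifield
  elements be inspected earlier.
* **Detection** — inspecting the target detects it with probability
  ``1 − slope × max(0, angle into the neglected hemifield)``; the neglected
  side is contralateral to the bias direction.  After ``give_up_after``
  inspections without detection the agent gives up and selects the
  inspected distractor nearest its gaze.
* **Orientation traces** — gaze interpolates linearly between the resting
  direction and successive inspected elements (a re-centring dwell precedes
  each excursion).  The head carries the postural bias and follows gaze
  excursions with a small gain; the controller with a somewhat larger gain;
  both get white orientation noise.  The head-gain construction makes the
  headset lateral mean a consistent estimator of the injected bias.
* **Timing** — each inspection costs a noisy dwell; selection adds a motor
  constant.  RT is the array-phase (cue-selection → selection) interval.

All randomness flows from a single seed through ``numpy``'s SeedSequence
spawning, so cohorts are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .geometry import AngularPosition, angular_distance_matrix, ring_positions
from .model import (
    FRAME_COLUMNS,
    GameConfig,
    LevelConfig,
    PlayerSession,
    TrialRecord,
    default_game,
)

CUE_DURATION = 0.8  # seconds the central cue is fixated before array onset
MIN_DWELL = 0.05  # floor on a single inspection dwell, seconds


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated player.

    Units: biases and noise in degrees, dwell/motor times in seconds,
    ``contralesional_miss_slope`` in extra miss probability per degree into
    the neglected hemifield, ``frame_rate`` in Hz.
    """

    lateral_bias: float = 0.0  # positive = rightward orienting preference
    vertical_bias: float = 0.0
    contralesional_miss_slope: float = 0.0
    base_dwell: float = 0.6
    dwell_noise_sd: float = 0.15
    orientation_noise_sd: float = 3.0
    give_up_after: int = 20
    selection_error_rate: float = 0.02
    frame_rate: float = 90.0
    motor_time: float = 0.4
    # behaviour-model shape parameters
    softmax_temperature: float = 10.0  # degrees
    rest_weight: float = 1.0  # λ: pull of the resting direction on inspection choice
    head_gain: float = 0.1  # head excursion toward gaze, fraction
    ctrl_gain: float = 0.2
    recentre_fraction: float = 0.5  # fraction of each dwell spent re-centring

    def __post_init__(self) -> None:
        if not (0 <= self.selection_error_rate <= 1):
            raise ValueError("selection_error_rate must lie in [0, 1]")
        if self.frame_rate <= 0 or self.base_dwell <= 0 or self.motor_time <= 0:
            raise ValueError("rates and durations must be positive")
        if self.give_up_after < 1:
            raise ValueError("give_up_after must be at least 1")

    @property
    def rest(self) -> np.ndarray:
        return np.array([self.lateral_bias, self.vertical_bias])

    @property
    def neglected_sign(self) -> float:
        """Sign of the neglected lateral hemifield (−1 = left)."""
        return -1.0 if self.lateral_bias >= 0 else 1.0


def level_elements(level: LevelConfig, trial_index: int) -> np.ndarray:
    """Array-element positions (n, 2) in degrees for one trial of a level.

    The axes level alternates horizontal and vertical on-axis arrays;
    ring levels place elements at polar phase 22.5° so every element has an
    unambiguous quadrant.
    """
    if level.name == "axes":
        eccs = np.array([12.5, 25.0, 37.5, 50.0])
        if trial_index % 2 == 0:  # horizontal trial
            return np.column_stack([np.concatenate([eccs, -eccs]), np.zeros(8)])
        return np.column_stack([np.zeros(8), np.concatenate([eccs, -eccs])])
    positions: list[AngularPosition] = []
    for ecc, n in zip(level.ring_eccentricities, level.elements_per_ring):
        positions.extend(ring_positions(ecc, n, phase_deg=22.5))
    return np.array([[p.lateral, p.vertical] for p in positions])


def _gaze_keypoints(
    inspected: np.ndarray, dwells: np.ndarray, rest: np.ndarray, recentre: float
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear gaze path: times and (lateral, vertical) keypoints."""
    times = [0.0]
    points = [rest]
    t = 0.0
    for pos, dwell in zip(inspected, dwells):
        t_mid = t + recentre * dwell
        t_end = t + dwell
        times.extend([t_mid, t_end])
        points.extend([rest, pos])
        t = t_end
    return np.asarray(times), np.asarray(points)


def _simulate_trial_arrays(
    agent: AgentParams,
    level: LevelConfig,
    rng: np.random.Generator,
    player_id: str = "sim",
    trial_index: int = 0,
) -> tuple[TrialRecord, dict]:
    """Trial core returning frame columns as plain arrays (fast path)."""
    if not level.has_trials:
        raise ValueError(f"level {level.name!r} has no trials")
    elements = level_elements(level, trial_index)
    n = len(elements)
    target_idx = int(rng.integers(n))
    rest = agent.rest
    tau = agent.softmax_temperature
    d_rest = angular_distance_matrix(elements, rest)

    gaze = rest.copy()
    visited: set[int] = set()
    inspected: list[int] = []
    found = False
    for _ in range(agent.give_up_after):
        if len(visited) == n:
            visited.clear()  # new scan round over the full array
        d_gaze = angular_distance_matrix(elements, gaze)
        logw = -(d_gaze + agent.rest_weight * d_rest) / tau
        logw -= logw.max()
        w = np.exp(logw)
        w[list(visited)] = 0.0
        w_sum = w.sum()
        if w_sum <= 0:
            w = np.full(n, 1.0 / n)
        else:
            w = w / w_sum
        i = int(rng.choice(n, p=w))
        visited.add(i)
        inspected.append(i)
        gaze = elements[i]
        if i == target_idx:
            angle_into_neglect = max(
                0.0, agent.neglected_sign * elements[i, 0]
            )
            miss_p = min(0.95, agent.contralesional_miss_slope * angle_into_neglect)
            if rng.random() >= miss_p:
                found = True
                break

    dwells = np.maximum(
        MIN_DWELL, agent.base_dwell + rng.normal(0, agent.dwell_noise_sd, len(inspected))
    )
    rt = float(dwells.sum() + agent.motor_time)

    if found:
        if rng.random() < agent.selection_error_rate and n > 1:
            others = [j for j in range(n) if j != target_idx]
            sel_idx = int(rng.choice(others))
        else:
            sel_idx = target_idx
    else:  # give up: select the inspected distractor nearest the current gaze
        cand = [j for j in set(inspected) if j != target_idx]
        if not cand:
            cand = [j for j in range(n) if j != target_idx]
        d = angular_distance_matrix(elements[cand], gaze)
        sel_idx = int(cand[int(np.argmin(d))])

    target = AngularPosition(*elements[target_idx])
    selected = AngularPosition(*elements[sel_idx])
    depth_radius = float(rng.choice(level.depth_radii)) if len(level.depth_radii) > 1 else level.depth_radii[0]
    trial = TrialRecord(
        player_id=player_id,
        level=level.name,
        trial_index=trial_index,
        target_position=target,
        selected_position=selected,
        correct=sel_idx == target_idx,
        rt=rt,
        element_positions=elements,
        depth_radius=depth_radius,
    )

    # frames: cue phase at the centre, then the array-phase gaze path
    n_cue = max(1, int(round(CUE_DURATION * agent.frame_rate)))
    n_arr = max(1, int(round(rt * agent.frame_rate)))
    t_cue = np.arange(n_cue) / agent.frame_rate
    t_arr = np.arange(n_arr) / agent.frame_rate
    key_t, key_p = _gaze_keypoints(elements[inspected], dwells, rest, agent.recentre_fraction)
    gaze_lat = np.interp(t_arr, key_t, key_p[:, 0])
    gaze_vert = np.interp(t_arr, key_t, key_p[:, 1])
    cue_gaze = np.zeros((n_cue, 2))  # fixating the central cue
    gaze_all = np.vstack([cue_gaze, np.column_stack([gaze_lat, gaze_vert])])
    noise = rng.normal(0, agent.orientation_noise_sd, size=(len(gaze_all), 4))
    head = rest + agent.head_gain * (gaze_all - rest) + noise[:, :2]
    ctrl = rest + agent.ctrl_gain * (gaze_all - rest) + noise[:, 2:]
    n_frames = n_cue + n_arr
    cols = {
        "level": np.full(n_frames, level.name, dtype=object),
        "trial_index": np.full(n_frames, trial_index),
        "time_s": np.concatenate([t_cue, CUE_DURATION + t_arr]),
        "phase": np.array(["cue"] * n_cue + ["array"] * n_arr, dtype=object),
        "head_lat": head[:, 0],
        "head_vert": head[:, 1],
        "ctrl_lat": ctrl[:, 0],
        "ctrl_vert": ctrl[:, 1],
    }
    return trial, cols


def simulate_trial(
    agent: AgentParams,
    level: LevelConfig,
    rng: np.random.Generator,
    player_id: str = "sim",
    trial_index: int = 0,
) -> tuple[TrialRecord, pd.DataFrame]:
    """One cue/array trial: a trial record plus its frame table.

    Frame times are seconds from cue onset; the cue phase lasts
    ``CUE_DURATION`` and the array phase lasts the trial RT.
    """
    trial, cols = _simulate_trial_arrays(agent, level, rng, player_id, trial_index)
    return trial, pd.DataFrame(cols)


def _simulate_free_viewing(
    agent: AgentParams, level: LevelConfig, rng: np.random.Generator
) -> dict:
    """Free-viewing frame columns: gaze wanders around the resting direction."""
    duration = level.min_duration * 60.0
    n_key = max(2, int(duration) + 1)  # one wander target per second
    key_t = np.linspace(0.0, duration, n_key)
    key_p = agent.rest + rng.normal(0, 15.0, size=(n_key, 2))
    n_frames = max(1, int(round(duration * agent.frame_rate)))
    t = np.arange(n_frames) / agent.frame_rate
    gaze = np.column_stack(
        [np.interp(t, key_t, key_p[:, 0]), np.interp(t, key_t, key_p[:, 1])]
    )
    noise = rng.normal(0, agent.orientation_noise_sd, size=(n_frames, 4))
    head = agent.rest + agent.head_gain * (gaze - agent.rest) + noise[:, :2]
    ctrl = agent.rest + agent.ctrl_gain * (gaze - agent.rest) + noise[:, 2:]
    return {
        "level": np.full(n_frames, level.name, dtype=object),
        "trial_index": np.zeros(n_frames, dtype=int),
        "time_s": t,
        "phase": np.full(n_frames, "array", dtype=object),
        "head_lat": head[:, 0],
        "head_vert": head[:, 1],
        "ctrl_lat": ctrl[:, 0],
        "ctrl_vert": ctrl[:, 1],
    }


def simulate_session(
    agent: AgentParams,
    game: GameConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    player_id: str = "sim",
    group: str = "control",
) -> PlayerSession:
    """A full session: trials per level until each level's minimum duration.

    Deterministic given ``seed``; the same seed yields an identical
    session.
    """
    if game is None:
        game = default_game()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    trials: list[TrialRecord] = []
    frame_chunks: list[dict] = []
    for level in game.levels:
        if not level.has_trials:
            frame_chunks.append(_simulate_free_viewing(agent, level, rng))
            continue
        elapsed = 0.0
        idx = 0
        min_s = level.min_duration * 60.0
        while elapsed < min_s:
            trial, cols = _simulate_trial_arrays(agent, level, rng, player_id, idx)
            cols["time_s"] = cols["time_s"] + elapsed
            trials.append(trial)
            frame_chunks.append(cols)
            elapsed += CUE_DURATION + trial.rt
            idx += 1
    if frame_chunks:
        frames_df = pd.DataFrame(
            {c: np.concatenate([ch[c] for ch in frame_chunks]) for c in FRAME_COLUMNS}
        )
    else:
        frames_df = pd.DataFrame(columns=FRAME_COLUMNS)
    return PlayerSession(player_id=player_id, group=group, trials=trials, frames=frames_df)


def control_sampler(rng: np.random.Generator, base: AgentParams) -> AgentParams:
    """Default control-group agent: unbiased, small individual variation."""
    return replace(
        base,
        lateral_bias=float(rng.normal(0, 1.0)),
        vertical_bias=float(rng.normal(0, 1.0)),
        base_dwell=float(base.base_dwell * rng.uniform(0.9, 1.1)),
    )


def patient_sampler(rng: np.random.Generator, base: AgentParams) -> AgentParams:
    """Default patient-group agent mixture: sparse, heterogeneous deficits.

    Each patient draws one profile: mostly typical gameplay (like the
    controls), with a minority carrying one distinctive deficit each — a
    lateralised orienting bias (magnitude 10–30°, direction mostly toward
    the right hemispace as after right-hemisphere injury, with a
    contralesional detection deficit), a vertical orienting bias, marked
    slowing, or a hemifield detection deficit without orienting bias.
    Deficits are individually varied and sparse within the group, so an
    affected patient is atypical with respect to *both* reference
    distributions, mirroring heterogeneous clinical presentations.
    """
    u = rng.random()
    if u < 0.40:  # typical, possibly mildly slowed
        return replace(
            base,
            lateral_bias=float(rng.normal(0, 1.5)),
            vertical_bias=float(rng.normal(0, 1.5)),
            base_dwell=float(base.base_dwell * rng.uniform(1.0, 1.3)),
        )
    if u < 0.65:  # lateralised orienting bias + contralesional deficit
        sign = 1.0 if rng.random() < 0.75 else -1.0
        return replace(
            base,
            lateral_bias=float(sign * rng.uniform(10.0, 30.0)),
            vertical_bias=float(rng.normal(0, 2.0)),
            contralesional_miss_slope=float(rng.uniform(0.01, 0.03)),
            base_dwell=float(base.base_dwell * rng.uniform(1.2, 2.0)),
        )
    if u < 0.75:  # vertical orienting bias
        return replace(
            base,
            lateral_bias=float(rng.normal(0, 1.5)),
            vertical_bias=float(rng.choice([-1.0, 1.0]) * rng.uniform(8.0, 20.0)),
            base_dwell=float(base.base_dwell * rng.uniform(1.0, 1.5)),
        )
    if u < 0.90:  # marked non-spatial slowing
        return replace(
            base,
            lateral_bias=float(rng.normal(0, 1.5)),
            vertical_bias=float(rng.normal(0, 1.5)),
            base_dwell=float(base.base_dwell * rng.uniform(2.5, 4.0)),
        )
    # hemifield detection deficit without orienting bias
    return replace(
        base,
        lateral_bias=float(rng.normal(0, 1.5)),
        vertical_bias=float(rng.normal(0, 1.5)),
        contralesional_miss_slope=float(rng.uniform(0.02, 0.05)),
        base_dwell=float(base.base_dwell * rng.uniform(1.2, 1.8)),
    )


@dataclass
class CohortSpec:
    """Specification of a simulated cohort.

    ``control_sampler`` / ``patient_sampler`` draw per-player agent
    parameters from group-level distributions; the defaults encode an
    unbiased clinician control group and a heterogeneous patient group.
    Group sizes default to the 9-control / 13-patient study design.
    """

    n_controls: int = 9
    n_patients: int = 13
    game: GameConfig = field(default_factory=default_game)
    master_seed: int = 0
    base_params: AgentParams = field(default_factory=AgentParams)
    control_sampler: Callable[[np.random.Generator, AgentParams], AgentParams] = control_sampler
    patient_sampler: Callable[[np.random.Generator, AgentParams], AgentParams] = patient_sampler

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("group sizes must be non-negative")


def simulate_cohort(spec: CohortSpec) -> list[PlayerSession]:
    """Simulate every player in a cohort spec.

    Child seeds are spawned deterministically from the master seed, so the
    cohort is reproducible and players are independent.
    """
    root = np.random.SeedSequence(spec.master_seed)
    n_total = spec.n_controls + spec.n_patients
    children = root.spawn(2 * n_total) if n_total else []
    sessions: list[PlayerSession] = []
    k = 0
    for g, n, sampler in (
        ("control", spec.n_controls, spec.control_sampler),
        ("patient", spec.n_patients, spec.patient_sampler),
    ):
        for i in range(n):
            param_rng = np.random.default_rng(children[k])
            agent = sampler(param_rng, spec.base_params)
            pid = f"{'C' if g == 'control' else 'P'}{i + 1:02d}"
            sessions.append(
                simulate_session(agent, spec.game, seed=children[k + 1], player_id=pid, group=g)
            )
            k += 2
    return sessions


def unbiased_cohort_spec(
    n_controls: int = 9,
    n_patients: int = 13,
    game: GameConfig | None = None,
    master_seed: int = 0,
    base_params: AgentParams | None = None,
) -> CohortSpec:
    """A null cohort: every player unbiased (both groups use the control
    sampler).  Used for false-positive calibration of the atypicality rule."""
    return CohortSpec(
        n_controls=n_controls,
        n_patients=n_patients,
        game=game or default_game(),
        master_seed=master_seed,
        base_params=base_params or AgentParams(),
        patient_sampler=control_sampler,
    )


def quick_game(duration_scale: float = 0.02, frame_rate: float | None = None) -> tuple[GameConfig, AgentParams]:
    """A scaled-down game + agent base for bulk simulation studies.

    Scales every level's minimum duration and (optionally) the frame rate;
    the level structure, grids and behaviour model are unchanged.
    """
    game = default_game().scaled(duration_scale)
    base = AgentParams(frame_rate=frame_rate) if frame_rate else AgentParams()
    return game, base


def make_fixture_cohort() -> tuple[list[PlayerSession], pd.DataFrame]:
    """A tiny hand-constructed cohort with hand-computed expected metrics.

    Seven players (3 controls, 4 patients), each with four axes-level
    trials at eccentricity 25° (one target per quadrant) and ten
    constant-orientation array-phase frames.  Patient ``P3`` is constructed
    with a strong rightward head orientation (+30°) and a missed left
    target, so the atypicality pipeline must flag it on the lateral headset
    metric; everyone else is near-centred.  The expected table freezes
    hand-computed metric values.
    """
    targets = [
        AngularPosition(25.0, 0.0),
        AngularPosition(-25.0, 0.0),
        AngularPosition(0.0, 25.0),
        AngularPosition(0.0, -25.0),
    ]
    elements = np.array([[p.lateral, p.vertical] for p in targets])

    def player(pid, group, correct, rt, head_lat):
        trials = []
        for k, (tgt, ok) in enumerate(zip(targets, correct)):
            sel = tgt if ok else targets[(k + 1) % 4]
            trials.append(
                TrialRecord(
                    player_id=pid, level="axes", trial_index=k,
                    target_position=tgt, selected_position=sel,
                    correct=ok, rt=rt, element_positions=elements,
                )
            )
        frames = pd.DataFrame(
            {
                "level": "axes",
                "trial_index": 0,
                "time_s": np.arange(10) / 10.0,
                "phase": "array",
                "head_lat": float(head_lat),
                "head_vert": 0.0,
                "ctrl_lat": float(head_lat),
                "ctrl_vert": 0.0,
            }
        )
        return PlayerSession(player_id=pid, group=group, trials=trials, frames=frames)

    sessions = [
        player("C1", "control", [True, True, True, True], 2.0, 0.0),
        player("C2", "control", [True, True, True, False], 2.2, 1.0),
        player("C3", "control", [True, True, True, True], 1.8, -1.0),
        player("P1", "patient", [True, True, True, True], 3.0, 2.0),
        player("P2", "patient", [True, False, True, False], 3.5, -2.0),
        player("P3", "patient", [True, False, True, True], 4.0, 30.0),
        player("P4", "patient", [True, True, True, True], 2.5, -1.0),
    ]
    # hand-computed expectations (axes level; trimming keeps all equal RTs)
    expected = pd.DataFrame(
        [
            ("C1", "accuracy", "axes", 100.0), ("C1", "rt", "axes", 2.0), ("C1", "head_lat", "axes", 0.0),
            ("C2", "accuracy", "axes", 75.0), ("C2", "rt", "axes", 2.2), ("C2", "head_lat", "axes", 1.0),
            ("C3", "accuracy", "axes", 100.0), ("C3", "rt", "axes", 1.8), ("C3", "head_lat", "axes", -1.0),
            ("P1", "accuracy", "axes", 100.0), ("P1", "rt", "axes", 3.0), ("P1", "head_lat", "axes", 2.0),
            ("P2", "accuracy", "axes", 50.0), ("P2", "rt", "axes", 3.5), ("P2", "head_lat", "axes", -2.0),
            ("P3", "accuracy", "axes", 75.0), ("P3", "rt", "axes", 4.0), ("P3", "head_lat", "axes", 30.0),
            ("P4", "accuracy", "axes", 100.0), ("P4", "rt", "axes", 2.5), ("P4", "head_lat", "axes", -1.0),
            # pooled quadrant contrasts (right − left accuracy; left − right RT)
            ("C1", "acc_lr", "pooled", 0.0), ("C1", "rt_lr", "pooled", 0.0),
            ("P3", "acc_lr", "pooled", 100.0), ("P3", "rt_lr", "pooled", float("nan")),
        ],
        columns=["player_id", "metric", "level", "value"],
    )
    return sessions, expected
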