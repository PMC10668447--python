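"""Simulate the study-sized cohort and write its telemetry tables.

Generates 9 unbiased clinician-control sessions and 13 heterogeneous
patient sessions (a minority carrying lateralised orienting biases,
hemifield detection deficits, or marked slowing), using a duration-scaled
version of the six-level short game so the whole analysis runs in about a
minute.  Writes trials.csv, frames.csv and game.json under results/cohort/.
"""

from pathlib import Path

from vrsearch.io import game_to_json, write_sessions
from vrsearch.simulate import CohortSpec, quick_game, simulate_cohort

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    game, base = quick_game(duration_scale=0.1, frame_rate=10.0)
    spec = CohortSpec(n_controls=9, n_patients=13, game=game,
                      master_seed=SEED, base_params=base)
    sessions = simulate_cohort(spec)
    OUT.mkdir(parents=True, exist_ok=True)
    write_sessions(sessions, OUT / "trials.csv", OUT / "frames.csv")
    game_to_json(game, OUT / "game.json")
    n_trials = sum(len(s.trials) for s in sessions)
    n_frames = sum(len(s.frames) for s in sessions)
    print(f"simulated {len(sessions)} players ({n_trials} trials, "
          f"{n_frames} frames) -> {OUT}")


if __name__ == "__main__":
    main()
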