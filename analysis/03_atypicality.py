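"""Flag visuospatial atypicality and build the player × metric summary matrix.

Estimates control- and patient-group Tukey fences per metric (and per level
for the six primary metrics), flags values falling strictly outside BOTH
groups' fences, and writes summary_matrix.csv, fences.csv and
atypicality_summary.json under results/.
"""

import json
import warnings
from pathlib import Path

import numpy as np

from vrsearch.atypicality import build_summary_matrix
from vrsearch.io import read_sessions
from vrsearch.metrics import compute_metric_vector

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sessions = read_sessions(ROOT / "cohort" / "trials.csv",
                             ROOT / "cohort" / "frames.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = build_summary_matrix([compute_metric_vector(s) for s in sessions])
    matrix.cells.to_csv(ROOT / "summary_matrix.csv", na_rep="NA")
    matrix.fences.to_csv(ROOT / "fences.csv", index=False)
    mean_atyp = matrix.mean_atypicality_series()
    summary = {
        pid: {
            "group": matrix.groups[pid],
            "mean_atypicality": None if np.isnan(mean_atyp[pid]) else round(float(mean_atyp[pid]), 4),
            "atypical_metrics": matrix.flagged_metrics(pid),
        }
        for pid in matrix.player_ids
    }
    (ROOT / "atypicality_summary.json").write_text(json.dumps(summary, indent=2))
    n_flagged = sum(bool(v["atypical_metrics"]) for v in summary.values())
    print(f"summary matrix {matrix.cells.shape[0]} players x "
          f"{matrix.cells.shape[1]} metrics; {n_flagged} players atypical on >=1 metric")
    for pid, v in summary.items():
        if v["atypical_metrics"]:
            print(f"  {pid} ({v['group']}): mean atypicality {v['mean_atypicality']}, "
                  f"flagged: {', '.join(v['atypical_metrics'])}")


if __name__ == "__main__":
    main()
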