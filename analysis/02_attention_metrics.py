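"""Compute the 14 attention metrics for every player in the cohort.

Reads results/cohort/{trials,frames}.csv, computes per-level accuracy,
trimmed RT and raycast means plus the eight pooled spatial-preference
scores, and writes the long-format table to results/metrics.csv.
"""

from pathlib import Path

from vrsearch.io import read_sessions
from vrsearch.metrics import compute_metric_vector, metrics_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sessions = read_sessions(ROOT / "cohort" / "trials.csv",
                             ROOT / "cohort" / "frames.csv")
    vectors = [compute_metric_vector(s) for s in sessions]
    table = metrics_table(vectors)
    table.to_csv(ROOT / "metrics.csv", index=False)
    n_missing = int(table["missing"].sum())
    print(f"computed 14 metrics for {len(vectors)} players "
          f"({len(table)} metric cells, {n_missing} missing) -> {ROOT/'metrics.csv'}")


if __name__ == "__main__":
    main()
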