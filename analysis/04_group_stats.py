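"""Group-level statistics: typicality counts, chi-square, rank-sum, Levene.

Also reports the descriptive statistics of the bundled patient demographic
table.  Writes results/group_stats.json and results/demographics_summary.json.
"""

import json
import warnings
from pathlib import Path

from vrsearch.atypicality import build_summary_matrix
from vrsearch.demographics import demographics_summary
from vrsearch.io import read_sessions
from vrsearch.metrics import compute_metric_vector
from vrsearch.stats import group_stats

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sessions = read_sessions(ROOT / "cohort" / "trials.csv",
                             ROOT / "cohort" / "frames.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = build_summary_matrix([compute_metric_vector(s) for s in sessions])
        g = group_stats(matrix)
    (ROOT / "group_stats.json").write_text(json.dumps(g, indent=2))

    demo = demographics_summary()
    (ROOT / "demographics_summary.json").write_text(json.dumps(demo, indent=2))

    print(f"typicality counts (boolean grain): patients {g['counts']['patients_atypical']}"
          f"/{g['counts']['patients_atypical'] + g['counts']['patients_typical']} atypical, "
          f"controls {g['counts']['controls_atypical']}"
          f"/{g['counts']['controls_atypical'] + g['counts']['controls_typical']}")
    print(f"chi2 = {g['chi2']['statistic']:.2f}, p = {g['chi2']['p']:.2g}")
    print(f"mean atypicality: rank-sum z = {g['rank_sum_mean_atypicality']['statistic']:.2f} "
          f"(p = {g['rank_sum_mean_atypicality']['p']:.2g}); "
          f"Levene L = {g['levene_mean_atypicality']['statistic']:.2f} "
          f"(p = {g['levene_mean_atypicality']['p']:.2g})")
    print(f"patients atypical on >=1 metric: "
          f"{g['players_atypical_ge1_metric']['patients']}/13 "
          f"({g['players_atypical_ge1_metric']['patients_pct']:.1f}%); controls: "
          f"{g['players_atypical_ge1_metric']['controls']}/9 "
          f"({g['players_atypical_ge1_metric']['controls_pct']:.1f}%)")
    print(f"demographics: median age {demo['age_median']:.0f} y (IQR {demo['age_iqr']:.0f}), "
          f"neglect prevalence {demo['neglect_prevalence_pct']:.1f}%")


if __name__ == "__main__":
    main()
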