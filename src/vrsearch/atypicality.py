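"""Normative modelling of gameplay: double-reference Tukey-fence atypicality.

A player's metric value is *atypical* when it lies strictly outside the
1.5×IQR Tukey fences of **both** reference groups (controls and patients).
The conjunction makes the rule conservative: a value flagged here is an
outlier with respect to each group separately, so the false-positive rate
can never exceed the single-group Tukey rate.

Per-level metrics are flagged per metric × level (fences estimated within
each level) and summarised per player as the mean Boolean across the
player's non-missing levels — a proportion in [0, 1].  Pooled metrics yield
a single Boolean.  The resulting player × 14-metric summary matrix is the
unit of all downstream group statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import ALL_METRICS, MetricVector, metrics_table
from .tukey import DEFAULT_QUARTILE_METHOD, Fences, tukey_fences

#: Minimum group size for quartile (hence fence) estimation.
MIN_GROUP_N = 2


@dataclass(frozen=True)
class GroupFences(Fences):
    """Tukey fences of one metric (× level) within one reference group."""

    metric: str = ""
    level: str = "pooled"
    group: str = ""


def group_fences(
    values,
    metric: str = "",
    level: str = "pooled",
    group: str = "",
    quartile_method: str = DEFAULT_QUARTILE_METHOD,
) -> GroupFences | None:
    """Fences from one group's values for one metric×level.

    Returns None (fences undefined) when fewer than two non-missing values
    are available; downstream cells then become missing, never silently
    typical.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < MIN_GROUP_N:
        return None
    f = tukey_fences(v, method=quartile_method)
    return GroupFences(
        q1=f.q1, q3=f.q3, lower=f.lower, upper=f.upper, n=f.n,
        metric=metric, level=level, group=group,
    )


def atypical_flag(value: float, control_fences: Fences, patient_fences: Fences) -> float:
    """1.0 iff the value is a strict Tukey outlier w.r.t. BOTH groups.

    NaN propagates as NaN (missing cell).
    """
    if np.isnan(value):
        return float("nan")
    out_c = value < control_fences.lower or value > control_fences.upper
    out_p = value < patient_fences.lower or value > patient_fences.upper
    return float(out_c and out_p)


@dataclass
class SummaryMatrix:
    """Player × metric atypicality values in [0, 1] with missingness.

    ``cells``: DataFrame (players × 14 metrics) of atypicality proportions
    (NaN = missing).  ``flags``: the finest-grain Boolean table (one row per
    player × metric × level-or-pooled) from which cells are averaged and
    typicality counts are tallied.  ``fences``: the per-metric×level×group
    fence table.
    """

    cells: pd.DataFrame
    groups: pd.Series  # player_id -> 'control' | 'patient'
    flags: pd.DataFrame
    fences: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def player_ids(self) -> list[str]:
        return list(self.cells.index)

    def mean_atypicality(self, player_id: str) -> float:
        return mean_atypicality(self.cells.loc[player_id])

    def mean_atypicality_series(self) -> pd.Series:
        return self.cells.apply(lambda row: mean_atypicality(row), axis=1)

    def flagged_metrics(self, player_id: str) -> list[str]:
        row = self.cells.loc[player_id]
        return [m for m in self.cells.columns if row[m] > 0]


def mean_atypicality(row: pd.Series) -> float:
    """Mean of a player's non-missing atypicality cells, in [0, 1]."""
    vals = row.to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def build_summary_matrix(
    vectors: list[MetricVector],
    quartile_method: str = DEFAULT_QUARTILE_METHOD,
    leave_one_out: bool = False,
) -> SummaryMatrix:
    """Atypicality summary matrix for a cohort of metric vectors.

    Fences are estimated per metric × level within each reference group;
    by default the evaluated player contributes to their own group's
    quartiles (``leave_one_out=True`` holds them out).  A group with fewer
    than two usable values leaves the affected cells missing with a
    warning.
    """
    long = metrics_table(vectors)
    groups = pd.Series(
        {v.player_id: v.group for v in vectors}, name="group"
    )
    player_ids = [v.player_id for v in vectors]

    flag_rows = []
    fence_rows = []
    warned: set[tuple[str, str]] = set()
    for (metric, level), sub in long.groupby(["metric", "level"], sort=False):
        sub = sub.set_index("player_id")
        vals = sub["value"]
        grp = sub["group"]
        if not leave_one_out:
            fences = {
                g: group_fences(vals[grp == g], metric, level, g, quartile_method)
                for g in ("control", "patient")
            }
            for g, f in fences.items():
                if f is not None:
                    fence_rows.append(
                        {"metric": metric, "level": level, "group": g, "q1": f.q1,
                         "q3": f.q3, "iqr": f.iqr, "lower": f.lower, "upper": f.upper,
                         "n": f.n}
                    )
        for pid in sub.index:
            value = vals[pid]
            if np.isnan(value):
                flag = float("nan")
            else:
                if leave_one_out:
                    fences = {
                        g: group_fences(
                            vals[(grp == g) & (vals.index != pid)]
                            if g == grp[pid]
                            else vals[grp == g],
                            metric, level, g, quartile_method,
                        )
                        for g in ("control", "patient")
                    }
                fc, fp = fences["control"], fences["patient"]
                if fc is None or fp is None:
                    flag = float("nan")
                    if (metric, level) not in warned:
                        warnings.warn(
                            f"fences undefined for metric {metric!r} level {level!r} "
                            "(group smaller than 2); cells left missing",
                            stacklevel=2,
                        )
                        warned.add((metric, level))
                else:
                    flag = atypical_flag(value, fc, fp)
            flag_rows.append(
                {"player_id": pid, "group": grp[pid], "metric": metric,
                 "level": level, "value": value, "flag": flag}
            )

    flags = pd.DataFrame(flag_rows)
    cells = (
        flags.pivot_table(index="player_id", columns="metric", values="flag", aggfunc="mean")
        .reindex(index=player_ids, columns=list(ALL_METRICS))
    )
    cells.columns.name = None
    fences_df = pd.DataFrame(
        fence_rows,
        columns=["metric", "level", "group", "q1", "q3", "iqr", "lower", "upper", "n"],
    )
    return SummaryMatrix(cells=cells, groups=groups.reindex(player_ids), flags=flags,
                         fences=fences_df)
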