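"""Group-level nonparametric statistics on atypicality and questionnaires.

Everything here is distribution-free, matching the analysis philosophy of
the pipeline: Pearson chi-square on 2×2 typicality counts (no continuity
correction by default), Wilcoxon rank-sum and signed-rank tests with
midrank tie handling and normal approximations, and the Brown–Forsythe
(median-centred) Levene test.  Test statistics are computed in-package from
their textbook definitions; scipy supplies the reference distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atypicality import SummaryMatrix


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Typicality counts: rows (patients, controls) × columns (atypical, typical)."""

    patients_atypical: int
    patients_typical: int
    controls_atypical: int
    controls_typical: int

    def __post_init__(self) -> None:
        if min(self.patients_atypical, self.patients_typical,
               self.controls_atypical, self.controls_typical) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return (self.patients_atypical + self.patients_typical
                + self.controls_atypical + self.controls_typical)

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.patients_atypical, self.patients_typical],
             [self.controls_atypical, self.controls_typical]]
        )


def typicality_counts(matrix: SummaryMatrix, grain: str = "boolean") -> ContingencyTable2x2:
    """Tally typical/atypical Booleans by group from a summary matrix.

    ``grain='boolean'`` (default) counts the finest-grain Booleans: one per
    player × metric × level for per-level metrics and one per player ×
    metric for pooled metrics.  ``grain='cell'`` instead thresholds each
    player × metric cell (atypical iff the cell proportion > 0).  Missing
    entries are excluded from both.
    """
    if grain == "boolean":
        flags = matrix.flags.dropna(subset=["flag"])
        by = flags.groupby("group")["flag"]
        atyp = by.sum()
        n = by.count()
    elif grain == "cell":
        stacked = matrix.cells.stack(future_stack=True).rename("flag").reset_index()
        stacked["group"] = stacked["player_id"].map(matrix.groups)
        stacked = stacked.dropna(subset=["flag"])
        stacked["flag"] = (stacked["flag"] > 0).astype(float)
        by = stacked.groupby("group")["flag"]
        atyp = by.sum()
        n = by.count()
    else:
        raise ValueError(f"unknown counting grain {grain!r}")
    pa = int(atyp.get("patient", 0))
    pn = int(n.get("patient", 0))
    ca = int(atyp.get("control", 0))
    cn = int(n.get("control", 0))
    return ContingencyTable2x2(pa, pn - pa, ca, cn - ca)


def chisq_2x2(table: ContingencyTable2x2, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2×2 table, 1 df; no Yates correction by default.

    Uses the closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); a zero margin is
    an error (the statistic is undefined).
    """
    a, b = table.patients_atypical, table.patients_typical
    c, d = table.controls_atypical, table.controls_typical
    n = table.total
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: a table margin is zero")
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff**2 / np.prod([float(m) for m in margins])
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_test(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum test with midrank ties and normal approximation.

    Statistic convention: the tie-corrected standardised rank sum of ``x``,
    z = (R_x − E[R_x]) / sd; two-sided p from the normal distribution with a
    0.5 continuity correction (keeps the approximation close to the exact
    permutation p at small sample sizes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = _midranks(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    expected = n1 * (n + 1) / 2.0
    # tie correction to the rank-sum variance
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n) * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 0.0, 1.0
    sd = np.sqrt(var)
    z = (r1 - expected) / sd
    z_cc = max(abs(r1 - expected) - 0.5, 0.0) / sd
    p = 2.0 * float(sps.norm.sf(z_cc))
    return float(z), min(p, 1.0)


def signed_rank_test(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ties get midranks.  The statistic is W =
    the smaller of the positive/negative rank sums; p is two-sided from the
    continuity-corrected normal approximation.  All-zero differences give
    (0, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    ranks = _midranks(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    w = min(w_pos, w_neg)
    n = d.size
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    if var == 0:
        return float(w), 1.0
    z_cc = max(abs(w - mean) - 0.5, 0.0) / np.sqrt(var)
    p = 2.0 * float(sps.norm.sf(z_cc))
    return float(w), min(p, 1.0)


def levene_test(x, y, center: str = "median") -> tuple[float, float]:
    """Levene's test of variance homogeneity (median-centred by default).

    Median centring is the Brown–Forsythe variant, robust to skew; the
    statistic is the one-way ANOVA F on absolute deviations from each
    group's centre.  Two identical groups give statistic 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 observations")
    stat, p = sps.levene(x, y, center=center)
    if np.isnan(stat):  # zero spread in every group
        return 0.0, 1.0
    return float(stat), float(p)


def group_stats(
    matrix: SummaryMatrix, grain: str = "boolean", correction: bool = False
) -> dict:
    """The standard group-level comparison battery on a summary matrix.

    Returns typicality counts + chi-square, and rank-sum + Levene tests on
    per-player mean atypicality, as a JSON-serialisable dict.
    """
    table = typicality_counts(matrix, grain=grain)
    chi2, chi2_p = chisq_2x2(table, correction=correction)
    mean_atyp = matrix.mean_atypicality_series()
    groups = matrix.groups
    patients = mean_atyp[groups == "patient"].dropna().to_numpy()
    controls = mean_atyp[groups == "control"].dropna().to_numpy()
    w, w_p = rank_sum_test(patients, controls)
    lv, lv_p = levene_test(patients, controls)
    frac = lambda a, n: float(a) / n if n else float("nan")
    n_pat = int((groups == "patient").sum())
    n_con = int((groups == "control").sum())
    any_flag = (matrix.cells > 0).any(axis=1)
    return {
        "counts": {
            "patients_atypical": table.patients_atypical,
            "patients_typical": table.patients_typical,
            "controls_atypical": table.controls_atypical,
            "controls_typical": table.controls_typical,
            "grain": grain,
        },
        "chi2": {"statistic": chi2, "p": chi2_p, "correction": correction},
        "rank_sum_mean_atypicality": {"statistic": w, "p": w_p,
                                      "n_patients": len(patients), "n_controls": len(controls)},
        "levene_mean_atypicality": {"statistic": lv, "p": lv_p, "center": "median"},
        "players_atypical_ge1_metric": {
            "patients": int(any_flag[groups == "patient"].sum()),
            "patients_pct": 100.0 * frac(any_flag[groups == "patient"].sum(), n_pat),
            "controls": int(any_flag[groups == "control"].sum()),
            "controls_pct": 100.0 * frac(any_flag[groups == "control"].sum(), n_con),
        },
    }
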