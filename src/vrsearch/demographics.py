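"""Patient demographics: fixture loading and descriptive statistics.

The bundled fixture encodes the published demographic table of the 13-
patient inpatient cohort (age, sex, chronicity, diagnosis, lesion side,
normalised FIM scores, and pen-and-paper neglect flags).  Pen-and-paper
results (clock drawing, single-letter cancellation, line cancellation) are
recorded as given 0/1 flags, not re-scored.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .tukey import DEFAULT_QUARTILE_METHOD, quartiles

DEMOGRAPHICS_COLUMNS = [
    "player_id", "age", "sex", "days_since_injury", "days_in_rehab",
    "diagnosis", "hemisphere", "fim_motor", "fim_cognition", "fim_total",
    "neglect_present", "neglected_hemispace", "clox", "slct", "alberts",
]


def load_patient_demographics() -> pd.DataFrame:
    """The bundled 13-patient demographics fixture."""
    with resources.files("vrsearch.data").joinpath("patient_demographics.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"player_id": str})
    missing = set(DEMOGRAPHICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"demographics fixture missing columns: {sorted(missing)}")
    return df


def _median_iqr(values, method: str) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q1, q3 = quartiles(v, method=method)
    return float(np.median(v)), float(q3 - q1)


def demographics_summary(
    df: pd.DataFrame | None = None, quartile_method: str = DEFAULT_QUARTILE_METHOD
) -> dict:
    """Descriptive statistics of a patient demographics table.

    Medians/IQRs use linear-interpolation quartiles by default; days since
    injury and days in rehabilitation are summarised as means (with SD and
    range), matching clinical reporting practice for chronicity.
    """
    if df is None:
        df = load_patient_demographics()
    age_med, age_iqr = _median_iqr(df["age"], quartile_method)
    fim_m_med, fim_m_iqr = _median_iqr(df["fim_motor"], quartile_method)
    fim_c_med, fim_c_iqr = _median_iqr(df["fim_cognition"], quartile_method)
    n = len(df)
    neglect_n = int(df["neglect_present"].sum())
    return {
        "n_patients": n,
        "age_median": age_med,
        "age_iqr": age_iqr,
        "n_male": int((df["sex"] == "Male").sum()),
        "days_since_injury_mean": float(df["days_since_injury"].mean()),
        "days_since_injury_sd": float(df["days_since_injury"].std(ddof=1)),
        "days_in_rehab_mean": float(df["days_in_rehab"].mean()),
        "days_in_rehab_sd": float(df["days_in_rehab"].std(ddof=1)),
        "diagnosis_counts": df["diagnosis"].value_counts().to_dict(),
        "hemisphere_counts": df["hemisphere"].value_counts().to_dict(),
        "fim_motor_median": fim_m_med,
        "fim_motor_iqr": fim_m_iqr,
        "fim_cognition_median": fim_c_med,
        "fim_cognition_iqr": fim_c_iqr,
        "neglect_n": neglect_n,
        "neglect_prevalence_pct": 100.0 * neglect_n / n if n else float("nan"),
    }
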