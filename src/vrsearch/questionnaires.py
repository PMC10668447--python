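"""Feasibility and demographic instrument scoring.

Covers the single-category simulator-sickness rating (SSQ) and its
eligibility rule, the revised Game Experience Questionnaire (GEQ-R, four
factor means over 25 five-point items), the System Usability Scale (SUS,
0–100 with acceptability bands), Functional Independence Measure (FIM)
normalisation to the 1–7 item scale, and the combined eligibility screen.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

#: SSQ categories: 1 = no symptoms, 2 = stomach awareness, 3 = mild nausea,
#: 4 = moderate nausea, 5 = severe nausea, 6 = retching, 7 = vomiting.
SSQ_CATEGORIES = {
    1: "no symptoms", 2: "stomach awareness", 3: "mild nausea",
    4: "moderate nausea", 5: "severe nausea", 6: "retching", 7: "vomiting",
}

GEQ_FACTORS = ("positive_affect", "competence", "negativity", "flow")

#: FIM item counts per subscale.
FIM_ITEMS = {"motor": 13, "cognition": 5, "total": 18}


def ssq_eligibility(category: int) -> bool:
    """Eligible iff the sickness rating is below moderate nausea (< 4)."""
    if category not in SSQ_CATEGORIES:
        raise ValueError(f"SSQ category must be 1–7, got {category}")
    return category < 4


def load_geq_mapping() -> dict[str, list[int]]:
    """Default GEQ-R item→factor mapping (editable package-data JSON).

    The shipped mapping is a synthetic placeholder covering all 25 items;
    studies using the published instrument should supply their own file.
    """
    with resources.files("vrsearch.data").joinpath("geq_factors.json").open() as fh:
        mapping = json.load(fh)
    return {k: list(v) for k, v in mapping.items()}


def geq_factors(items: dict[int, float], mapping: dict[str, list[int]] | None = None) -> dict[str, float]:
    """Four GEQ-R factor means from 25 item scores (each 1–5).

    A factor with any missing item is missing (NaN).
    """
    if mapping is None:
        mapping = load_geq_mapping()
    mapped = sorted(i for items_ in mapping.values() for i in items_)
    if mapped != list(range(1, 26)):
        raise ValueError("mapping must cover items 1–25 exactly once each")
    for i, v in items.items():
        if not (1 <= v <= 5):
            raise ValueError(f"item {i} score {v} outside [1, 5]")
    out = {}
    for factor, idxs in mapping.items():
        vals = [items[i] for i in idxs if i in items]
        out[factor] = float(np.mean(vals)) if len(vals) == len(idxs) else float("nan")
    return out


def sus_score(items: list[float]) -> tuple[float, str]:
    """Standard SUS score (0–100) and acceptability category.

    Odd items contribute (score − 1), even items (5 − score); the sum is
    scaled by 2.5.  Categories: acceptable [70, 100], marginal [50, 70),
    unacceptable [0, 50) — band boundaries are lower-inclusive.
    """
    if len(items) != 10:
        raise ValueError("SUS requires exactly 10 item scores")
    if any(not (1 <= v <= 5) for v in items):
        raise ValueError("SUS item scores must lie in [1, 5]")
    contributions = [
        (v - 1) if (i % 2 == 0) else (5 - v) for i, v in enumerate(items)
    ]
    score = float(sum(contributions) * 2.5)
    if score >= 70:
        category = "acceptable"
    elif score >= 50:
        category = "marginal"
    else:
        category = "unacceptable"
    return score, category


def fim_normalise(raw_motor: float, raw_cognition: float) -> tuple[float, float, float]:
    """FIM subscale sums → per-item means on the original 1–7 scale.

    motor = raw/13, cognition = raw/5, total = (raw_motor + raw_cognition)/18.
    """
    for name, raw in (("motor", raw_motor), ("cognition", raw_cognition)):
        k = FIM_ITEMS[name]
        if not (k <= raw <= 7 * k):
            raise ValueError(f"raw FIM {name} sum {raw} outside [{k}, {7 * k}]")
    motor = raw_motor / FIM_ITEMS["motor"]
    cognition = raw_cognition / FIM_ITEMS["cognition"]
    total = (raw_motor + raw_cognition) / FIM_ITEMS["total"]
    return float(motor), float(cognition), float(total)


def fim_total_from_subscales(motor: float, cognition: float) -> float:
    """Recombine normalised subscales: total = (13·motor + 5·cognition)/18."""
    return (FIM_ITEMS["motor"] * motor + FIM_ITEMS["cognition"] * cognition) / FIM_ITEMS["total"]


def eligibility_screen(ssq_category: int, mmse_orientation: int) -> bool:
    """Study eligibility: sickness rating < moderate nausea and MMSE
    orientation-to-time-and-space score ≥ 6 of 10."""
    if not (0 <= mmse_orientation <= 10):
        raise ValueError("MMSE orientation score must lie in [0, 10]")
    return ssq_eligibility(ssq_category) and mmse_orientation >= 6
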