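"""Quartiles and Tukey fences — the primitive behind RT trimming and the
normative atypicality rule.

Quartiles default to linear interpolation between order statistics
(``numpy``'s ``linear`` method, R type 7), the convention under which the
package's demographic descriptives match their published counterparts.  The
method is a parameter everywhere so alternative conventions can be swept.

Fences are ``[Q1 − k·IQR, Q3 + k·IQR]`` with k = 1.5; outliers are values
*strictly* outside the fences, so zero-IQR data flags nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_QUARTILE_METHOD = "linear"


@dataclass(frozen=True)
class Fences:
    """Quartiles and Tukey fences of one sample."""

    q1: float
    q3: float
    lower: float
    upper: float
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def quartiles(values, method: str = DEFAULT_QUARTILE_METHOD) -> tuple[float, float]:
    """(Q1, Q3) of the non-NaN values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("quartiles of an empty sample are undefined")
    q1, q3 = np.quantile(v, [0.25, 0.75], method=method)
    return float(q1), float(q3)


def tukey_fences(values, k: float = 1.5, method: str = DEFAULT_QUARTILE_METHOD) -> Fences:
    """Quartiles and k·IQR fences of a sample (NaNs dropped)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q1, q3 = quartiles(v, method=method)
    iqr = q3 - q1
    return Fences(q1=q1, q3=q3, lower=q1 - k * iqr, upper=q3 + k * iqr, n=int(v.size))


def outlier_mask(values, fences: Fences) -> np.ndarray:
    """Boolean mask of values strictly outside the fences (NaN → False)."""
    v = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        return (v < fences.lower) | (v > fences.upper)
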