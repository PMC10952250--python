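"""Test-retest agreement statistics: Bland-Altman, RC, and ICC(A,1).

These quantify how well a biomarker (here, the median lung PSE) agrees
between repeated measurements — repeat scans, or repeat applications of the
stochastic ICA pipeline to the same scan.

* Bland-Altman: bias = mean paired difference; limits of agreement
  bias +/- 1.96 * SD(d) with the sample SD (n-1).  The bias is flagged
  significant when 0 lies outside bias +/- 1.96 * SD(d)/sqrt(n).
* Repeatability coefficient: RC = 1.96 * SD(d), the smallest change
  detectable beyond measurement error (equivalently 1.96 * sqrt(2) * S_w).
* ICC(A,1): two-way single-measure intraclass correlation with absolute
  agreement (McGraw-Wong), from the two-way ANOVA mean squares with rows =
  subjects and columns = sessions.  Qualitative bands: < 0.5 poor,
  [0.5, 0.75) moderate, [0.75, 0.9) good, >= 0.9 excellent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import ValidationError

__all__ = [
    "AgreementReport",
    "bland_altman",
    "repeatability_coefficient",
    "icc_absolute_single",
    "icc_band",
    "agreement_report",
]


@dataclass
class AgreementReport:
    """Bundle of agreement statistics for one paired comparison."""

    bias: float
    loa_low: float
    loa_high: float
    repeatability_coefficient: float
    icc: float | None  # None when undefined (zero total variance)
    icc_band: str | None
    bias_significant: bool
    n: int

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "repeatability_coefficient": self.repeatability_coefficient,
            "icc": self.icc,
            "icc_band": self.icc_band,
            "bias_significant": self.bias_significant,
            "n": self.n,
        }


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise ValidationError("paired measurements must be equal-length 1-D arrays")
    if a.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("missing pairs are not allowed")
    return a, b


def bland_altman(value_a, value_b) -> dict:
    """Bias and 1.96-SD limits of agreement of differences ``b - a``."""
    a, b = _paired(value_a, value_b)
    d = b - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    sem = sd / math.sqrt(d.size)
    significant = abs(bias) > 1.96 * sem if sd > 0 else bias != 0.0
    return {
        "bias": bias,
        "loa_low": bias - half,
        "loa_high": bias + half,
        "sd_diff": sd,
        "bias_significant": bool(significant),
        "n": int(d.size),
    }


def repeatability_coefficient(value_a, value_b) -> float:
    """RC = 1.96 * SD of the paired differences (sample SD, n-1)."""
    a, b = _paired(value_a, value_b)
    return float(1.96 * (b - a).std(ddof=1))


def icc_absolute_single(matrix) -> float | None:
    """ICC(A,1) from a complete subjects x sessions matrix.

    ``ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))`` with
    MS_R/MS_C/MS_E the row (subject), column (session), and residual mean
    squares of the two-way ANOVA.  Returns ``None`` when the total variance
    is zero, where the ICC is undefined.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ICC expects a 2-D subjects x sessions matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValidationError("ICC needs >= 3 subjects and >= 2 sessions")
    if np.isnan(x).any():
        raise ValidationError("ICC requires a complete matrix")
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0.0:
        return None
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0.0:
        return None
    return float((ms_r - ms_e) / denom)


def icc_band(icc: float | None) -> str | None:
    """Qualitative repeatability label for an ICC value."""
    if icc is None:
        return None
    if icc >= 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def agreement_report(value_a, value_b) -> AgreementReport:
    """All agreement statistics for one pair of measurement sessions."""
    ba = bland_altman(value_a, value_b)
    rc = repeatability_coefficient(value_a, value_b)
    a, b = _paired(value_a, value_b)
    icc = icc_absolute_single(np.column_stack([a, b]))
    return AgreementReport(
        bias=ba["bias"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        repeatability_coefficient=rc,
        icc=icc,
        icc_band=icc_band(icc),
        bias_significant=ba["bias_significant"],
        n=ba["n"],
    )
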