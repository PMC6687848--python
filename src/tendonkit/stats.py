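"""Normality-gated correlation statistics for tendon cohort tables.

Association between mechanical and structural outcomes is tested with the
Pearson product-moment coefficient when both variables pass the Shapiro-Wilk
normality test (alpha 0.05), and with Spearman's rho (Pearson on midranks)
otherwise. Two-sided p-values use the t-transform ``t = r sqrt((n-2)/(1-r^2))``
with n-2 degrees of freedom (n-3 for a single-control partial correlation).
Group contrasts use Welch's unequal-variance t-test. Biological maturity is
summarized as the predicted offset from peak height velocity (PHV), a linear
function of age x sitting height whose coefficients must be supplied
explicitly (a published recalibrated boys' equation ships as a
citation-tagged constant).

No multiple-testing correction is applied; report builders annotate the
number of tests run instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "normality_gate",
    "pearson",
    "spearman",
    "correlate",
    "partial_correlation",
    "welch_t",
    "MaturityCoefficients",
    "MOORE_2015_BOYS",
    "maturity_offset",
    "classify_symptoms",
]


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    estimate: float
    p_value: float
    n: int
    normality_p_x: float = float("nan")
    normality_p_y: float = float("nan")

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.estimate <= 1.0 + 1e-12:
            raise ValueError("correlation estimate must lie in [-1, 1]")


def _check_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < min_n:
        raise ValueError(f"need n >= {min_n}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant variable: correlation undefined")
    return x, y


def _r_to_p(r: float, df: int) -> float:
    """Two-sided p for a correlation via the t-transform with ``df`` d.f."""
    if df < 1:
        raise ValueError("need at least 1 degree of freedom")
    r2 = min(r * r, 1.0)
    if r2 >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt(df / (1.0 - r2))
    return float(2.0 * sps.t.sf(t, df))


def normality_gate(x, y, alpha: float = 0.05) -> tuple[str, float, float]:
    """Choose Pearson iff *both* variables pass Shapiro-Wilk at ``alpha``.

    Returns ``(method, shapiro_p_x, shapiro_p_y)``.
    """
    x, y = _check_pair(x, y)
    px = float(sps.shapiro(x).pvalue)
    py = float(sps.shapiro(y).pvalue)
    method = "pearson" if (px > alpha and py > alpha) else "spearman"
    return method, px, py


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-transform p (n-2 d.f.)."""
    x, y = _check_pair(x, y)
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = float(np.clip(r, -1.0, 1.0))
    return CorrelationResult("pearson", r, _r_to_p(r, n - 2), n)


def spearman(x, y) -> CorrelationResult:
    """Spearman's rho: Pearson on midranks (average-rank ties), t-transform p."""
    x, y = _check_pair(x, y)
    rx = sps.rankdata(x)  # average ranks for ties
    ry = sps.rankdata(y)
    base = pearson(rx, ry)
    return CorrelationResult("spearman", base.estimate, base.p_value, base.n)


def correlate(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Normality-gated correlation: Pearson if both pass Shapiro-Wilk, else Spearman."""
    method, px, py = normality_gate(x, y, alpha)
    res = pearson(x, y) if method == "pearson" else spearman(x, y)
    return CorrelationResult(res.method, res.estimate, res.p_value, res.n, px, py)


def partial_correlation(x, y, control) -> CorrelationResult:
    """Pearson correlation of the OLS residuals of x and y on the control.

    The p-value uses n-3 degrees of freedom. A control collinear with x or y
    raises ``ValueError``.
    """
    x, y = _check_pair(x, y, min_n=4)
    z = np.asarray(control, dtype=float)
    if z.size != x.size:
        raise ValueError("control must match x and y in length")

    def residuals(v):
        a = np.column_stack([z, np.ones_like(z)])
        coef, *_ = np.linalg.lstsq(a, v, rcond=None)
        return v - a @ coef

    rx, ry = residuals(x), residuals(y)
    if np.var(rx) <= 1e-15 * max(1.0, np.var(x)) or np.var(ry) <= 1e-15 * max(1.0, np.var(y)):
        raise ValueError("control is collinear with x or y")
    n = x.size
    base = pearson(rx, ry)
    return CorrelationResult("partial_pearson", base.estimate,
                             _r_to_p(base.estimate, n - 3), n)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: ``(t, df, two-sided p)``.

    Degrees of freedom follow the Welch-Satterthwaite approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both groups constant with different means")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), float(df), p


@dataclass(frozen=True)
class MaturityCoefficients:
    """Coefficients of the linear-in-product maturity prediction equation."""

    b0: float
    b1: float
    citation: str = ""


#: Recalibrated boys' maturity-offset equation (Moore et al., 2015):
#: offset (years from PHV) = -7.999994 + 0.0036124 * (age [y] x sitting height [cm]).
MOORE_2015_BOYS = MaturityCoefficients(
    b0=-7.999994, b1=0.0036124,
    citation="Moore et al. (2015) Med Sci Sports Exerc 47(8):1755-1764",
)


def maturity_offset(age_y, sitting_height_cm, coefficients: MaturityCoefficients):
    """Predicted years from peak height velocity: ``b0 + b1 * (age x sitting height)``.

    Coefficients must be passed explicitly (e.g. :data:`MOORE_2015_BOYS`);
    there is no silent default.
    """
    if coefficients is None:
        raise ValueError("maturity coefficients must be supplied explicitly")
    age = np.asarray(age_y, dtype=float)
    sh = np.asarray(sitting_height_cm, dtype=float)
    out = coefficients.b0 + coefficients.b1 * (age * sh)
    return float(out) if out.ndim == 0 else out


def classify_symptoms(
    visap_baseline: float,
    visap_followup: float,
    recovery_threshold: float = 85.0,
) -> str:
    """Symptom grouping from baseline and 2-month follow-up VISA-P scores.

    A participant is ``"asymptomatic"`` iff the follow-up score reaches the
    recovery threshold (default 85): this covers pain-free athletes and those
    recovering from tendinopathy, while persisting pain (follow-up below
    threshold) and tendinopathy developing within the follow-up window are
    ``"symptomatic"``. The threshold is configurable.
    """
    for s in (visap_baseline, visap_followup):
        if not 0.0 <= s <= 100.0:
            raise ValueError("VISA-P scores must lie in [0, 100]")
    return "asymptomatic" if visap_followup >= recovery_threshold else "symptomatic"
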