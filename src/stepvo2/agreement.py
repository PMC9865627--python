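"""Method-comparison statistics for paired measured/estimated VO2max.

Two sign conventions coexist in this literature and both are kept, exactly:

* cross-validation error statistics use ``measured - estimated``:
  CE = mean(Y - Ŷ), with Y the measured value;
* Bland–Altman differences use ``estimated - measured``, so the fixed bias
  is exactly ``-CE``.

TE is the root mean squared difference (an RMSE): the square root keeps it
in mL·kg⁻¹·min⁻¹, directly comparable with the SEE, and satisfies the
decomposition TE² = CE² + (n-1)/n · SD(diff)².  SEE = SD_Y·sqrt(1-r²) uses
the sample (n-1) SD of the measured values.  Proportional bias is the
Pearson correlation of the Bland–Altman difference against the pair mean
(measured + estimated)/2, the standard abscissa; its p-value is the
correlation t-test, identical to the regression slope's t-test for a simple
regression.  Limits of agreement use the conventional 1.96 multiplier, not
a t-quantile.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import PairedCohort, ValidationError

__all__ = [
    "AgreementReport",
    "BlandAltmanResult",
    "constant_error",
    "standard_error_of_estimate",
    "total_error",
    "bland_altman",
    "agreement_report",
    "compare_methods",
    "format_report_table",
]

logger = logging.getLogger(__name__)

#: Conventional 95% limits-of-agreement multiplier.
LOA_Z = 1.96


def _require_n(pairs: PairedCohort, minimum: int, what: str) -> None:
    if pairs.n < minimum:
        raise ValidationError(f"{what} requires n >= {minimum}, got n={pairs.n}")


def constant_error(pairs: PairedCohort) -> tuple[float, float, float]:
    """CE = mean(measured - estimated), its sample SD, and a two-tailed
    one-sample t-test p-value against zero.

    With zero difference variance the t statistic is undefined; the p-value
    is returned as NaN.
    """
    _require_n(pairs, 3, "constant_error")
    d = pairs.measured - pairs.estimated
    ce = float(np.mean(d))
    ce_sd = float(np.std(d, ddof=1))
    if ce_sd == 0.0:
        return ce, ce_sd, float("nan")
    p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return ce, ce_sd, p


def standard_error_of_estimate(pairs: PairedCohort) -> float:
    """SEE = SD(measured) * sqrt(1 - r²), r the Pearson correlation of
    measured with estimated.  Sample (n-1) SD throughout."""
    _require_n(pairs, 3, "standard_error_of_estimate")
    if np.std(pairs.measured, ddof=1) == 0 or np.std(pairs.estimated, ddof=1) == 0:
        raise ValidationError(
            "standard_error_of_estimate requires nonzero variance in both vectors"
        )
    r = float(stats.pearsonr(pairs.measured, pairs.estimated).statistic)
    sd_y = float(np.std(pairs.measured, ddof=1))
    return sd_y * math.sqrt(max(0.0, 1.0 - r * r))


def total_error(pairs: PairedCohort) -> float:
    """TE = sqrt(mean((measured - estimated)²)), an RMSE."""
    if pairs.n < 1:
        raise ValidationError("total_error requires n >= 1")
    d = pairs.measured - pairs.estimated
    return float(np.sqrt(np.mean(d * d)))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman summary; differences are estimated - measured."""

    fixed_bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    fixed_p: float
    prop_bias_r: Optional[float]
    prop_bias_p: Optional[float]
    prop_bias_reason: Optional[str] = None


def bland_altman(pairs: PairedCohort) -> BlandAltmanResult:
    """Fixed and proportional bias with 95% limits of agreement.

    Fixed bias is the mean of (estimated - measured) with LoA at
    ±1.96 sample SDs.  Proportional bias is the Pearson correlation of the
    differences against the pair means; degenerate variance on either axis
    leaves it undefined with a reason rather than NaN.
    """
    _require_n(pairs, 3, "bland_altman")
    d = pairs.estimated - pairs.measured
    mean_axis = (pairs.measured + pairs.estimated) / 2.0
    fixed_bias = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    loa_low = fixed_bias - LOA_Z * sd_diff
    loa_high = fixed_bias + LOA_Z * sd_diff
    fixed_p = (
        float("nan") if sd_diff == 0.0 else float(stats.ttest_1samp(d, 0.0).pvalue)
    )
    if sd_diff == 0.0 or float(np.std(mean_axis, ddof=1)) == 0.0:
        return BlandAltmanResult(
            fixed_bias=fixed_bias,
            sd_diff=sd_diff,
            loa_low=loa_low,
            loa_high=loa_high,
            fixed_p=fixed_p,
            prop_bias_r=None,
            prop_bias_p=None,
            prop_bias_reason="zero variance in differences or pair means",
        )
    res = stats.pearsonr(d, mean_axis)
    return BlandAltmanResult(
        fixed_bias=fixed_bias,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        fixed_p=fixed_p,
        prop_bias_r=float(res.statistic),
        prop_bias_p=float(res.pvalue),
    )


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary for one estimator against the measured values."""

    n: int
    measured_mean: float
    measured_sd: float
    estimated_mean: float
    estimated_sd: float
    ce: float
    ce_sd: float
    ce_p: float
    see: float
    te: float
    pearson_r: float
    fixed_bias: float
    loa_low: float
    loa_high: float
    fixed_p: float
    prop_bias_r: Optional[float]
    prop_bias_p: Optional[float]
    prop_bias_reason: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def agreement_report(pairs: PairedCohort) -> AgreementReport:
    """Compute every agreement statistic on one paired cohort."""
    ce, ce_sd, ce_p = constant_error(pairs)
    see = standard_error_of_estimate(pairs)
    te = total_error(pairs)
    r = float(stats.pearsonr(pairs.measured, pairs.estimated).statistic)
    ba = bland_altman(pairs)
    return AgreementReport(
        n=pairs.n,
        measured_mean=float(np.mean(pairs.measured)),
        measured_sd=float(np.std(pairs.measured, ddof=1)),
        estimated_mean=float(np.mean(pairs.estimated)),
        estimated_sd=float(np.std(pairs.estimated, ddof=1)),
        ce=ce,
        ce_sd=ce_sd,
        ce_p=ce_p,
        see=see,
        te=te,
        pearson_r=r,
        fixed_bias=ba.fixed_bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        fixed_p=ba.fixed_p,
        prop_bias_r=ba.prop_bias_r,
        prop_bias_p=ba.prop_bias_p,
        prop_bias_reason=ba.prop_bias_reason,
    )


def compare_methods(
    frame: pd.DataFrame,
    measured: str = "vo2max_measured",
    methods: Sequence[str] = ("mrm", "lem", "combined"),
    id_col: str = "id",
) -> dict[str, AgreementReport]:
    """One report per estimate column, complete cases per method.

    Rows with a missing measured value are dropped globally; rows with a
    missing estimate are dropped for that method only (pairwise deletion,
    never imputation), with dropped counts logged.  A fully missing method
    column is omitted with a warning.
    """
    if measured not in frame.columns:
        raise ValidationError(f"measured column {measured!r} not in frame")
    base = frame[frame[measured].notna()]
    n_dropped_measured = len(frame) - len(base)
    if n_dropped_measured:
        logger.info("dropped %d rows with missing measured values", n_dropped_measured)
    reports: dict[str, AgreementReport] = {}
    for method in methods:
        if method not in frame.columns:
            logger.warning("method column %r absent; skipped", method)
            continue
        sub = base[base[method].notna()]
        n_dropped = len(base) - len(sub)
        if n_dropped:
            logger.info("method %s: dropped %d rows with missing estimates",
                        method, n_dropped)
        if sub.empty:
            logger.warning("method column %r has no complete pairs; omitted", method)
            continue
        ids = sub[id_col] if id_col in sub.columns else sub.index.astype(str)
        pairs = PairedCohort(ids, sub[measured], sub[method])
        reports[method] = agreement_report(pairs)
    return reports


def format_report_table(reports: dict[str, AgreementReport]) -> str:
    """Fixed-width text rendering with the conventional column order:
    method, measured mean±SD, estimated mean±SD, CE±SD (p), SEE, TE.
    Values rounded to 2 decimals; JSON serialization keeps full precision."""
    header = (
        f"{'Method':<10}{'Measured':>14}{'Estimated':>14}"
        f"{'CE (p)':>20}{'SEE':>8}{'TE':>8}"
    )
    lines = [header, "-" * len(header)]
    for name, rep in reports.items():
        measured = f"{rep.measured_mean:.2f}±{rep.measured_sd:.2f}"
        estimated = f"{rep.estimated_mean:.2f}±{rep.estimated_sd:.2f}"
        ce = f"{rep.ce:.2f}±{rep.ce_sd:.2f} ({rep.ce_p:.2f})"
        lines.append(
            f"{name:<10}{measured:>14}{estimated:>14}{ce:>20}"
            f"{rep.see:>8.2f}{rep.te:>8.2f}"
        )
    return "\n".join(lines)
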