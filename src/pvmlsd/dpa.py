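"""Disproportionality statistics: reporting odds ratio and information component.

The reporting odds ratio (ROR) on a drug-by-event 2×2 report-count table is
``(a·d)/(b·c)`` — the odds of the specific event among study-drug reports
divided by the same odds among comparator reports.  A Haldane–Anscombe 0.5
correction is added to all four cells when any cell is zero.  The Wald 95%
interval is ``exp(ln OR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``.  Signal
criterion: lower bound ≥ 1 (inclusive).

The adjusted ROR comes from a report-level case/non-case logistic
regression over study-drug and comparator reports: the outcome is "report
contains the event", the exposure indicator is the study drug, and the
reporting covariates enter as one-hot dummies.  ``exp`` of the exposure
coefficient is the adjusted ROR.

The information component (IC) is the shrinkage observed-to-expected
measure of the Bayesian confidence propagation neural network family:
with expected count ``E = (a+b)(a+c)/N``,

    IC    = log2((a + 0.5) / (E + 0.5))
    IC025 = log2 of the 2.5% quantile of Gamma(shape=a+0.5, rate=E+0.5)

Signal criterion: IC025 > 0 (strict).  A closed-form normal-style
approximation ``IC − 3.3(a+0.5)^(−1/2) − 2.0(a+0.5)^(−3/2)`` is provided
as an independent cross-check for moderate-to-large ``a``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InestimableError, SeparationError
from .features import ContingencyTable, _is_comparator_only, _is_study
from .srs_data import (
    AGE_VALUES,
    INSTITUTION_VALUES,
    OCCUPATION_VALUES,
    REPORT_TYPE_VALUES,
    SEX_VALUES,
    Report,
    ReportSet,
    TermDictionary,
)

Z95 = 1.96

COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": SEX_VALUES,
    "age_group": AGE_VALUES,
    "serious": ("no", "yes"),
    "report_type": REPORT_TYPE_VALUES,
    "reporter_occupation": OCCUPATION_VALUES,
    "institution": INSTITUTION_VALUES,
}


@dataclass(frozen=True)
class RORResult:
    estimate: float
    ci_low: float
    ci_high: float
    adjusted: bool = False
    covariates_used: tuple[str, ...] = ()
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.estimate <= self.ci_high):
            raise DegenerateDataError(
                f"invalid interval ordering: {self.ci_low}, {self.estimate}, {self.ci_high}"
            )


@dataclass(frozen=True)
class ICResult:
    observed: int
    expected: float
    ic: float
    ic025: float
    ic975: float

    def __post_init__(self) -> None:
        if not (self.ic025 <= self.ic <= self.ic975):
            raise DegenerateDataError("IC credible bounds must bracket the point estimate")


def crude_ror(table: ContingencyTable) -> RORResult:
    """Crude reporting odds ratio with Wald 95% CI.

    Zero cells trigger the 0.5 continuity correction on all four cells
    (flagged via ``corrected``).
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    estimate = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(estimate)
    return RORResult(
        estimate=estimate,
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        adjusted=False,
        corrected=corrected,
    )


def _report_soc_indicators(report: Report, term_dict: TermDictionary) -> set[str]:
    return {term_dict.soc(t) for t in report.ae_terms if t in term_dict}


def adjusted_ror(
    reports: ReportSet | Iterable[Report],
    drug: str,
    ae: str,
    comparators: Iterable[str],
    covariates: Sequence[str] = (),
    term_dict: TermDictionary | None = None,
) -> RORResult:
    """Covariate-adjusted ROR from report-level case/non-case logistic regression.

    ``covariates`` selects covariate families (keys of
    :data:`COVARIATE_LEVELS`); each family is one-hot encoded against its
    first level as reference.  Passing ``"soc"`` (requires ``term_dict``)
    adds per-report SOC-presence indicators.  With no covariates the MLE
    reproduces the sample odds ratio of the 2×2 table.
    """
    import statsmodels.api as sm

    comparators = frozenset(comparators)
    rows, y, exposure = [], [], []
    soc_codes = term_dict.soc_codes if term_dict is not None else ()
    for r in reports:
        if _is_study(r, drug):
            exp_flag = 1
        elif _is_comparator_only(r, drug, comparators):
            exp_flag = 0
        else:
            continue
        exposure.append(exp_flag)
        y.append(1 if ae in r.ae_terms else 0)
        rec = {}
        for family in covariates:
            if family == "soc":
                present = _report_soc_indicators(r, term_dict)
                for code in soc_codes:
                    rec[f"soc_{code}"] = 1.0 if code in present else 0.0
                continue
            levels = COVARIATE_LEVELS[family]
            value = ("yes" if r.serious else "no") if family == "serious" else getattr(r, family)
            for level in levels[1:]:  # first level is the reference
                rec[f"{family}_{level}"] = 1.0 if value == level else 0.0
        rows.append(rec)
    if not exposure:
        raise InestimableError("no report names the study drug or a comparator")
    y_arr = np.asarray(y, dtype=float)
    x_arr = np.asarray(exposure, dtype=float)
    if x_arr.min() == x_arr.max():
        raise InestimableError("one exposure arm is empty")
    if y_arr.min() == y_arr.max():
        raise InestimableError("outcome is constant; odds ratio inestimable")
    X = pd.DataFrame(rows)
    # levels never observed produce all-zero dummies; drop them to keep the
    # information matrix nonsingular
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=constant)
    X.insert(0, "exposure", x_arr)
    X.insert(0, "const", 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y_arr, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises PerfectSeparationError and friends
            raise SeparationError(
                f"logistic fit failed ({exc}); consider falling back to crude_ror"
            ) from exc
    if not fit.mle_retvals.get("converged", True) or not np.isfinite(
        fit.bse["exposure"]
    ):
        raise SeparationError(
            "logistic fit did not converge (possible complete separation); "
            "consider falling back to crude_ror"
        )
    beta = fit.params["exposure"]
    se = fit.bse["exposure"]
    return RORResult(
        estimate=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
        adjusted=True,
        covariates_used=tuple(covariates),
    )


def information_component(table: ContingencyTable) -> ICResult:
    """Shrinkage IC with exact gamma-posterior 95% credible bounds."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if a + b == 0 or a + c == 0:
        raise DegenerateDataError("IC requires a+b > 0 and a+c > 0")
    expected = (a + b) * (a + c) / n
    shape = a + 0.5
    rate = expected + 0.5
    ic = math.log2(shape / rate)
    q_low, q_high = stats.gamma.ppf([0.025, 0.975], shape, scale=1.0 / rate)
    return ICResult(
        observed=a,
        expected=expected,
        ic=ic,
        ic025=math.log2(q_low),
        ic975=math.log2(q_high),
    )


def ic025_approx(table: ContingencyTable) -> float:
    """Closed-form approximation to IC025; accurate for observed counts ≥ 5."""
    res = information_component(table)
    s = table.a + 0.5
    return res.ic - 3.3 * s ** (-0.5) - 2.0 * s ** (-1.5)


def dpa_signal(result: RORResult | ICResult) -> bool:
    """Apply the signal criterion: ROR lower bound ≥ 1 (inclusive),
    IC025 > 0 (strict)."""
    if isinstance(result, RORResult):
        return result.ci_low >= 1.0
    if isinstance(result, ICResult):
        return result.ic025 > 0.0
    raise TypeError(f"unsupported result type {type(result).__name__}")
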