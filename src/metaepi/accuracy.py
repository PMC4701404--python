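"""Per-study diagnostic accuracy statistics.

The diagnostic odds ratio DOR = (TP*TN)/(FP*FN) summarises discriminative
performance in a single number.  On the log scale it is the D statistic of
the Moses-Littenberg SROC model,

    D = logit(TPR) - logit(FPR) = ln DOR,
    S = logit(TPR) + logit(FPR),

where S proxies the positivity threshold: regressing D on S (plus design
covariates) adjusts accuracy comparisons for threshold variation across
studies.  The variance of ln DOR is Woolf's 1/a + 1/b + 1/c + 1/d on the
(continuity-corrected) counts, which supplies the first-stage regression
weights.  Likelihood ratios and Fagan-style post-test probabilities express
what a given sensitivity/specificity means for an individual patient.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import logit

from .core_data import TwoByTwoTable

__all__ = [
    "CorrectedTable",
    "AccuracyMeasures",
    "FaganResult",
    "correct_table",
    "accuracy_from_table",
    "dor_from_sens_spec",
    "equal_sens_spec_for_dor",
    "posttest_probability",
    "relative_dor",
]


@dataclass(frozen=True)
class CorrectedTable:
    """Real-valued 2x2 counts after continuity correction."""

    tp: float
    fp: float
    fn: float
    tn: float

    def counts(self) -> tuple[float, float, float, float]:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class AccuracyMeasures:
    """Accuracy statistics of one validation study (corrected counts)."""

    sens: float
    spec: float
    dor: float
    ln_dor: float
    var_ln_dor: float
    d: float  # ln DOR: the Moses model response
    s: float  # logit(TPR) + logit(FPR): threshold proxy


@dataclass(frozen=True)
class FaganResult:
    pretest_prob: float
    lr: float
    posttest_prob: float


def correct_table(table: TwoByTwoTable) -> CorrectedTable:
    """Haldane-Anscombe correction: add 0.5 to all four cells iff any is 0."""
    if table.total == 0:
        raise ValueError("degenerate study: all four cells are zero")
    if table.has_zero_cell:
        return CorrectedTable(*(c + 0.5 for c in table.counts()))
    return CorrectedTable(*(float(c) for c in table.counts()))


def accuracy_from_table(table: TwoByTwoTable) -> AccuracyMeasures:
    """Sens/spec, DOR, Woolf variance and the Moses D and S statistics."""
    tp, fp, fn, tn = correct_table(table).counts()
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    fpr = fp / (fp + tn)
    d = float(logit(sens) - logit(fpr))
    s = float(logit(sens) + logit(fpr))
    dor = (tp * tn) / (fp * fn)
    var = 1.0 / tp + 1.0 / fp + 1.0 / fn + 1.0 / tn
    return AccuracyMeasures(
        sens=sens,
        spec=spec,
        dor=dor,
        ln_dor=math.log(dor),
        var_ln_dor=var,
        d=d,
        s=s,
    )


def _check_open_unit(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name}={value} must lie strictly in (0, 1)")


def dor_from_sens_spec(sens: float, spec: float) -> float:
    """DOR implied by a sensitivity and specificity pair.

    DOR = [sens/(1-sens)] * [spec/(1-spec)]; e.g. 90%/90% gives 81.
    """
    _check_open_unit("sens", sens)
    _check_open_unit("spec", spec)
    return (sens / (1.0 - sens)) * (spec / (1.0 - spec))


def equal_sens_spec_for_dor(dor: float) -> float:
    """The common sensitivity = specificity value implied by a DOR.

    Solves (s/(1-s))^2 = dor: s = sqrt(dor) / (1 + sqrt(dor)).  Used to
    translate a bias-adjusted DOR back onto the sens/spec scale.
    """
    if dor <= 0:
        raise ValueError(f"dor={dor} must be positive")
    r = math.sqrt(dor)
    return r / (1.0 + r)


def posttest_probability(
    pretest: float, sens: float, spec: float, result: str = "positive"
) -> FaganResult:
    """Bayes update of a pre-test probability through a test result.

    LR+ = sens/(1-spec) for a positive result, LR- = (1-sens)/spec for a
    negative one; post-test odds = pre-test odds x LR.
    """
    _check_open_unit("pretest", pretest)
    _check_open_unit("sens", sens)
    if result == "positive":
        if spec >= 1.0:
            raise ValueError("spec = 1 gives an infinite positive LR")
        if not 0.0 < spec < 1.0:
            raise ValueError(f"spec={spec} must lie strictly in (0, 1)")
        lr = sens / (1.0 - spec)
    elif result == "negative":
        _check_open_unit("spec", spec)
        lr = (1.0 - sens) / spec
    else:
        raise ValueError(f"result must be 'positive' or 'negative', got {result!r}")
    odds = pretest / (1.0 - pretest) * lr
    return FaganResult(pretest_prob=pretest, lr=lr, posttest_prob=odds / (1.0 + odds))


def relative_dor(dor_with: float, dor_without: float) -> float:
    """Ratio of DORs with vs without a design characteristic (RDOR).

    RDOR > 1 means the characteristic inflates apparent performance.
    """
    if dor_with <= 0 or dor_without <= 0:
        raise ValueError("DORs must be positive")
    return dor_with / dor_without
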