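"""Stage 1: Moses-Littenberg meta-regression within one meta-analysis.

Fits, by weighted least squares,

    D_i = a + b*S_i + sum_k gamma_k Z_ik + e_i,

where D_i = ln DOR of study i, S_i its threshold proxy, and Z_ik the binary
design covariates.  Each gamma_k is the natural log of a relative diagnostic
odds ratio (RDOR): exp(gamma_k) is the factor by which the design flaw k
multiplies the DOR within this meta-analysis, adjusted for threshold.

Weighting modes
---------------
``fixed_effect``     weights 1/var(ln DOR_i) (Woolf variance).
``random_effects``   adds a moment estimate of the residual between-study
                     variance: tau2 = max(0, (Q_res - df) / tr(P)) from the
                     fixed-effect fit, with P = W - WX(X'WX)^-1 X'W the
                     weighted residual projector, then refits with weights
                     1/(var_i + tau2).  This is the DerSimonian-Laird moment
                     estimator generalised to a regression.
``unweighted``       ordinary least squares with the usual OLS covariance.

Standard errors in the weighted modes come from (X'WX)^-1, the
normal-equations covariance under the assumed known variances.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .accuracy import accuracy_from_table
from .core_data import MetaAnalysisSet

__all__ = [
    "WEIGHTING_MODES",
    "CoefficientEstimate",
    "MetaRegressionFit",
    "NotEstimable",
    "RdorEstimate",
    "CollinearityError",
    "DegreesOfFreedomError",
    "fit",
    "fit_arrays",
    "rdor",
]

WEIGHTING_MODES = ("unweighted", "fixed_effect", "random_effects")


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


class DegreesOfFreedomError(ValueError):
    """Too few studies for the requested model (residual df < 1)."""


@dataclass(frozen=True)
class CoefficientEstimate:
    """A per-meta-analysis log-RDOR with its standard error."""

    meta_id: str
    covariate: str
    gamma: float
    se: float
    n_studies: int
    df: int
    tau2_reg: float
    weighting: str


@dataclass(frozen=True)
class RdorEstimate:
    covariate: str
    rdor: float
    ci_low: float
    ci_high: float
    level: float


@dataclass(frozen=True)
class NotEstimable:
    """Explicit marker for a covariate with no estimable coefficient."""

    covariate: str
    reason: str


@dataclass
class MetaRegressionFit:
    """Coefficients of one within-meta-analysis Moses model fit."""

    meta_id: str
    names: list[str]  # parameter names: intercept, s, covariates...
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    n_studies: int
    df: int
    tau2_reg: float
    weighting: str
    dropped: list[str] = field(default_factory=list)

    @property
    def intercept(self) -> float:
        return float(self.beta[self.names.index("intercept")])

    @property
    def slope_s(self) -> float:
        if "s" not in self.names:
            raise KeyError("fit has no threshold term")
        return float(self.beta[self.names.index("s")])

    @property
    def covariates(self) -> list[str]:
        return [n for n in self.names if n not in ("intercept", "s")]

    def gamma(self, covariate: str) -> float:
        return float(self.beta[self.names.index(covariate)])

    def gamma_se(self, covariate: str) -> float:
        return float(self.se[self.names.index(covariate)])

    def coefficient_estimates(self) -> list[CoefficientEstimate]:
        return [
            CoefficientEstimate(
                meta_id=self.meta_id,
                covariate=c,
                gamma=self.gamma(c),
                se=self.gamma_se(c),
                n_studies=self.n_studies,
                df=self.df,
                tau2_reg=self.tau2_reg,
                weighting=self.weighting,
            )
            for c in self.covariates
        ]


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Greedy scan for columns that do not increase the rank."""
    bad: list[str] = []
    kept = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(kept):
            kept = cand
        else:
            bad.append(name)
    return bad


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    XtW = X.T * w
    A = XtW @ X
    beta = np.linalg.solve(A, XtW @ y)
    cov = np.linalg.inv(A)
    resid = y - X @ beta
    q = float(np.sum(w * resid**2))
    return beta, cov, q


def fit_arrays(
    d: np.ndarray,
    s: np.ndarray | None,
    var: np.ndarray,
    Z: np.ndarray | None = None,
    covariate_names: Sequence[str] = (),
    weighting: str = "random_effects",
    meta_id: str = "",
    include_threshold: bool = True,
) -> MetaRegressionFit:
    """Fit the Moses model on precomputed per-study statistics.

    The table-level entry point is :func:`fit`; this array form is the
    computational core and is also convenient for simulation studies.
    ``include_threshold=False`` omits the S term (intercept-only pooling,
    useful for degenerate designs with constant S).
    """
    if weighting not in WEIGHTING_MODES:
        raise ValueError(f"weighting must be one of {WEIGHTING_MODES}")
    d = np.asarray(d, dtype=float)
    var = np.asarray(var, dtype=float)
    n = d.size
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    if include_threshold:
        if s is None:
            raise ValueError("include_threshold=True requires S values")
        cols.append(np.asarray(s, dtype=float))
        names.append("s")
    if Z is not None and Z.size:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        for j, nm in enumerate(covariate_names):
            cols.append(Z[:, j])
            names.append(nm)
    X = np.column_stack(cols)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        bad = _collinear_columns(X, names)
        raise CollinearityError(
            f"{meta_id or 'meta-analysis'}: design matrix is rank deficient;"
            f" collinear column(s): {', '.join(bad)}"
        )
    df = n - p
    if df < 1:
        raise DegreesOfFreedomError(
            f"{meta_id or 'meta-analysis'}: {n} studies leave {df} residual"
            " df (need >= 1)"
        )
    if weighting == "unweighted":
        beta, a_inv, _ = _wls(X, d, np.ones(n))
        resid = d - X @ beta
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * a_inv
        tau2 = 0.0
    else:
        w = 1.0 / var
        beta, cov, q = _wls(X, d, w)
        tau2 = 0.0
        if weighting == "random_effects":
            # tr(P) for P = W - WX(X'WX)^-1 X'W
            tr_p = float(w.sum() - np.trace(cov @ ((X.T * w**2) @ X)))
            tau2 = max(0.0, (q - df) / tr_p) if tr_p > 0 else 0.0
            w = 1.0 / (var + tau2)
            beta, cov, q = _wls(X, d, w)
    return MetaRegressionFit(
        meta_id=meta_id,
        names=names,
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        cov=cov,
        n_studies=n,
        df=df,
        tau2_reg=tau2,
        weighting=weighting,
    )


def fit(
    ma_set: MetaAnalysisSet,
    matrix: pd.DataFrame | None = None,
    weighting: str = "random_effects",
    include_threshold: bool = True,
) -> MetaRegressionFit:
    """Moses-Littenberg meta-regression of one meta-analysis.

    ``matrix`` is the 0/1 design matrix from :func:`metaepi.coding.encode`
    (after :func:`~metaepi.coding.drop_invariant_covariates`); ``None`` fits
    the threshold-only model.  Studies absent from the matrix (dropped by an
    exclusion policy) are left out of the fit.
    """
    if matrix is None:
        studies = list(ma_set.studies)
        Z = None
        names: list[str] = []
    else:
        ids = set(matrix.index)
        studies = [st for st in ma_set.studies if st.study_id in ids]
        matrix = matrix.loc[[st.study_id for st in studies]]
        Z = matrix.to_numpy(dtype=float)
        names = list(matrix.columns)
    acc = [accuracy_from_table(st.table) for st in studies]
    return fit_arrays(
        d=np.array([a.d for a in acc]),
        s=np.array([a.s for a in acc]),
        var=np.array([a.var_ln_dor for a in acc]),
        Z=Z,
        covariate_names=names,
        weighting=weighting,
        meta_id=ma_set.meta_id,
        include_threshold=include_threshold,
    )


def rdor(
    fit_: MetaRegressionFit, covariate: str, level: float = 0.95
) -> RdorEstimate | NotEstimable:
    """RDOR = exp(gamma) with a z-based confidence interval.

    Returns :class:`NotEstimable` (not a number) when the covariate was
    dropped as invariant within the meta-analysis.
    """
    if covariate not in fit_.names:
        reason = (
            "dropped: constant within meta-analysis"
            if covariate in fit_.dropped
            else "covariate not in fit"
        )
        return NotEstimable(covariate=covariate, reason=reason)
    g = fit_.gamma(covariate)
    se = fit_.gamma_se(covariate)
    z = float(norm.ppf(0.5 + level / 2.0))
    return RdorEstimate(
        covariate=covariate,
        rdor=math.exp(g),
        ci_low=math.exp(g - z * se),
        ci_high=math.exp(g + z * se),
        level=level,
    )
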