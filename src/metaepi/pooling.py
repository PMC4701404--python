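"""Stage 2: DerSimonian-Laird pooling of per-meta-analysis log-RDORs.

Given coefficient estimates (gamma_j, se_j), one per meta-analysis where the
covariate was estimable, the DL random-effects procedure is the moment
method:

    w_j      = 1/se_j^2                     (fixed-effect weights)
    theta_FE = sum(w g) / sum(w)
    Q        = sum w_j (g_j - theta_FE)^2   (Cochran heterogeneity)
    tau2     = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    w*_j     = 1/(se_j^2 + tau2)
    theta    = sum(w* g) / sum(w*),  se(theta) = (sum w*)^{-1/2}
    I2       = max(0, 100 (Q - (k-1)) / Q)

The summary RDOR is exp(theta) with z-based confidence limits.  The
fixed-effect model sets tau2 = 0 and reuses w_j.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .regression import CoefficientEstimate

__all__ = [
    "PooledEffect",
    "PoolingError",
    "pool",
    "summary_rdor",
    "sensitivity",
]

POOLING_MODELS = ("random_effects_DL", "fixed_effect")


class PoolingError(ValueError):
    """Pooling not possible (no estimates, or all excluded)."""


@dataclass(frozen=True)
class PooledEffect:
    """DL- or FE-pooled log-RDOR with heterogeneity statistics."""

    covariate: str
    k: int
    theta: float  # pooled log RDOR
    se: float
    q: float
    tau2: float
    i2: float  # percent
    ci_low: float  # log scale
    ci_high: float
    model: str
    level: float = 0.95
    variant: str = "all"

    @property
    def rdor(self) -> float:
        return math.exp(self.theta)

    @property
    def rdor_ci(self) -> tuple[float, float]:
        return (math.exp(self.ci_low), math.exp(self.ci_high))


def _as_arrays(
    estimates: Sequence[CoefficientEstimate] | Sequence[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray, list[str], str]:
    gammas, ses, ids = [], [], []
    covariate = ""
    for e in estimates:
        if isinstance(e, CoefficientEstimate):
            gammas.append(e.gamma)
            ses.append(e.se)
            ids.append(e.meta_id)
            covariate = covariate or e.covariate
        else:
            g, s = e
            gammas.append(float(g))
            ses.append(float(s))
            ids.append(str(len(ids)))
    return np.array(gammas), np.array(ses), ids, covariate


def pool(
    estimates: Sequence[CoefficientEstimate] | Sequence[tuple[float, float]],
    model: str = "random_effects_DL",
    level: float = 0.95,
    covariate: str | None = None,
    variant: str = "all",
) -> PooledEffect:
    """Pool per-meta-analysis coefficients into one summary effect."""
    if model not in POOLING_MODELS:
        raise ValueError(f"model must be one of {POOLING_MODELS}")
    g, se, _, cov_name = _as_arrays(estimates)
    if covariate is not None:
        cov_name = covariate
    k = g.size
    if k == 0:
        raise PoolingError(f"{cov_name or 'covariate'}: no estimates to pool")
    if np.any(se <= 0):
        raise PoolingError("all standard errors must be positive")
    w = 1.0 / se**2
    theta_fe = float(np.sum(w * g) / np.sum(w))
    q = float(np.sum(w * (g - theta_fe) ** 2))
    if k > 1:
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        i2 = max(0.0, 100.0 * (q - (k - 1)) / q) if q > 0 else 0.0
    else:
        tau2 = 0.0
        i2 = 0.0
    if model == "fixed_effect":
        w_star = w
        tau2_out = 0.0
    else:
        w_star = 1.0 / (se**2 + tau2)
        tau2_out = tau2
    theta = float(np.sum(w_star * g) / np.sum(w_star))
    se_theta = float(1.0 / math.sqrt(np.sum(w_star)))
    z = float(norm.ppf(0.5 + level / 2.0))
    return PooledEffect(
        covariate=cov_name,
        k=k,
        theta=theta,
        se=se_theta,
        q=q,
        tau2=tau2_out,
        i2=i2,
        ci_low=theta - z * se_theta,
        ci_high=theta + z * se_theta,
        model=model,
        level=level,
        variant=variant,
    )


def summary_rdor(effect: PooledEffect) -> tuple[float, tuple[float, float]]:
    """Antilog of the pooled effect: (RDOR, (ci_low, ci_high)).

    Full precision; report rendering rounds to one decimal.
    """
    return effect.rdor, effect.rdor_ci


def sensitivity(
    estimates: Sequence[CoefficientEstimate],
    exclude: Iterable[str] | None = None,
    leave_one_out: bool = False,
    model: str = "random_effects_DL",
    level: float = 0.95,
) -> list[PooledEffect]:
    """Re-pool under exclusion and/or leave-one-out variants.

    ``exclude`` removes the named meta-analyses in one variant (e.g. an
    outlier meta-analysis with an extreme coefficient); ``leave_one_out``
    produces one variant per contributing meta-analysis.
    """
    estimates = list(estimates)
    if not all(isinstance(e, CoefficientEstimate) for e in estimates):
        raise TypeError("sensitivity requires CoefficientEstimate inputs")
    out: list[PooledEffect] = []
    if exclude is not None:
        excl = set(exclude)
        kept = [e for e in estimates if e.meta_id not in excl]
        if not kept:
            raise PoolingError(
                "exclusion removes every contributing meta-analysis"
            )
        out.append(
            pool(
                kept,
                model=model,
                level=level,
                variant="exclude:" + ",".join(sorted(excl)),
            )
        )
    if leave_one_out:
        for e in estimates:
            kept = [x for x in estimates if x.meta_id != e.meta_id]
            if not kept:
                raise PoolingError("leave-one-out with a single estimate")
            out.append(
                pool(kept, model=model, level=level, variant=f"loo:{e.meta_id}")
            )
    return out
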