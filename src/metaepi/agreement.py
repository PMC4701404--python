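"""Cohen's kappa for inter-rater agreement on design-characteristic ratings."""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

log = logging.getLogger("metaepi")

__all__ = ["KappaResult", "cohen_kappa", "kappa_table"]


@dataclass(frozen=True)
class KappaResult:
    characteristic: str
    p_observed: float
    p_expected: float
    kappa: float
    n: int


def cohen_kappa(
    ratings_a: Sequence[object],
    ratings_b: Sequence[object],
    characteristic: str = "",
) -> KappaResult:
    """Unweighted Cohen's kappa between two raters of nominal categories.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the fraction of identical
    ratings and p_e the chance agreement from the raters' marginals.  If
    both raters use a single identical category, p_e = 1 and kappa is
    defined as 1 with a warning (agreement is perfect but uninformative).
    """
    if len(ratings_a) != len(ratings_b):
        raise ValueError(
            f"rating sequences differ in length:"
            f" {len(ratings_a)} vs {len(ratings_b)}"
        )
    n = len(ratings_a)
    if n < 2:
        raise ValueError("need at least 2 jointly rated items")
    p_o = sum(a == b for a, b in zip(ratings_a, ratings_b)) / n
    marg_a = Counter(ratings_a)
    marg_b = Counter(ratings_b)
    cats = set(marg_a) | set(marg_b)
    p_e = sum((marg_a[c] / n) * (marg_b[c] / n) for c in cats)
    if p_e >= 1.0:
        log.warning(
            "both raters constant and identical (%s): kappa defined as 1",
            characteristic or "unnamed",
        )
        kappa = 1.0
        p_e = 1.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(
        characteristic=characteristic,
        p_observed=p_o,
        p_expected=p_e,
        kappa=kappa,
        n=n,
    )


def kappa_table(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-characteristic kappa from a long ratings table.

    Expects columns ``item_id, characteristic, rater, level`` with exactly
    two raters; each characteristic is scored on its pairwise-complete
    subset (items rated by both raters).
    """
    required = {"item_id", "characteristic", "rater", "level"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table missing column(s): {sorted(missing)}")
    raters = sorted(ratings["rater"].unique())
    if len(raters) != 2:
        raise ValueError(f"expected exactly 2 raters, found {len(raters)}")
    rows = []
    for char, sub in ratings.groupby("characteristic", sort=True):
        wide = sub.pivot_table(
            index="item_id", columns="rater", values="level", aggfunc="first"
        ).dropna()
        if len(wide) < 2:
            log.warning("characteristic %s: fewer than 2 joint items", char)
            continue
        res = cohen_kappa(
            list(wide[raters[0]]), list(wide[raters[1]]), characteristic=char
        )
        rows.append(
            {
                "characteristic": char,
                "n": res.n,
                "p_observed": res.p_observed,
                "p_expected": res.p_expected,
                "kappa": res.kappa,
            }
        )
    return pd.DataFrame(rows)
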