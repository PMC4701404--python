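"""Binary covariate coding of design profiles for meta-regression.

A ContrastScheme partitions the levels of one design characteristic into an
*exposed* group (coded 1, the design flaw under study) and a *reference*
group (coded 0).  The default multivariable scheme collapses levels into six
contrasts; univariable schemes keep the original levels, one indicator per
non-reference level, a single characteristic at a time.  Blinding is excluded
from the default multivariable scheme (too often unreported to estimate) but
can be re-included.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .core_data import DESIGN_LEVELS, MetaAnalysisSet

__all__ = [
    "ContrastScheme",
    "CodingError",
    "multivariable_scheme",
    "univariable_schemes",
    "encode",
    "drop_invariant_covariates",
    "DEFAULT_UNIVARIABLE_REFERENCE",
]


class CodingError(ValueError):
    """A design level is not covered by the requested contrast scheme."""


@dataclass(frozen=True)
class ContrastScheme:
    """One binary contrast on a design characteristic.

    Levels in ``excluded`` are neither exposed nor reference: studies at an
    excluded level are dropped from the design matrix (with the drop
    recorded by :func:`encode`).
    """

    name: str
    characteristic: str
    exposed: frozenset[str]
    reference: frozenset[str]
    excluded: frozenset[str] = frozenset()
    mode: str = "multivariable"

    def __post_init__(self) -> None:
        levels = set(DESIGN_LEVELS[self.characteristic])
        if self.exposed & self.reference:
            raise ValueError(f"{self.name}: exposed and reference overlap")
        covered = self.exposed | self.reference | self.excluded
        if covered != levels:
            raise ValueError(
                f"{self.name}: scheme covers {sorted(covered)} but"
                f" {self.characteristic} has levels {sorted(levels)}"
            )

    def code(self, level: str) -> int | None:
        """1 for exposed, 0 for reference, None for excluded."""
        if level in self.exposed:
            return 1
        if level in self.reference:
            return 0
        if level in self.excluded:
            return None
        raise CodingError(
            f"level {level!r} of {self.characteristic} not covered by"
            f" scheme {self.name}"
        )


def multivariable_scheme(
    internal_validation_policy: str = "narrow",
    include_assessment: bool = False,
) -> tuple[ContrastScheme, ...]:
    """The six collapsed multivariable contrasts (exposed=1 vs reference=0).

    - inadequate vs adequate sample size;
    - nonconsecutive vs consecutive-or-unclear patient selection;
    - case-control vs cohort-or-unclear spectrum;
    - narrow vs broad-or-unclear validation type;
    - differential vs complete/partial/unclear verification;
    - unclear vs prospective-or-retrospective data collection.

    ``internal_validation_policy`` places the "internal" validation level
    with the exposed (narrow) side by default; "reference" groups it with
    broad/unclear, "exclude" drops internally validated studies.  Blinding is
    excluded unless ``include_assessment`` (nonblind/unclear vs blind).
    """
    if internal_validation_policy not in ("narrow", "reference", "exclude"):
        raise ValueError(
            "internal_validation_policy must be narrow|reference|exclude,"
            f" got {internal_validation_policy!r}"
        )
    narrow_exposed = {"narrow"}
    narrow_reference = {"broad", "unclear"}
    narrow_excluded: set[str] = set()
    if internal_validation_policy == "narrow":
        narrow_exposed.add("internal")
    elif internal_validation_policy == "reference":
        narrow_reference.add("internal")
    else:
        narrow_excluded.add("internal")
    schemes = [
        ContrastScheme(
            "inadequate_sample_size",
            "sample_size",
            frozenset({"inadequate"}),
            frozenset({"adequate"}),
        ),
        ContrastScheme(
            "nonconsecutive_selection",
            "patient_selection",
            frozenset({"nonconsecutive"}),
            frozenset({"consecutive", "unclear"}),
        ),
        ContrastScheme(
            "case_control_design",
            "spectrum",
            frozenset({"case_control"}),
            frozenset({"cohort", "unclear"}),
        ),
        ContrastScheme(
            "narrow_validation",
            "validation_type",
            frozenset(narrow_exposed),
            frozenset(narrow_reference),
            frozenset(narrow_excluded),
        ),
        ContrastScheme(
            "differential_verification",
            "verification",
            frozenset({"differential"}),
            frozenset({"complete", "partial", "unclear"}),
        ),
        ContrastScheme(
            "unclear_data_collection",
            "data_collection",
            frozenset({"unclear"}),
            frozenset({"prospective", "retrospective"}),
        ),
    ]
    if include_assessment:
        schemes.insert(
            4,
            ContrastScheme(
                "nonblind_assessment",
                "assessment",
                frozenset({"nonblind", "unclear"}),
                frozenset({"blind"}),
            ),
        )
    return tuple(schemes)


#: Reference level of each characteristic in the univariable analysis.
DEFAULT_UNIVARIABLE_REFERENCE: dict[str, str] = {
    "sample_size": "adequate",
    "patient_selection": "consecutive",
    "spectrum": "cohort",
    "validation_type": "broad",
    "assessment": "blind",
    "verification": "complete",
    "data_collection": "prospective",
}


def univariable_schemes(
    characteristic: str,
    reference: str | None = None,
) -> tuple[ContrastScheme, ...]:
    """Uncollapsed indicators for one characteristic, one per non-reference level.

    Each indicator contrasts a single level against the reference level; the
    remaining levels are excluded from that indicator's contrast so each
    regression compares exactly two groups, mirroring a one-characteristic-
    at-a-time analysis.
    """
    if reference is None:
        reference = DEFAULT_UNIVARIABLE_REFERENCE[characteristic]
    levels = DESIGN_LEVELS[characteristic]
    if reference not in levels:
        raise ValueError(f"{reference!r} is not a level of {characteristic}")
    return tuple(
        ContrastScheme(
            name=f"{characteristic}_{lvl}",
            characteristic=characteristic,
            exposed=frozenset({lvl}),
            reference=frozenset({reference}),
            excluded=frozenset(set(levels) - {lvl, reference}),
            mode="univariable",
        )
        for lvl in levels
        if lvl != reference
    )


def encode(
    ma_set: MetaAnalysisSet, schemes: tuple[ContrastScheme, ...]
) -> pd.DataFrame:
    """Design matrix: one row per study, one 0/1 column per contrast.

    Deterministic given input order.  A study whose level is *excluded* by
    any scheme is dropped from the matrix entirely (its row would have no
    defined code for that contrast); the caller can detect drops by
    comparing row counts.
    """
    rows: dict[str, dict[str, int]] = {}
    for st in ma_set.studies:
        codes: dict[str, int] = {}
        dropped = False
        for sch in schemes:
            c = sch.code(st.design.level(sch.characteristic))
            if c is None:
                dropped = True
                break
            codes[sch.name] = c
        if not dropped:
            rows[st.study_id] = codes
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[s.name for s in schemes], dtype=int
    )


def drop_invariant_covariates(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Remove covariate columns constant within the meta-analysis.

    A constant column is collinear with the intercept: its coefficient is
    not estimable and the meta-analysis contributes nothing to that
    covariate's pooled effect.  Returns the reduced matrix and the dropped
    column names so pooling can account for the evidence base.
    """
    dropped = [c for c in matrix.columns if matrix[c].nunique() <= 1]
    return matrix.drop(columns=dropped), dropped
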