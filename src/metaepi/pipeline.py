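"""End-to-end two-stage driver: encode -> stage 1 fits -> stage 2 pooling.

``run_two_stage`` is the library core reused by the simulation harness and
the CLI; ``run_pipeline`` adds file IO, logging and report rendering around
it.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import coding, pooling, regression
from .accuracy import accuracy_from_table
from .core_data import (
    MetaAnalysisSet,
    read_studies,
    studies_frame,
    validate_dataset,
)

log = logging.getLogger("metaepi")

__all__ = [
    "TwoStageResult",
    "PipelineConfig",
    "run_two_stage",
    "run_scheme_groups",
    "scheme_groups_for",
    "run_pipeline",
]


@dataclass
class TwoStageResult:
    """Fits, per-covariate coefficient estimates, and pooled effects."""

    fits: list[regression.MetaRegressionFit]
    estimates: dict[str, list[regression.CoefficientEstimate]]
    pooled: dict[str, pooling.PooledEffect]
    skipped: list[tuple[str, str]]  # (meta_id, reason)
    not_estimable: dict[str, str]  # covariate -> reason

    def fits_frame(self) -> pd.DataFrame:
        rows = [
            dataclasses.asdict(e)
            for ests in self.estimates.values()
            for e in ests
        ]
        cols = [
            "meta_id",
            "covariate",
            "gamma",
            "se",
            "n_studies",
            "df",
            "tau2_reg",
            "weighting",
        ]
        return pd.DataFrame(rows, columns=cols)

    def summary_frame(
        self, variants: Sequence[pooling.PooledEffect] = ()
    ) -> pd.DataFrame:
        rows = []
        for eff in list(self.pooled.values()) + list(variants):
            lo, hi = eff.rdor_ci
            rows.append(
                {
                    "covariate": eff.covariate,
                    "k": eff.k,
                    "rdor": eff.rdor,
                    "ci_low": lo,
                    "ci_high": hi,
                    "tau2": eff.tau2,
                    "Q": eff.q,
                    "I2": eff.i2,
                    "model": eff.model,
                    "variant": eff.variant,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "covariate",
                "k",
                "rdor",
                "ci_low",
                "ci_high",
                "tau2",
                "Q",
                "I2",
                "model",
                "variant",
            ],
        )


def run_two_stage(
    sets: Sequence[MetaAnalysisSet],
    schemes: tuple[coding.ContrastScheme, ...] | None = None,
    weighting: str = "random_effects",
    model: str = "random_effects_DL",
    level: float = 0.95,
) -> TwoStageResult:
    """Stage 1 per eligible meta-analysis, then DL pooling per covariate.

    Meta-analyses with fewer than four studies, a rank-deficient design, or
    no residual degrees of freedom are skipped with a recorded reason; a
    covariate's pooled effect uses only meta-analyses where it survived the
    invariance drop.
    """
    if schemes is None:
        schemes = coding.multivariable_scheme()
    fits: list[regression.MetaRegressionFit] = []
    skipped: list[tuple[str, str]] = []
    estimates: dict[str, list[regression.CoefficientEstimate]] = {
        s.name: [] for s in schemes
    }
    for ms in sets:
        if not ms.eligible:
            skipped.append((ms.meta_id, f"only {ms.n_studies} studies (< 4)"))
            continue
        matrix = coding.encode(ms, schemes)
        matrix, dropped = coding.drop_invariant_covariates(matrix)
        try:
            f = regression.fit(ms, matrix, weighting=weighting)
        except (
            regression.CollinearityError,
            regression.DegreesOfFreedomError,
        ) as err:
            skipped.append((ms.meta_id, str(err)))
            continue
        f.dropped = dropped
        fits.append(f)
        for est in f.coefficient_estimates():
            estimates[est.covariate].append(est)
    pooled: dict[str, pooling.PooledEffect] = {}
    not_estimable: dict[str, str] = {}
    for name, ests in estimates.items():
        if not ests:
            not_estimable[name] = "constant in every fitted meta-analysis"
            continue
        pooled[name] = pooling.pool(ests, model=model, level=level)
    return TwoStageResult(
        fits=fits,
        estimates=estimates,
        pooled=pooled,
        skipped=skipped,
        not_estimable=not_estimable,
    )


@dataclass
class PipelineConfig:
    """Serializable run configuration; echoed next to the outputs."""

    input: str = ""
    scheme: str = "multivariable"
    internal_validation_policy: str = "narrow"
    include_assessment: bool = False
    weighting: str = "random_effects"
    model: str = "random_effects_DL"
    level: float = 0.95
    exclude: list[str] = field(default_factory=list)
    leave_one_out: bool = False
    fixed_effect_sensitivity: bool = False
    out_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"
    column_map: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def scheme_groups_for(
    config: PipelineConfig,
) -> list[tuple[coding.ContrastScheme, ...]]:
    """Contrast groups fitted together in one regression.

    Multivariable mode fits all six collapsed contrasts jointly; univariable
    mode fits one indicator at a time (each original level against its
    reference, the other levels excluded), one regression per indicator.
    """
    if config.scheme == "multivariable":
        return [
            coding.multivariable_scheme(
                internal_validation_policy=config.internal_validation_policy,
                include_assessment=config.include_assessment,
            )
        ]
    if config.scheme == "univariable":
        groups: list[tuple[coding.ContrastScheme, ...]] = []
        for char in coding.DEFAULT_UNIVARIABLE_REFERENCE:
            groups.extend((s,) for s in coding.univariable_schemes(char))
        return groups
    raise ValueError(f"unknown scheme {config.scheme!r}")


def run_scheme_groups(
    sets: Sequence[MetaAnalysisSet],
    groups: Sequence[tuple[coding.ContrastScheme, ...]],
    weighting: str = "random_effects",
    model: str = "random_effects_DL",
    level: float = 0.95,
) -> TwoStageResult:
    """Run the two-stage analysis per contrast group and merge the results."""
    merged = TwoStageResult([], {}, {}, [], {})
    for group in groups:
        res = run_two_stage(
            sets, schemes=group, weighting=weighting, model=model, level=level
        )
        merged.fits.extend(res.fits)
        merged.estimates.update(res.estimates)
        merged.pooled.update(res.pooled)
        merged.skipped.extend(res.skipped)
        merged.not_estimable.update(res.not_estimable)
    return merged


def _render_report(
    result: TwoStageResult, variants: Sequence[pooling.PooledEffect]
) -> str:
    """Forest-style text table of summary RDORs (1-decimal rounding)."""
    lines = [
        "# Summary relative diagnostic odds ratios",
        "",
        "| covariate | k | RDOR | 95% CI | I2 (%) | variant |",
        "|---|---|---|---|---|---|",
    ]
    for eff in list(result.pooled.values()) + list(variants):
        lo, hi = eff.rdor_ci
        lines.append(
            f"| {eff.covariate} | {eff.k} | {eff.rdor:.1f} |"
            f" {lo:.1f}-{hi:.1f} | {eff.i2:.1f} | {eff.variant} |"
        )
    if result.not_estimable:
        lines.append("")
        lines.append("Not estimable: " + ", ".join(
            f"{c} ({r})" for c, r in result.not_estimable.items()
        ))
    if result.skipped:
        lines.append("")
        lines.append("## Skipped meta-analyses")
        for mid, reason in result.skipped:
            lines.append(f"- {mid}: {reason}")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(
    config: PipelineConfig,
    sets: Sequence[MetaAnalysisSet] | None = None,
) -> TwoStageResult:
    """Read -> validate -> encode -> stage 1 -> stage 2 (+ sensitivity).

    Writes ``fits.tsv``, ``summary.tsv``, ``accuracy.tsv``, ``report.md``,
    ``validation.json``, ``run.log`` and ``config.echo.yaml`` under
    ``config.out_dir``.  Pre-loaded ``sets`` bypass file reading (used by
    the simulation harness).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level.upper())
    try:
        if sets is None:
            sets = read_studies(
                config.input, column_map=config.column_map or None
            )
        report = validate_dataset(sets)
        for issue in report.issues:
            log.warning(issue)
        report.to_json(out / "validation.json")

        acc_rows = []
        for ms in sets:
            for st in ms.studies:
                a = accuracy_from_table(st.table)
                acc_rows.append(
                    {
                        "meta_id": st.meta_id,
                        "study_id": st.study_id,
                        "sens": a.sens,
                        "spec": a.spec,
                        "dor": a.dor,
                        "ln_dor": a.ln_dor,
                        "var_ln_dor": a.var_ln_dor,
                        "d": a.d,
                        "s": a.s,
                    }
                )
        pd.DataFrame(acc_rows).to_csv(
            out / "accuracy.tsv", sep="\t", index=False
        )

        result = run_scheme_groups(
            sets,
            scheme_groups_for(config),
            weighting=config.weighting,
            model=config.model,
            level=config.level,
        )
        for mid, reason in result.skipped:
            log.info("skipped %s: %s", mid, reason)
        for eff in result.pooled.values():
            if eff.k == 1:
                log.warning(
                    "covariate %s pooled from a single meta-analysis",
                    eff.covariate,
                )

        variants: list[pooling.PooledEffect] = []
        for name, ests in result.estimates.items():
            if not ests:
                continue
            if config.exclude:
                variants.extend(
                    pooling.sensitivity(
                        ests,
                        exclude=config.exclude,
                        model=config.model,
                        level=config.level,
                    )
                )
            if config.leave_one_out and len(ests) >= 2:
                variants.extend(
                    pooling.sensitivity(
                        ests,
                        leave_one_out=True,
                        model=config.model,
                        level=config.level,
                    )
                )
            if config.fixed_effect_sensitivity:
                variants.append(
                    pooling.pool(
                        ests,
                        model="fixed_effect",
                        level=config.level,
                        variant="fixed_effect",
                    )
                )

        result.fits_frame().to_csv(out / "fits.tsv", sep="\t", index=False)
        result.summary_frame(variants).to_csv(
            out / "summary.tsv", sep="\t", index=False
        )
        (out / "report.md").write_text(_render_report(result, variants))
        config.to_yaml(out / "config.echo.yaml")
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
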