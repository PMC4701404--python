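import pandas as pd
import pytest

from metaepi.coding import (
    CodingError,
    ContrastScheme,
    drop_invariant_covariates,
    encode,
    multivariable_scheme,
    univariable_schemes,
)
from metaepi.core_data import DESIGN_LEVELS, MetaAnalysisSet
from .conftest import make_study

REFERENCE_PROFILE = dict(
    sample_size="adequate",
    patient_selection="consecutive",
    spectrum="cohort",
    validation_type="broad",
    verification="complete",
    data_collection="prospective",
)


def _set_of(profiles):
    studies = tuple(
        make_study(f"s{i}", "m1", 150, 30, 50, 170, **p)
        for i, p in enumerate(profiles)
    )
    return MetaAnalysisSet("m1", studies)


class TestMultivariableScheme:
    def test_six_contrasts_blinding_absent(self):
        schemes = multivariable_scheme()
        names = [s.name for s in schemes]
        assert len(names) == 6
        assert not any("blind" in n or "assessment" in n for n in names)

    def test_collapsing_rules(self):
        by_name = {s.name: s for s in multivariable_scheme()}
        assert by_name["nonconsecutive_selection"].reference == {
            "consecutive", "unclear"}
        assert by_name["case_control_design"].reference == {"cohort", "unclear"}
        assert by_name["narrow_validation"].reference == {"broad", "unclear"}
        assert by_name["differential_verification"].reference == {
            "complete", "partial", "unclear"}
        assert by_name["unclear_data_collection"].exposed == {"unclear"}
        assert by_name["unclear_data_collection"].reference == {
            "prospective", "retrospective"}

    def test_assessment_can_be_reincluded(self):
        names = [s.name for s in multivariable_scheme(include_assessment=True)]
        assert "nonblind_assessment" in names

    def test_every_level_covered(self):
        for sch in multivariable_scheme():
            covered = sch.exposed | sch.reference | sch.excluded
            assert covered == set(DESIGN_LEVELS[sch.characteristic])


class TestEncode:
    def test_reference_profile_is_all_zero(self):
        matrix = encode(_set_of([REFERENCE_PROFILE] * 4), multivariable_scheme())
        assert matrix.shape == (4, 6)
        assert (matrix == 0).all().all()

    def test_exposed_trio_codes_one(self):
        flawed = dict(REFERENCE_PROFILE)
        flawed.update(
            spectrum="case_control", verification="differential",
            sample_size="inadequate",
            patient_selection="unclear", validation_type="unclear",
            data_collection="prospective",
        )
        row = encode(_set_of([flawed]), multivariable_scheme()).iloc[0]
        assert row["case_control_design"] == 1
        assert row["differential_verification"] == 1
        assert row["inadequate_sample_size"] == 1
        assert row["nonconsecutive_selection"] == 0
        assert row["narrow_validation"] == 0
        assert row["unclear_data_collection"] == 0

    def test_identical_profiles_identical_rows(self):
        matrix = encode(_set_of([REFERENCE_PROFILE] * 4), multivariable_scheme())
        assert matrix.drop_duplicates().shape[0] == 1

    @pytest.mark.parametrize(
        "policy,expected", [("narrow", 1), ("reference", 0)]
    )
    def test_internal_validation_policy(self, policy, expected):
        prof = dict(REFERENCE_PROFILE, validation_type="internal")
        matrix = encode(
            _set_of([prof]),
            multivariable_scheme(internal_validation_policy=policy),
        )
        assert matrix.iloc[0]["narrow_validation"] == expected

    def test_internal_exclude_policy_drops_study(self):
        profs = [REFERENCE_PROFILE] * 3 + [
            dict(REFERENCE_PROFILE, validation_type="internal")]
        matrix = encode(
            _set_of(profs),
            multivariable_scheme(internal_validation_policy="exclude"),
        )
        assert matrix.shape[0] == 3

    def test_uncovered_level_is_named_error(self):
        bad_scheme = (
            ContrastScheme(
                "partial_verification",
                "verification",
                frozenset({"partial"}),
                frozenset({"complete"}),
                frozenset({"differential", "unclear"}),
            ),
        )
        # excluded levels drop studies rather than erroring
        profs = [dict(REFERENCE_PROFILE, verification="unclear")]
        assert encode(_set_of(profs), bad_scheme).empty
        with pytest.raises(CodingError, match="verification"):
            bad_scheme[0].code("nonsense")

    def test_empty_scheme_gives_zero_columns(self):
        matrix = encode(_set_of([REFERENCE_PROFILE] * 4), ())
        assert matrix.shape[1] == 0


class TestUnivariableSchemes:
    def test_one_indicator_per_nonreference_level(self):
        schemes = univariable_schemes("verification")
        assert {s.name for s in schemes} == {
            "verification_partial",
            "verification_differential",
            "verification_unclear",
        }
        for s in schemes:
            assert s.reference == {"complete"}
            assert s.mode == "univariable"


class TestDropInvariantCovariates:
    def test_constant_column_dropped_and_recorded(self):
        m = pd.DataFrame({"a": [1, 1, 1], "b": [0, 1, 0]})
        reduced, dropped = drop_invariant_covariates(m)
        assert dropped == ["a"]
        assert list(reduced.columns) == ["b"]

    def test_varying_column_retained(self):
        m = pd.DataFrame({"b": [0, 1, 0]})
        reduced, dropped = drop_invariant_covariates(m)
        assert dropped == []
        assert reduced.equals(m)

    def test_all_constant_yields_threshold_only_model(self):
        m = pd.DataFrame({"a": [1, 1], "b": [0, 0]})
        reduced, dropped = drop_invariant_covariates(m)
        assert reduced.shape[1] == 0
        assert set(dropped) == {"a", "b"}

    def test_retained_coefficients_unchanged_by_drop(self, six_study_set):
        """Dropping a constant column must not move the other estimates."""
        from metaepi import regression

        schemes = multivariable_scheme()
        matrix = encode(six_study_set, schemes)
        reduced, dropped = drop_invariant_covariates(matrix)
        assert "case_control_design" in reduced.columns
        fit_reduced = regression.fit(six_study_set, reduced, "fixed_effect")
        manual = matrix[[c for c in matrix.columns if matrix[c].nunique() > 1]]
        fit_manual = regression.fit(six_study_set, manual, "fixed_effect")
        assert fit_reduced.gamma("case_control_design") == pytest.approx(
            fit_manual.gamma("case_control_design"), rel=1e-12
        )
        assert set(dropped) == set(matrix.columns) - set(manual.columns)
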