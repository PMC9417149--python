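"""Ground-truth labelling, the three prediction rules and eligibility."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmdframe import (
    POINT_MUTATION,
    FrameStatus,
    PatientRecord,
    PhenotypeLabel,
    VariantEvent,
    VariantKind,
    apply_eligibility,
    milestone_delayed,
    phenotype_from_followup,
    predict_combined,
    predict_frame,
    predict_milestone,
)

DEL_45 = VariantEvent(VariantKind.DELETION, 45, 45)


def _record(**kwargs) -> PatientRecord:
    defaults = dict(
        patient_id="p1",
        sex="male",
        variant=DEL_45,
        first_walking_age_months=15.0,
        ambulation_lost=False,
        age_at_last_followup_years=17.0,
    )
    defaults.update(kwargs)
    return PatientRecord(**defaults)


class TestPhenotypeFromFollowup:
    def test_ambulation_lost_before_cutoff_is_dmd(self):
        r = _record(ambulation_lost=True, age_at_ambulation_loss_years=11.14,
                    age_at_last_followup_years=12.0)
        assert phenotype_from_followup(r) is PhenotypeLabel.DMD

    def test_ambulant_past_cutoff_is_bmd(self):
        r = _record(age_at_last_followup_years=18.0)
        assert phenotype_from_followup(r) is PhenotypeLabel.BMD

    def test_ambulant_under_cutoff_is_indeterminate(self):
        r = _record(age_at_last_followup_years=12.0)
        assert phenotype_from_followup(r) is PhenotypeLabel.INDETERMINATE

    def test_loss_after_cutoff_is_bmd(self):
        r = _record(ambulation_lost=True, age_at_ambulation_loss_years=17.0,
                    age_at_last_followup_years=18.0)
        assert phenotype_from_followup(r) is PhenotypeLabel.BMD

    def test_cutoff_is_configurable(self):
        r = _record(ambulation_lost=True, age_at_ambulation_loss_years=11.0,
                    age_at_last_followup_years=12.0)
        assert phenotype_from_followup(r, cutoff_years=10.0) is PhenotypeLabel.BMD


class TestMilestone:
    @pytest.mark.parametrize(
        "months,expected",
        [(30.0, True), (18.0, True), (17.99, False), (14.0, False), (12.0, False)],
    )
    def test_threshold_inclusive_at_18_months(self, months, expected):
        assert milestone_delayed(months) is expected

    def test_missing_age_is_unknown_not_false(self):
        assert milestone_delayed(None) is None

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            milestone_delayed(-1.0)


class TestRulePredictions:
    def test_frame_rule_mapping(self):
        assert predict_frame(FrameStatus.OUT_OF_FRAME) is PhenotypeLabel.DMD
        assert predict_frame(FrameStatus.IN_FRAME) is PhenotypeLabel.BMD
        assert predict_frame(FrameStatus.INDETERMINATE) is PhenotypeLabel.INDETERMINATE

    def test_milestone_rule_mapping(self):
        assert predict_milestone(True) is PhenotypeLabel.DMD
        assert predict_milestone(False) is PhenotypeLabel.BMD
        assert predict_milestone(None) is PhenotypeLabel.INDETERMINATE

    @pytest.mark.parametrize(
        "frame,milestone,expected",
        [
            (PhenotypeLabel.BMD, PhenotypeLabel.DMD, PhenotypeLabel.DMD),
            (PhenotypeLabel.DMD, PhenotypeLabel.BMD, PhenotypeLabel.DMD),
            (PhenotypeLabel.DMD, PhenotypeLabel.DMD, PhenotypeLabel.DMD),
            (PhenotypeLabel.BMD, PhenotypeLabel.BMD, PhenotypeLabel.BMD),
            (PhenotypeLabel.INDETERMINATE, PhenotypeLabel.BMD, PhenotypeLabel.BMD),
            (PhenotypeLabel.INDETERMINATE, PhenotypeLabel.DMD, PhenotypeLabel.DMD),
            (
                PhenotypeLabel.INDETERMINATE,
                PhenotypeLabel.INDETERMINATE,
                PhenotypeLabel.INDETERMINATE,
            ),
        ],
    )
    def test_combined_or_truth_table(self, frame, milestone, expected):
        assert predict_combined(frame, milestone) is expected

    @given(
        frame=st.sampled_from(list(PhenotypeLabel)),
        milestone=st.sampled_from(list(PhenotypeLabel)),
    )
    def test_combined_monotone_in_both_inputs(self, frame, milestone):
        """Upgrading either input BMD -> DMD never downgrades the output."""
        base = predict_combined(frame, milestone)
        for up in (
            predict_combined(PhenotypeLabel.DMD, milestone),
            predict_combined(frame, PhenotypeLabel.DMD),
        ):
            if base is PhenotypeLabel.DMD:
                assert up is PhenotypeLabel.DMD
            else:
                assert up is not PhenotypeLabel.BMD or base is PhenotypeLabel.BMD


def test_combined_rule_dominance_on_random_cohorts():
    """OR combination never loses sensitivity and never gains specificity
    relative to either component rule, on 1,000 random cohorts."""
    rng = np.random.default_rng(20221)
    for _ in range(1000):
        n = int(rng.integers(10, 60))
        truth = rng.random(n) < rng.uniform(0.2, 0.9)  # True = DMD
        frame_says_dmd = rng.random(n) < rng.uniform(0.1, 0.9)
        milestone_says_dmd = rng.random(n) < rng.uniform(0.1, 0.9)
        combined = frame_says_dmd | milestone_says_dmd
        if truth.any():
            sens = lambda pred: (pred & truth).sum() / truth.sum()
            assert sens(combined) >= max(sens(frame_says_dmd), sens(milestone_says_dmd))
        if (~truth).any():
            spec = lambda pred: (~pred & ~truth).sum() / (~truth).sum()
            assert spec(combined) <= min(spec(frame_says_dmd), spec(milestone_says_dmd))


class TestEligibility:
    def test_study_profile_counts(self, manifest):
        eligible, flow = apply_eligibility(manifest)
        assert len(manifest) == 208
        assert flow == {"female": 0, "point_mutation": 23, "ambulant_under_cutoff": 16}
        assert len(eligible) == 169
        # del/dup fraction before the ambulation filter: 185/208
        n_deldup = sum(1 for r in manifest if r.variant != POINT_MUTATION)
        assert n_deldup == 185
        assert round(100 * n_deldup / len(manifest), 1) == 88.9

    def test_empty_manifest(self):
        eligible, flow = apply_eligibility([])
        assert eligible == []
        assert all(v == 0 for v in flow.values())

    def test_female_record_excluded(self):
        eligible, flow = apply_eligibility([_record(sex="female")])
        assert eligible == [] and flow["female"] == 1

    def test_filter_order_independent_counts(self, manifest):
        """Each exclusion reason touches a disjoint set of records in the
        study-profile manifest, so tallies are order-invariant."""
        _, flow = apply_eligibility(manifest)
        point = [r for r in manifest if r.variant == POINT_MUTATION]
        assert all(r.sex == "male" for r in point)
        young = [
            r
            for r in manifest
            if r.variant != POINT_MUTATION
            and phenotype_from_followup(r) is PhenotypeLabel.INDETERMINATE
        ]
        assert (len(point), len(young)) == (
            flow["point_mutation"],
            flow["ambulant_under_cutoff"],
        )


class TestPatientRecordInvariants:
    def test_ambulation_loss_requires_age(self):
        with pytest.raises(ValueError, match="ambulation_lost"):
            _record(ambulation_lost=True, age_at_ambulation_loss_years=None)

    def test_loss_after_followup_rejected(self):
        with pytest.raises(ValueError, match="after last follow-up"):
            _record(
                ambulation_lost=True,
                age_at_ambulation_loss_years=13.0,
                age_at_last_followup_years=12.0,
            )

    def test_implausible_walking_age_rejected(self):
        with pytest.raises(ValueError, match="plausible"):
            _record(first_walking_age_months=100.0)
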