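"""Synoptic lesion scoring: scheme validation, grading, caps, profiles."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pps import lesion_scoring as ls
from pps.lesion_scoring import (
    CategoryDefinition,
    DuplicateObservationError,
    GradeRangeError,
    LesionDefinition,
    LesionObservation,
    SchemeValidationError,
    ScoringScheme,
    UnknownLesionError,
)

CAPS = {"MVM": 14, "implantation_site": 4, "chorioamnionitis": 11,
        "villous_maldevelopment": 5, "fetal_vascular_malperfusion": 6,
        "interface_disturbance": 5, "chronic_inflammation": 6}


def obs_at_max(scheme, category_id=None, participant="p1"):
    lesions = scheme.lesions
    if category_id is not None:
        lesions = [l for l in lesions if l.category_id == category_id]
    return [LesionObservation(participant, l.lesion_id, l.max_grade) for l in lesions]


class TestSchemeValidation:
    def test_default_scheme_structure(self, scheme):
        assert {c.category_id: c.max_score for c in scheme.categories} == CAPS
        assert len(scheme.categories) == 7
        # every lesion belongs to exactly one declared category
        for lesion in scheme.lesions:
            assert lesion.lesion_id in scheme.category(lesion.category_id).member_lesions

    def test_dangling_category_reference_rejected(self):
        with pytest.raises(SchemeValidationError, match="unknown category"):
            ScoringScheme(
                categories=(CategoryDefinition("A", "A", 3),),
                lesions=(LesionDefinition("x", "x", "B", "binary"),),
            )

    def test_duplicate_lesion_id_rejected(self):
        with pytest.raises(SchemeValidationError, match="duplicate lesion_id"):
            ScoringScheme(
                categories=(CategoryDefinition("A", "A", 3),),
                lesions=(
                    LesionDefinition("x", "x", "A", "binary"),
                    LesionDefinition("x", "x2", "A", "graded"),
                ),
            )

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(scale="ternary"), "scale"),
            (dict(scale="binary", grade_labels=("a", "b", "c")), "grade labels"),
            (dict(scale="graded", max_grade=2), "max_grade"),
        ],
    )
    def test_bad_lesion_definitions_rejected(self, kwargs, message):
        with pytest.raises(SchemeValidationError, match=message):
            LesionDefinition("x", "x", "A", **kwargs)

    def test_nonpositive_cap_rejected(self):
        with pytest.raises(SchemeValidationError, match="positive"):
            CategoryDefinition("A", "A", 0)

    def test_load_scheme_malformed_file(self, tmp_path):
        bad = tmp_path / "scheme.yaml"
        bad.write_text("categories:\n  - category_id: A\n")  # missing max_score + lesions
        with pytest.raises(SchemeValidationError):
            ls.load_scheme(bad)


class TestScoreLesion:
    @pytest.mark.parametrize(
        "lesion_id, grade, expected",
        [
            ("infarction", "diffuse", 3),
            ("infarction", "focal", 1),
            ("infarction", "absent", 0),
            ("thrombosis", "present", 1),
            ("thrombosis", "absent", 0),
            ("syncytial_knots", 2, 2),
        ],
    )
    def test_grades_and_labels(self, scheme, lesion_id, grade, expected):
        obs = LesionObservation("p1", lesion_id, grade)
        assert ls.score_lesion(obs, scheme) == expected

    @pytest.mark.parametrize(
        "lesion_id, grade, error",
        [
            ("thrombosis", 2, GradeRangeError),   # binary lesion graded 2
            ("infarction", 4, GradeRangeError),   # beyond the graded scale
            ("infarction", -1, GradeRangeError),
            ("infarction", "massive", GradeRangeError),  # unknown label
            ("not_a_lesion", 1, UnknownLesionError),
        ],
    )
    def test_invalid_observations_rejected(self, scheme, lesion_id, grade, error):
        with pytest.raises(error):
            ls.score_lesion(LesionObservation("p1", lesion_id, grade), scheme)


class TestCategorySeverity:
    def test_cap_binds_at_saturation(self, scheme):
        # MVM member max-grades sum to 15; the printed cap of 14 binds
        cat = scheme.category("MVM")
        assert sum(scheme.lesion(l).max_grade for l in cat.member_lesions) == 15
        assert ls.category_severity(obs_at_max(scheme, "MVM"), cat, scheme) == 14

    @pytest.mark.parametrize("category_id", sorted(CAPS))
    def test_saturation_reaches_each_cap(self, scheme, category_id):
        cat = scheme.category(category_id)
        assert ls.category_severity(obs_at_max(scheme, category_id), cat, scheme) == CAPS[category_id]

    def test_empty_observations_score_zero(self, scheme):
        assert ls.category_severity([], scheme.category("MVM"), scheme) == 0

    def test_partial_sum_below_cap(self, scheme):
        obs = [
            LesionObservation("p1", "infarction", 1),
            LesionObservation("p1", "syncytial_knots", 2),
        ]
        assert ls.category_severity(obs, scheme.category("MVM"), scheme) == 3

    def test_other_category_observations_ignored(self, scheme):
        obs = [LesionObservation("p1", "villitis_unknown_etiology", 3)]
        assert ls.category_severity(obs, scheme.category("MVM"), scheme) == 0

    def test_duplicate_observation_rejected(self, scheme):
        obs = [
            LesionObservation("p1", "infarction", 1),
            LesionObservation("p1", "infarction", 2),
        ]
        with pytest.raises(DuplicateObservationError):
            ls.category_severity(obs, scheme.category("MVM"), scheme)


class TestSeverityProfile:
    def test_pathology_free_placenta(self, scheme):
        obs = [LesionObservation("p1", l.lesion_id, 0) for l in scheme.lesions]
        prof = ls.severity_profile(obs, scheme)
        assert prof.cumulative_score == 0
        assert not prof.mvm_severe
        assert all(v == 0 for v in prof.category_scores.values())
        assert prof.missing_lesions == ()

    @pytest.mark.parametrize("mvm_grade, severe", [(1, False), (2, True), (3, True)])
    def test_severe_mvm_flips_exactly_at_threshold(self, scheme, mvm_grade, severe):
        obs = [LesionObservation("p1", "accelerated_villous_maturation", mvm_grade)]
        assert ls.severity_profile(obs, scheme).mvm_severe is severe

    def test_custom_threshold(self, scheme):
        obs = [LesionObservation("p1", "accelerated_villous_maturation", 2)]
        assert not ls.severity_profile(obs, scheme, mvm_threshold=3).mvm_severe

    def test_unobserved_lesions_flagged_missing(self, scheme):
        obs = [LesionObservation("p1", "infarction", 1)]
        prof = ls.severity_profile(obs, scheme)
        assert "syncytial_knots" in prof.missing_lesions
        assert "infarction" not in prof.missing_lesions

    def test_mixed_participants_rejected(self, scheme):
        obs = [
            LesionObservation("p1", "infarction", 1),
            LesionObservation("p2", "thrombosis", 1),
        ]
        with pytest.raises(ValueError, match="participants"):
            ls.severity_profile(obs, scheme)


@st.composite
def observation_sets(draw):
    scheme = ls.default_scheme()
    lesions = draw(
        st.lists(st.sampled_from(scheme.lesions), unique_by=lambda l: l.lesion_id, max_size=12)
    )
    return [
        LesionObservation("p1", l.lesion_id, draw(st.integers(0, l.max_grade))) for l in lesions
    ]


class TestProperties:
    @given(observation_sets(), st.randoms(use_true_random=False))
    def test_grade_increase_never_decreases_scores(self, obs, rnd):
        scheme = ls.default_scheme()
        before = ls.severity_profile(obs, scheme)
        bumpable = [
            (i, o) for i, o in enumerate(obs)
            if o.grade < scheme.lesion(o.lesion_id).max_grade
        ]
        if not bumpable:
            return
        i, o = rnd.choice(bumpable)
        bumped = list(obs)
        bumped[i] = LesionObservation(o.participant_id, o.lesion_id, o.grade + 1)
        after = ls.severity_profile(bumped, scheme)
        cat = scheme.lesion(o.lesion_id).category_id
        assert after.category_scores[cat] >= before.category_scores[cat]
        assert after.cumulative_score >= before.cumulative_score

    @given(observation_sets(), st.integers(0, 2**31 - 1))
    def test_permutation_invariance_and_idempotence(self, obs, seed):
        scheme = ls.default_scheme()
        shuffled = list(obs)
        random.Random(seed).shuffle(shuffled)
        assert ls.severity_profile(obs, scheme) == ls.severity_profile(shuffled, scheme)
        assert ls.severity_profile(obs, scheme) == ls.severity_profile(obs, scheme)


class TestReaders:
    def test_long_reader_round_trip(self, scheme):
        import pandas as pd

        df = pd.DataFrame(
            {
                "participant_id": ["p1", "p1", "p2"],
                "lesion_id": ["infarction", "thrombosis", "syncytial_knots"],
                "grade": ["patchy", 1, None],
            }
        )
        obs = ls.read_observations_long(df)
        assert len(obs) == 2  # the missing grade is skipped
        profiles = {p.participant_id: p for p in ls.profiles_for_cohort(obs, scheme)}
        assert profiles["p1"].category_scores["MVM"] == 2

    def test_wide_reader_missing_cells_become_missing_lesions(self, scheme, small_cohort):
        obs = ls.read_observations_wide(small_cohort.table, scheme)
        profiles = {p.participant_id: p for p in ls.profiles_for_cohort(obs, scheme)}
        assert "karyorrhexis" in profiles["P010"].missing_lesions
        assert profiles["P001"].missing_lesions == ()

    def test_profiles_frame_shape(self, scheme, small_cohort):
        obs = ls.read_observations_wide(small_cohort.table, scheme)
        frame = ls.profiles_to_frame(ls.profiles_for_cohort(obs, scheme))
        assert len(frame) == 12
        assert frame["cumulative_score"].min() >= 0
        assert set(f"score_{c}" for c in CAPS) <= set(frame.columns)
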