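"""The TBV formula registry: Nadler, Lemmens-Bernstein, Gilcher."""

import math

import pytest
from hypothesis import given, strategies as st

from tbvtools import (
    ConfigurationError,
    PatientRecord,
    Sex,
    gilcher,
    lemmens_bernstein,
    nadler,
    profile_for,
    round_half_up,
)
from tbvtools.estimators import (
    DEFAULT_FORMULA_MATRIX,
    FormulaId,
    WeightBasis,
    estimate_all,
    resolve_formula,
)

MALE_AIBW_173_120 = 81.5595  # male-Devine adjusted IBW at 173 cm / 120 kg


@pytest.mark.parametrize(
    "sex, height, weight, rounded",
    [
        (Sex.MALE, 173.0, MALE_AIBW_173_120, 5113),
        (Sex.FEMALE, 173.0, MALE_AIBW_173_120, 4718),
    ],
)
def test_nadler_worked_example(sex, height, weight, rounded):
    assert round_half_up(nadler(sex, height, weight)) == rounded


def test_nadler_female_with_female_aibw():
    # direct evaluation of the female equation at the female-Devine AIBW
    assert nadler(Sex.FEMALE, 173.0, 78.1845) == pytest.approx(
        183.3 + 0.000356 * 173**3 + 33 * 78.1845, rel=1e-12
    )


def test_lemmens_bernstein_uses_unrounded_bmi():
    # 70*120/sqrt(BMI/22) with BMI = 40.0949... gives 6222.2; with the
    # display-rounded BMI of exactly 40 it would give 6229.6 instead.
    tbv = lemmens_bernstein(173.0, 120.0)
    assert round_half_up(tbv) == 6222
    assert tbv == pytest.approx(6222.2, abs=0.05)
    rounded_bmi_value = 70 * 120 / math.sqrt(40.0 / 22.0)
    assert abs(tbv - rounded_bmi_value) > 5


def test_lemmens_bernstein_hand_arithmetic():
    assert lemmens_bernstein(160.0, 76.8) == pytest.approx(
        70 * 76.8 / math.sqrt(30.0 / 22.0), rel=1e-12
    )


@given(weight=st.floats(min_value=40, max_value=130))
def test_lemmens_bernstein_at_reference_bmi_is_70_per_kg(weight):
    height = 100.0 * math.sqrt(weight / 22.0)
    assert lemmens_bernstein(height, weight) == pytest.approx(70 * weight,
                                                             rel=1e-9)


@given(
    height=st.floats(min_value=140, max_value=200),
    bmi=st.floats(min_value=22.01, max_value=60),
)
def test_lemmens_bernstein_below_70_per_kg_above_reference_bmi(height, bmi):
    weight = bmi * (height / 100.0) ** 2
    assert lemmens_bernstein(height, weight) < 70 * weight


@given(
    height=st.floats(min_value=140, max_value=200),
    weights=st.tuples(
        st.floats(min_value=40, max_value=240),
        st.floats(min_value=40, max_value=240),
    ),
)
def test_lemmens_bernstein_increasing_in_weight(height, weights):
    lo, hi = sorted(weights)
    if hi - lo > 1e-6:
        assert lemmens_bernstein(height, lo) < lemmens_bernstein(height, hi)


@pytest.mark.parametrize(
    "weight, constant, rounded",
    [
        (MALE_AIBW_173_120, 60, 4894),
        (MALE_AIBW_173_120, 55, 4486),
        (100.0, 60, 6000),
    ],
)
def test_gilcher_worked_examples(weight, constant, rounded):
    assert round_half_up(gilcher(weight, constant)) == rounded


@given(
    sex=st.sampled_from(list(Sex)),
    height=st.floats(min_value=120, max_value=220),
    w1=st.floats(min_value=40, max_value=200),
    w2=st.floats(min_value=40, max_value=200),
)
def test_nadler_strictly_increasing_in_weight_and_height(sex, height, w1, w2):
    lo, hi = sorted((w1, w2))
    if hi - lo > 1e-9:
        assert nadler(sex, height, lo) < nadler(sex, height, hi)
    if height + 5 < 250:
        assert nadler(sex, height, lo) < nadler(sex, height + 5, lo)


def test_gilcher_aibw_below_abw_for_obese(small_cohort):
    for rec in small_cohort:
        prof = profile_for(rec)
        assert prof.aibw_kg < rec.weight_kg  # all fixture patients are obese
        assert gilcher(prof.aibw_kg, 60) < gilcher(rec.weight_kg, 60)


class TestEstimateAll:
    def test_default_matrix_female(self):
        rec = PatientRecord(id="F", sex=Sex.FEMALE, height_cm=165.0,
                            weight_kg=90.0)
        est = estimate_all(rec, profile_for(rec))
        assert set(est.estimates) == {
            (FormulaId.NADLER_FEMALE, WeightBasis.AIBW),
            (FormulaId.LEMMENS_BERNSTEIN, WeightBasis.ABW),
            (FormulaId.GILCHER_55, WeightBasis.ABW),
            (FormulaId.GILCHER_55, WeightBasis.AIBW),
        }

    def test_default_matrix_male(self, male_patient):
        est = estimate_all(male_patient, profile_for(male_patient))
        assert set(est.estimates) == {
            (FormulaId.NADLER_MALE, WeightBasis.AIBW),
            (FormulaId.LEMMENS_BERNSTEIN, WeightBasis.ABW),
            (FormulaId.GILCHER_60, WeightBasis.ABW),
            (FormulaId.GILCHER_60, WeightBasis.AIBW),
        }
        assert len(est) == len(DEFAULT_FORMULA_MATRIX)

    def test_empty_matrix_gives_empty_set(self, male_patient):
        est = estimate_all(male_patient, profile_for(male_patient), ())
        assert len(est) == 0

    def test_unknown_formula_rejected(self, male_patient):
        with pytest.raises(ConfigurationError):
            estimate_all(male_patient, profile_for(male_patient),
                         [("feldschuh", WeightBasis.ABW)])

    def test_lemmens_bernstein_aibw_basis_rejected(self, male_patient):
        with pytest.raises(ConfigurationError):
            estimate_all(male_patient, profile_for(male_patient),
                         [("lemmens_bernstein", WeightBasis.AIBW)])


def test_resolve_formula_by_sex_and_explicit_override():
    assert resolve_formula("nadler", Sex.MALE) is FormulaId.NADLER_MALE
    assert resolve_formula("gilcher", Sex.FEMALE) is FormulaId.GILCHER_55
    assert resolve_formula("gilcher_60", Sex.FEMALE) is FormulaId.GILCHER_60
    with pytest.raises(ConfigurationError):
        resolve_formula("dubois", Sex.MALE)
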