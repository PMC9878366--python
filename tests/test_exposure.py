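import math

import pytest

from tatexpo.colors import ColorScheme, UnknownColorError
from tatexpo.exposure import (
    CREDIT_CARD_AREA_CM2,
    CoverageError,
    ExposureEstimate,
    SelfReport,
    ShapeError,
    TattooRecord,
    convert_scheme_report,
    convert_unit_report,
    coverage_weighted,
    shape_area,
    validation_exposure,
)


class TestShapeArea:
    @pytest.mark.parametrize(
        "components, expected",
        [
            ([("circle", (5,))], math.pi * 25),
            ([("square", (3,))], 9.0),
            ([("rectangle", (4, 2)), ("circle", (1,))], 8.0 + math.pi),
            ([("oval", (3, 2))], math.pi * 6),
            ([], 0.0),
        ],
    )
    def test_component_areas_are_additive(self, components, expected):
        assert shape_area(components) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "components",
        [
            [("triangle", (3,))],
            [("circle", (-1,))],
            [("rectangle", (4,))],
            [("square", (1, 2))],
        ],
    )
    def test_malformed_components_rejected(self, components):
        with pytest.raises(ShapeError):
            shape_area(components)


class TestColorScheme:
    def test_gray_and_gray_wash_merge_into_black_gray(self):
        scheme = ColorScheme()
        assert scheme.canonical("gray") == "black_gray"
        assert scheme.canonical("gray_wash") == "black_gray"
        assert scheme.canonical("black") == "black_gray"

    def test_white_counts_as_colored(self):
        assert ColorScheme.is_colored("white")
        assert not ColorScheme.is_colored("black_gray")

    def test_unknown_label_is_named_error(self):
        with pytest.raises(UnknownColorError):
            ColorScheme().canonical("chartreuse")


class TestConvertUnitReport:
    def test_credit_card_constant(self):
        rep = SelfReport("p", "credit_card", entries=(("left_arm", "black", 10.0),))
        est = convert_unit_report(rep, CREDIT_CARD_AREA_CM2)
        assert est.total_area_cm2 == pytest.approx(300.0)

    def test_hand_surface_product(self):
        rep = SelfReport("p", "hand_surface", entries=(("left_arm", "black", 3.5),))
        est = convert_unit_report(rep, 162.0)
        assert est.total_area_cm2 == pytest.approx(567.0)

    def test_empty_report_has_undefined_coverage(self):
        est = convert_unit_report(SelfReport("p", "credit_card"), 30.0)
        assert est.total_area_cm2 == 0.0
        assert est.coverage_fraction is None

    def test_colors_aggregate_through_scheme(self):
        rep = SelfReport(
            "p",
            "credit_card",
            entries=(
                ("left_arm", "black", 1.0),
                ("left_arm", "gray", 1.0),
                ("right_arm", "red", 2.0),
            ),
        )
        est = convert_unit_report(rep, 30.0)
        assert est.per_color_area_cm2["black_gray"] == pytest.approx(60.0)
        assert est.per_color_area_cm2["red"] == pytest.approx(60.0)
        assert est.per_part_area_cm2["left_arm"] == pytest.approx(60.0)

    def test_per_entry_coverage_is_area_weighted(self):
        rep = SelfReport(
            "p",
            "credit_card",
            entries=(("left_arm", "black", 1.0), ("right_arm", "black", 1.0)),
            coverage_entries=(("left_arm", 50), ("right_arm", 100)),
        )
        est = convert_unit_report(rep, 30.0)
        assert est.coverage_fraction == pytest.approx(0.75)

    def test_unknown_color_names_offending_label(self):
        rep = SelfReport("p", "credit_card", entries=(("left_arm", "plaid", 1.0),))
        with pytest.raises(UnknownColorError, match="plaid"):
            convert_unit_report(rep, 30.0)


class TestConvertSchemeReport:
    PART_AREAS = {"left_arm": 1433.4, "right_leg": 2866.8}

    def test_scenario_fraction_times_part_area(self):
        rep = SelfReport(
            "p",
            "body_schemes",
            entries=(("left_arm", "black", 1.0),),
            scenario_entries=(("left_arm", 25),),
        )
        est = convert_scheme_report(rep, self.PART_AREAS)
        assert est.total_area_cm2 == pytest.approx(1433.4 * 0.25)
        assert est.total_area_cm2 == pytest.approx(358.35)

    def test_identity_chain_full_coverage(self):
        rep = SelfReport(
            "p",
            "body_schemes",
            entries=(("whole", "black", 1.0),),
            scenario_entries=(("whole", 100),),
        )
        est = convert_scheme_report(rep, {"whole": 15930.0})
        assert est.total_area_cm2 == pytest.approx(15930.0)

    def test_color_likert_proportion(self):
        rep = SelfReport(
            "p",
            "body_schemes",
            entries=(("left_arm", "black", 0.5), ("left_arm", "red", 0.5)),
            scenario_entries=(("left_arm", 10),),
        )
        est = convert_scheme_report(rep, self.PART_AREAS)
        # 10% scenario split equally: each color gets 0.05 × part area
        assert est.per_color_area_cm2["black_gray"] == pytest.approx(0.05 * 1433.4)
        assert est.per_color_area_cm2["red"] == pytest.approx(0.05 * 1433.4)

    def test_likert_weights_are_normalized_within_part(self):
        rep = SelfReport(
            "p",
            "body_schemes",
            entries=(("left_arm", "black", 0.75), ("left_arm", "red", 0.75)),
            scenario_entries=(("left_arm", 50),),
        )
        est = convert_scheme_report(rep, self.PART_AREAS)
        assert est.total_area_cm2 == pytest.approx(1433.4 * 0.5)
        assert est.per_color_area_cm2["red"] == pytest.approx(1433.4 * 0.25)

    def test_missing_part_area_is_error(self):
        rep = SelfReport(
            "p", "body_schemes", scenario_entries=(("torso", 25),)
        )
        with pytest.raises(KeyError):
            convert_scheme_report(rep, self.PART_AREAS)


class TestCoverageWeighted:
    @pytest.mark.parametrize(
        "areas, props, denom, expected",
        [
            ([100, 100], [0.5, 1.0], 200, 0.75),
            ([300], [0.25], 300, 0.25),
            ([50, 150, 10], [1.0, 1.0, 1.0], 210, 1.0),
        ],
    )
    def test_weighted_mean(self, areas, props, denom, expected):
        assert coverage_weighted(areas, props, denom) == pytest.approx(expected)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(CoverageError):
            coverage_weighted([1.0], [0.5], 0.0)

    def test_bounded_by_extreme_props_when_denominator_is_total(self):
        areas = [12.0, 55.0, 7.0, 140.0]
        props = [0.1, 0.5, 0.75, 0.25]
        cov = coverage_weighted(areas, props, sum(areas))
        assert min(props) <= cov <= max(props)


class TestValidationExposure:
    def test_single_tattoo_chain(self):
        rec = TattooRecord(
            "p", "t1", "left_arm", (("circle", (5.0,)),), 50, {"black_gray": 1.0}
        )
        est = validation_exposure([rec])
        assert est.total_area_cm2 == pytest.approx(math.pi * 25)
        assert est.coverage_fraction == pytest.approx(0.5)
        assert est.per_color_area_cm2["black_gray"] == pytest.approx(math.pi * 25)

    def test_equal_area_coverage_average(self):
        recs = [
            TattooRecord("p", "t1", "left_arm", (("square", (10.0,)),), 25, {"black": 1.0}),
            TattooRecord("p", "t2", "right_arm", (("square", (10.0,)),), 75, {"black": 1.0}),
        ]
        assert validation_exposure(recs).coverage_fraction == pytest.approx(0.5)

    def test_proportional_color_split(self):
        rec = TattooRecord(
            "p",
            "t1",
            "left_arm",
            (("rectangle", (10.0, 5.0)),),
            100,
            {"black_gray": 0.6, "red": 0.4},
        )
        est = validation_exposure([rec])
        assert est.per_color_area_cm2["black_gray"] == pytest.approx(30.0)
        assert est.per_color_area_cm2["red"] == pytest.approx(20.0)

    def test_empty_record_list(self):
        est = validation_exposure([])
        assert est.total_area_cm2 == 0.0
        assert est.coverage_fraction is None

    def test_mixed_participants_rejected(self):
        recs = [
            TattooRecord("p1", "t1", "left_arm", (("square", (2.0,)),), 50, {"black": 1.0}),
            TattooRecord("p2", "t2", "left_arm", (("square", (2.0,)),), 50, {"black": 1.0}),
        ]
        with pytest.raises(ValueError):
            validation_exposure(recs)


class TestEstimateInvariants:
    def test_color_sum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ExposureEstimate("p", 100.0, {"red": 50.0}, {"left_arm": 100.0}, 0.5)

    def test_part_sum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ExposureEstimate("p", 100.0, {"red": 100.0}, {"left_arm": 80.0}, 0.5)

    def test_coverage_bounds(self):
        with pytest.raises(ValueError):
            ExposureEstimate("p", 10.0, {"red": 10.0}, {"left_arm": 10.0}, 1.5)
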