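"""Convert self-reports in all three measurement-unit dialects into cm².

The same person answers three questionnaire variants: counting hand
surfaces, counting 30 cm² credit cards, or picking per-body-part coverage
scenarios plus per-color Likert proportions. All three end in the same
ExposureEstimate container (total, per color, per part, coverage).
"""

from tatexpo import (
    CREDIT_CARD_AREA_CM2,
    ParticipantProfile,
    SelfReport,
    body_part_areas,
    convert_scheme_report,
    convert_unit_report,
    hand_unit_area,
)

profile = ParticipantProfile("demo", "female", 165.0, 60.0, 18.0, 9.0)

hand = SelfReport(
    "demo",
    "hand_surface",
    entries=(("left_arm", "black", 2.0), ("left_arm", "red", 0.5)),
    coverage_entries=(("left_arm", 75),),
)
card = SelfReport(
    "demo",
    "credit_card",
    entries=(("left_arm", "black", 10.0), ("left_arm", "red", 2.5)),
    coverage_entries=(("left_arm", 75),),
)
schemes = SelfReport(
    "demo",
    "body_schemes",
    entries=(("left_arm", "black", 0.75), ("left_arm", "red", 0.25)),
    scenario_entries=(("left_arm", 25),),
    coverage_entries=(("left_arm", 75),),
)

for report, est in [
    (hand, convert_unit_report(hand, hand_unit_area(profile))),
    (card, convert_unit_report(card, CREDIT_CARD_AREA_CM2)),
    (schemes, convert_scheme_report(schemes, body_part_areas(profile))),
]:
    print(f"{report.dialect:13s} total {est.total_area_cm2:7.1f} cm^2  "
          f"black/gray {est.black_gray_area_cm2():7.1f}  "
          f"colored {est.colored_area_cm2():6.1f}  "
          f"coverage {est.coverage_fraction:.2f}")

# The hand unit is this person's measured 18 x 9 cm hand (162 cm^2), so
# 2.5 hands ≈ 405 cm^2; 12.5 credit cards ≈ 375 cm^2; and "25 % of the
# left arm" ≈ 358 cm^2 — three dialects for the same underlying tattoos.
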