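"""Derive total and per-body-part skin area from anthropometrics.

Total body surface area (BSA) comes from sex-stratified power laws of
weight and height; per-part areas follow from the rule-of-nines partition.
These part areas are the denominators that turn body-scheme categories
("25 % of my forearm is tattooed") into absolute cm².
"""

from tatexpo import BodyPartition, ParticipantProfile, body_part_areas, bsa_schlich

profile = ParticipantProfile(
    participant_id="demo",
    sex="female",
    height_cm=165.0,
    weight_kg=60.0,
    hand_length_cm=18.0,
    hand_width_cm=9.0,
)

bsa_m2 = bsa_schlich(profile.sex, profile.weight_kg, profile.height_cm)
print(f"total body surface area: {bsa_m2:.3f} m^2")

print("\nper-body-part skin area (rule of nines):")
for part, area in body_part_areas(profile, BodyPartition.default()).items():
    print(f"  {part:16s} {area:8.1f} cm^2")

# A 1.59 m^2 adult has ~1433 cm^2 of skin on the head/neck (9 % of BSA);
# a "25 % tattooed" body-scheme answer for that part therefore means ~358 cm^2.
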