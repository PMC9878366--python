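import numpy as np
import pytest

from tatexpo import (
    BiasModel,
    CohortSpec,
    ParticipantProfile,
    StudyDataset,
    apply_reporting_bias,
    simulate_cohort,
)


@pytest.fixture
def profile():
    return ParticipantProfile(
        participant_id="p1",
        sex="female",
        height_cm=165.0,
        weight_kg=60.0,
        hand_length_cm=18.0,
        hand_width_cm=9.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """60 participants with true tattoo records, fixed seed."""
    spec = CohortSpec(n_participants=60, seed=123)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def null_bias_dataset(small_cohort):
    """Same cohort self-reported in all three dialects with identity bias."""
    participants, records = small_cohort
    reports = []
    for i, dialect in enumerate(("hand_surface", "credit_card", "body_schemes")):
        subset = participants[i::3]
        reports.extend(
            apply_reporting_bias(subset, records, BiasModel.null(), dialect, seed=99)
        )
    return StudyDataset(
        participants={p.participant_id: p for p in participants},
        self_reports=reports,
        validation_records=records,
    )


@pytest.fixture(scope="session")
def disk_image():
    """Black disk of radius 50 px on white, 200×200, scale 10 px/cm."""
    yy, xx = np.mgrid[0:200, 0:200]
    img = np.full((200, 200), 255, dtype=np.uint8)
    img[(xx - 100) ** 2 + (yy - 100) ** 2 <= 50**2] = 10
    return img
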