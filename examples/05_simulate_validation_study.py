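"""Simulate a full validation study and recover the reporting bias.

Generates a synthetic cohort, produces biased self-reports in each
questionnaire dialect (median 2x overestimation at the median tattoo size,
stronger for small tattoos), runs the per-arm agreement analysis, and then
re-estimates the bias parameters from the paired totals.
"""

import numpy as np

from tatexpo import (
    BiasModel,
    CohortSpec,
    StudyDataset,
    apply_reporting_bias,
    convert_self_report,
    recover_bias,
    run_validation_analysis,
    simulate_cohort,
    validation_exposure,
)

spec = CohortSpec(n_participants=300, seed=1)
participants, records = simulate_cohort(spec)
profiles = {p.participant_id: p for p in participants}
print(f"cohort: {len(participants)} participants, {len(records)} tattoos")

# one exclusive questionnaire arm per participant, as in a validation study
reports = []
for i, dialect in enumerate(("hand_surface", "credit_card", "body_schemes")):
    reports.extend(
        apply_reporting_bias(
            participants[i::3], records, BiasModel.default_study(), dialect, seed=2
        )
    )
dataset = StudyDataset(profiles, reports, records)
bundle = run_validation_analysis(dataset)

print("\narm            outcome      n   self-mean  valid-mean      p   AA-ICC  CA-ICC   tau")
for row in bundle.summary_frame().itertuples(index=False):
    if row.outcome != "total_size":
        continue
    print(
        f"{row.arm:14s} {row.outcome:10s} {row.n:4d}  {row.mean_self:9.0f} "
        f"{row.mean_validation:11.0f} {row.p_value:7.3f}  {row.aa_icc:6.2f} "
        f"{row.ca_icc:7.2f} {row.kendall_tau:6.2f}"
    )

# bias recovery on the hand-surface arm's paired totals
by_pid: dict = {}
for rec in records:
    by_pid.setdefault(rec.participant_id, []).append(rec)
hand_reports = [r for r in reports if r.dialect == "hand_surface"]
selfs = {
    r.participant_id: convert_self_report(r, profiles[r.participant_id]).total_area_cm2
    for r in hand_reports
}
valid = {pid: validation_exposure(rs).total_area_cm2 for pid, rs in by_pid.items()}
fit = recover_bias(selfs, valid)
print(
    f"\nrecovered bias: median factor {fit.b0:.2f} at {fit.reference_size_cm2:.0f} cm^2, "
    f"size exponent gamma = {fit.gamma:.2f} ({fit.n_used} pairs, {fit.n_excluded} excluded)"
)

# Self-assessed means roughly double the validation means, absolute
# agreement drops below consistency, and the regression recovers a ~2x
# median factor that shrinks with tattoo size (gamma > 0).
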