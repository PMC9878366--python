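import io as _io
import math

import numpy as np
import pytest

from tatexpo import io as tio
from tatexpo.anthropometry import body_part_areas, hand_unit_area
from tatexpo.cohort import (
    BiasModel,
    CohortSpec,
    InsufficientPairsError,
    InvalidSpecError,
    apply_reporting_bias,
    recover_bias,
    simulate_cohort,
    true_part_color_areas,
)
from tatexpo.exposure import validation_exposure
from tatexpo.pipeline import convert_self_report


def _totals(participants, records, reports):
    profs = {p.participant_id: p for p in participants}
    by_pid = {}
    for r in records:
        by_pid.setdefault(r.participant_id, []).append(r)
    valid = {pid: validation_exposure(rs).total_area_cm2 for pid, rs in by_pid.items()}
    selfs = {
        rep.participant_id: convert_self_report(rep, profs[rep.participant_id]).total_area_cm2
        for rep in reports
    }
    return selfs, valid


class TestSimulateCohort:
    def test_same_spec_and_seed_is_byte_identical(self):
        spec = CohortSpec(n_participants=25, seed=7)
        out = []
        for _ in range(2):
            participants, records = simulate_cohort(spec)
            buf_p, buf_r = _io.StringIO(), _io.StringIO()
            tio.write_participants(buf_p, participants)
            tio.write_validation_records(buf_r, records)
            out.append(buf_p.getvalue() + buf_r.getvalue())
        assert out[0] == out[1]

    def test_lognormal_median_recovered(self):
        # enough participants for ~2000 tattoos; log-normal(μ=4) median is e⁴
        spec = CohortSpec(n_participants=340, seed=21, size_log_mu=4.0, size_log_sigma=1.0)
        _, records = simulate_cohort(spec)
        areas = [r.area_cm2 for r in records]
        assert len(areas) > 1500
        assert float(np.median(areas)) == pytest.approx(math.e**4, rel=0.05)

    def test_degenerate_placement_puts_all_tattoos_on_one_part(self):
        probs = {"posterior_trunk": 1.0}
        spec = CohortSpec(n_participants=15, seed=3, placement_probs=probs)
        _, records = simulate_cohort(spec)
        assert records and all(r.body_part == "posterior_trunk" for r in records)

    def test_spec_loads_from_yaml_config(self, tmp_path):
        cfg = tmp_path / "spec.yaml"
        cfg.write_text(
            "n_participants: 5\nseed: 9\n"
            "coverage_probs: {10: 0.2, 25: 0.2, 50: 0.2, 75: 0.2, 100: 0.2}\n"
        )
        spec = CohortSpec.from_yaml(cfg)
        assert spec.n_participants == 5
        assert spec.coverage_probs[100] == 0.2
        participants, _ = simulate_cohort(spec)
        assert len(participants) == 5
        cfg.write_text("not_a_field: 1\n")
        with pytest.raises(InvalidSpecError):
            CohortSpec.from_yaml(cfg)

    def test_invalid_spec_rejected_before_sampling(self):
        with pytest.raises(InvalidSpecError):
            CohortSpec(palette_probs={"black": 0.5, "colored": 0.4}).validate()
        with pytest.raises(InvalidSpecError):
            CohortSpec(size_log_sigma=-1).validate()

    def test_tattoos_fit_on_their_body_part(self, small_cohort):
        participants, records = small_cohort
        profs = {p.participant_id: p for p in participants}
        used: dict = {}
        for rec in records:
            key = (rec.participant_id, rec.body_part)
            used[key] = used.get(key, 0.0) + rec.area_cm2
        for (pid, part), area in used.items():
            assert area <= body_part_areas(profs[pid])[part] + 1e-6

    def test_records_satisfy_ingest_invariants(self, small_cohort):
        _, records = small_cohort
        for rec in records:
            assert abs(math.fsum(rec.color_shares.values()) - 1.0) <= 1e-6
            assert rec.coverage_category in (10, 25, 50, 75, 100)
            assert rec.area_cm2 > 0


class TestApplyReportingBias:
    def test_null_bias_unquantized_equals_truth_exactly(self, small_cohort):
        participants, records = small_cohort
        for dialect in ("hand_surface", "credit_card"):
            reports = apply_reporting_bias(
                participants, records, BiasModel.null(), dialect, seed=5, quantize=False
            )
            selfs, valid = _totals(participants, records, reports)
            for pid, v in valid.items():
                assert selfs[pid] == pytest.approx(v, rel=1e-9)

    def test_null_bias_quantization_bound_per_entry(self, small_cohort):
        """Unit-dialect reports differ from truth by at most half a unit per entry."""
        participants, records = small_cohort
        profs = {p.participant_id: p for p in participants}
        by_pid: dict = {}
        for r in records:
            by_pid.setdefault(r.participant_id, []).append(r)
        model = BiasModel.null()
        for dialect in ("hand_surface", "credit_card"):
            reports = apply_reporting_bias(participants, records, model, dialect, seed=6)
            for rep in reports:
                prof = profs[rep.participant_id]
                unit = hand_unit_area(prof, 166.25) if dialect == "hand_surface" else 30.0
                cells, _ = true_part_color_areas(by_pid.get(rep.participant_id, []))
                truth: dict = {}
                for (part, color), area in cells.items():
                    truth[(part, color)] = truth.get((part, color), 0.0) + area
                reported = {(p, c): m * unit for p, c, m in rep.entries}
                for key in set(truth) | set(reported):
                    diff = abs(reported.get(key, 0.0) - truth.get(key, 0.0))
                    assert diff <= 0.5 * unit + 1e-9

    def test_null_bias_scheme_bound_per_part(self, small_cohort):
        """Scheme reports differ from truth by at most one category gap per part."""
        participants, records = small_cohort
        profs = {p.participant_id: p for p in participants}
        by_pid: dict = {}
        for r in records:
            by_pid.setdefault(r.participant_id, []).append(r)
        levels = (0.0, 0.1, 0.25, 0.5, 0.75, 1.0)
        reports = apply_reporting_bias(
            participants, records, BiasModel.null(), "body_schemes", seed=6
        )
        for rep in reports:
            part_areas = body_part_areas(profs[rep.participant_id])
            cells, _ = true_part_color_areas(by_pid.get(rep.participant_id, []))
            true_parts: dict = {}
            for (part, _), area in cells.items():
                true_parts[part] = true_parts.get(part, 0.0) + area
            reported = {p: 0.01 * cat * part_areas[p] for p, cat in rep.scenario_entries}
            for part in set(true_parts) | set(reported):
                frac = min(true_parts.get(part, 0.0) / part_areas[part], 1.0)
                lo = max(lv for lv in levels if lv <= frac)
                hi = min(lv for lv in levels if lv >= frac)
                gap = max(hi - lo, 1e-12)
                diff = abs(reported.get(part, 0.0) - true_parts.get(part, 0.0))
                assert diff <= gap * part_areas[part] + 1e-6

    def test_mean_overestimation_factor_near_two(self):
        """Median factor 2 with γ=0 → self/validation mean ratio ≈ 2 at n=500."""
        spec = CohortSpec(n_participants=500, seed=31)
        participants, records = simulate_cohort(spec)
        model = BiasModel(b0=2.0, gamma=0.0, sigma_b=0.3)
        reports = apply_reporting_bias(participants, records, model, "hand_surface", seed=32)
        selfs, valid = _totals(participants, records, reports)
        ratio = np.mean(list(selfs.values())) / np.mean(list(valid.values()))
        assert ratio == pytest.approx(2.0, rel=0.12)  # mean of a median-2 log-normal

    def test_size_dependent_bias_orders_quartile_factors(self):
        spec = CohortSpec(n_participants=400, seed=41)
        participants, records = simulate_cohort(spec)
        model = BiasModel(b0=2.0 * 49.0**0.4, gamma=0.4, sigma_b=0.3)
        reports = apply_reporting_bias(participants, records, model, "hand_surface", seed=42)
        selfs, valid = _totals(participants, records, reports)
        pids = sorted(valid)
        v = np.array([valid[p] for p in pids])
        s = np.array([selfs[p] for p in pids])
        q1, q3 = np.percentile(v, [25, 75])
        small = (s[v <= q1] / v[v <= q1]).mean()
        large = (s[v >= q3] / v[v >= q3]).mean()
        assert small > large

    def test_gray_misreported_as_black(self, small_cohort):
        participants, records = small_cohort
        model = BiasModel(gray_to_black_prob=1.0)
        reports = apply_reporting_bias(participants, records, model, "credit_card", seed=8)
        for rep in reports:
            assert all(color != "gray" for _, color, _ in rep.entries)


class TestRecoverBias:
    @staticmethod
    def _fit(model, n=500, seed=11, dialect="credit_card"):
        spec = CohortSpec(n_participants=n, seed=seed)
        participants, records = simulate_cohort(spec)
        reports = apply_reporting_bias(participants, records, model, dialect, seed=seed + 1)
        selfs, valid = _totals(participants, records, reports)
        return recover_bias(selfs, valid)

    def test_recovers_twofold_bias(self):
        fit = self._fit(BiasModel(b0=2.0, gamma=0.0, sigma_b=0.3))
        assert fit.b0 == pytest.approx(2.0, rel=0.10)
        assert abs(fit.gamma) <= 0.05

    def test_null_bias_recovery(self):
        fit = self._fit(BiasModel.null(), seed=5)
        assert fit.b0 == pytest.approx(1.0, rel=0.05)
        assert abs(fit.gamma) <= 0.05

    def test_invariant_to_participant_ordering(self):
        rng = np.random.default_rng(2)
        v = dict(enumerate(rng.lognormal(5, 1, 100)))
        s = {k: val * 2 * rng.lognormal(0, 0.2) for k, val in v.items()}
        a = recover_bias(s, v)
        shuffled = dict(reversed(list(s.items())))
        b = recover_bias(shuffled, v)
        assert a == b

    def test_too_few_pairs_is_named_error(self):
        with pytest.raises(InsufficientPairsError):
            recover_bias({"a": 1.0}, {"a": 2.0})
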