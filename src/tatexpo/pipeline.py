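"""End-to-end validation analysis: ingest, conversion, pairing, reporting.

For each questionnaire arm (measurement-unit dialect) and each outcome —
total tattooed area, black/gray area, colored area, coverage — the pipeline
pairs converted self-reports with validation measurements, runs the full
agreement battery, and collects the results, a cohort composition summary,
plot-ready Bland–Altman/rank series, and an exclusion log in a
:class:`ReportBundle`. Every input participant is accounted for either in a
result's n or in the exclusion log.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__ as _pkg_version
from .agreement import AgreementResult, PairedSample, compute_agreement, rank_series
from .anthropometry import (
    BodyPartition,
    DEFAULT_HAND_FALLBACK_CM2,
    ParticipantProfile,
    body_part_areas,
    hand_unit_area,
)
from .colors import ColorScheme, DEFAULT_COLOR_SCHEME
from .exposure import (
    CREDIT_CARD_AREA_CM2,
    DIALECTS,
    ExposureEstimate,
    SelfReport,
    TattooRecord,
    convert_scheme_report,
    convert_unit_report,
    validation_exposure,
)

OUTCOMES: tuple[str, ...] = ("total_size", "black_gray", "colored", "coverage")

_GRAY_RAW = ("gray", "grey", "gray_wash")
_BLACK_RAW = ("black", "black_gray")


class FunnelError(ValueError):
    """Completed count exceeds initiated count."""


@dataclass(frozen=True)
class StudyDataset:
    """Participants, one self-report each (exclusive arm), validation records."""

    participants: Mapping[str, ParticipantProfile]
    self_reports: Sequence[SelfReport]
    validation_records: Sequence[TattooRecord]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for rep in self.self_reports:
            if rep.participant_id in seen:
                raise ValueError(
                    f"participant {rep.participant_id} appears in more than one arm"
                )
            seen[rep.participant_id] = rep.dialect

    def reports_by_arm(self) -> dict[str, list[SelfReport]]:
        out: dict[str, list[SelfReport]] = {d: [] for d in DIALECTS}
        for rep in self.self_reports:
            out[rep.dialect].append(rep)
        return out

    def records_by_participant(self) -> dict[str, list[TattooRecord]]:
        out: dict[str, list[TattooRecord]] = {}
        for rec in self.validation_records:
            out.setdefault(rec.participant_id, []).append(rec)
        return out


@dataclass
class ReportBundle:
    """All outputs of one validation-analysis run."""

    results: dict[tuple[str, str], AgreementResult] = field(default_factory=dict)
    samples: dict[tuple[str, str], PairedSample] = field(default_factory=dict)
    exclusions: list[tuple[str, str, str]] = field(default_factory=list)  # pid, arm, reason
    skipped: list[tuple[str, str, str]] = field(default_factory=list)  # arm, outcome, reason
    cohort_summary: Optional[pd.DataFrame] = None
    n_input: int = 0

    def summary_frame(self) -> pd.DataFrame:
        """Agreement table: one row per arm × outcome (areas in cm², coverage %)."""
        rows = []
        for (arm, outcome), res in sorted(self.results.items()):
            rows.append(
                {
                    "arm": arm,
                    "outcome": outcome,
                    "n": res.n,
                    "mean_self": res.mean_x,
                    "sd_self": res.sd_x,
                    "median_self": res.median_x,
                    "q1_self": res.iqr_x[0],
                    "q3_self": res.iqr_x[1],
                    "mean_validation": res.mean_y,
                    "sd_validation": res.sd_y,
                    "median_validation": res.median_y,
                    "q1_validation": res.iqr_y[0],
                    "q3_validation": res.iqr_y[1],
                    "p_value": res.p_value,
                    "aa_icc": res.aa_icc,
                    "ca_icc": res.ca_icc,
                    "kendall_tau": res.kendall_tau,
                }
            )
        return pd.DataFrame(rows)

    def plot_frame(self) -> pd.DataFrame:
        """Long table of Bland–Altman points and paired ranks for plotting."""
        rows = []
        for (arm, outcome), sample in sorted(self.samples.items()):
            res = self.results[(arm, outcome)]
            rx, ry = rank_series(sample)
            ba = res.bland_altman
            for pid, x, y, m, d, r1, r2 in zip(
                sample.ids, sample.x, sample.y, ba.means, ba.diffs, rx, ry
            ):
                rows.append(
                    {
                        "arm": arm,
                        "outcome": outcome,
                        "participant_id": pid,
                        "self": x,
                        "validation": y,
                        "ba_mean": m,
                        "ba_diff": d,
                        "rank_self": r1,
                        "rank_validation": r2,
                        "bias": ba.bias,
                        "loa_lower": ba.loa_lower,
                        "loa_upper": ba.loa_upper,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir, seed: Optional[int] = None, config: Optional[dict] = None) -> None:
        """Write the bundle as a directory of CSV tables plus a run manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary_frame().to_csv(out / "agreement.csv", index=False)
        self.plot_frame().to_csv(out / "plot_series.csv", index=False)
        pd.DataFrame(self.exclusions, columns=["participant_id", "arm", "reason"]).to_csv(
            out / "exclusions.csv", index=False
        )
        pd.DataFrame(self.skipped, columns=["arm", "outcome", "reason"]).to_csv(
            out / "skipped.csv", index=False
        )
        if self.cohort_summary is not None:
            self.cohort_summary.to_csv(out / "cohort_summary.csv", index=False)
        cfg = config or {}
        manifest = {
            "seed": seed,
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "version": _pkg_version,
            "n_input": self.n_input,
            "n_results": len(self.results),
            "n_exclusions": len(self.exclusions),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def convert_self_report(
    report: SelfReport,
    profile: ParticipantProfile,
    partition: Optional[BodyPartition] = None,
    color_scheme: ColorScheme = DEFAULT_COLOR_SCHEME,
    hand_fallback_cm2: float = DEFAULT_HAND_FALLBACK_CM2,
) -> ExposureEstimate:
    """Dispatch a self-report to the conversion matching its dialect."""
    if report.dialect == "hand_surface":
        return convert_unit_report(
            report, hand_unit_area(profile, hand_fallback_cm2), color_scheme
        )
    if report.dialect == "credit_card":
        return convert_unit_report(report, CREDIT_CARD_AREA_CM2, color_scheme)
    return convert_scheme_report(report, body_part_areas(profile, partition), color_scheme)


def _outcome_value(est: ExposureEstimate, outcome: str) -> Optional[float]:
    if outcome == "total_size":
        return est.total_area_cm2
    if outcome == "black_gray":
        return est.black_gray_area_cm2()
    if outcome == "colored":
        return est.colored_area_cm2()
    if est.coverage_fraction is None:
        return None
    return est.coverage_fraction * 100.0  # coverage in percent


def run_validation_analysis(
    dataset: StudyDataset,
    partition: Optional[BodyPartition] = None,
    color_scheme: ColorScheme = DEFAULT_COLOR_SCHEME,
    hand_fallback_cm2: float = DEFAULT_HAND_FALLBACK_CM2,
    include_cohort_summary: bool = True,
) -> ReportBundle:
    """Run the full per-arm × per-outcome agreement analysis.

    Color outcomes are restricted to participants for whom *either* measure
    records that color group, so a missed color reduces agreement rather
    than sample size. Arms/outcomes with n < 3 are skipped with a logged
    reason, never silently dropped.
    """
    bundle = ReportBundle(n_input=len({r.participant_id for r in dataset.self_reports}))
    by_pid = dataset.records_by_participant()
    for arm, reports in dataset.reports_by_arm().items():
        pairs: dict[str, tuple[ExposureEstimate, ExposureEstimate]] = {}
        for rep in reports:
            pid = rep.participant_id
            profile = dataset.participants.get(pid)
            if profile is None:
                bundle.exclusions.append((pid, arm, "no participant profile"))
                continue
            if pid not in by_pid:
                bundle.exclusions.append((pid, arm, "no validation data"))
                continue
            try:
                self_est = convert_self_report(
                    rep, profile, partition, color_scheme, hand_fallback_cm2
                )
            except Exception as exc:  # conversion failure is an exclusion, not a crash
                bundle.exclusions.append((pid, arm, f"conversion failed: {exc}"))
                continue
            valid_est = validation_exposure(by_pid[pid], color_scheme)
            pairs[pid] = (self_est, valid_est)
        for outcome in OUTCOMES:
            x: dict[str, float] = {}
            y: dict[str, float] = {}
            for pid, (self_est, valid_est) in pairs.items():
                xv = _outcome_value(self_est, outcome)
                yv = _outcome_value(valid_est, outcome)
                if outcome in ("black_gray", "colored") and (xv or 0) <= 0 and (yv or 0) <= 0:
                    continue  # neither measure has this color group
                if xv is None or yv is None:
                    continue  # undefined coverage on one side
                x[pid] = xv
                y[pid] = yv
            if len(x) < 3:
                bundle.skipped.append((arm, outcome, f"n={len(x)} < 3"))
                continue
            sample = PairedSample.from_dicts(x, y)
            bundle.samples[(arm, outcome)] = sample
            bundle.results[(arm, outcome)] = compute_agreement(sample)
    if include_cohort_summary:
        bundle.cohort_summary = cohort_summary(dataset)
    return bundle


# --------------------------------------------------------------------------
# descriptive summaries


def largest_remainder_percent(counts: Sequence[int], total: int) -> list[int]:
    """Integer percentages of mutually exclusive counts that sum to 100.

    Hamilton (largest-remainder) apportionment: floor every share, then give
    the leftover points to the largest fractional remainders.
    """
    if total <= 0:
        return [0 for _ in counts]
    shares = [100.0 * c / total for c in counts]
    floors = [math.floor(s) for s in shares]
    leftover = 100 - sum(floors) if sum(counts) == total else 0
    order = sorted(range(len(counts)), key=lambda i: shares[i] - floors[i], reverse=True)
    out = list(floors)
    for i in order[:max(leftover, 0)]:
        out[i] += 1
    return out


def _participant_color_group(records: Sequence[TattooRecord]) -> str:
    has_gray = False
    for rec in records:
        for color, share in rec.color_shares.items():
            if share <= 0:
                continue
            if color in _GRAY_RAW:
                has_gray = True
            elif color not in _BLACK_RAW:
                return "colored"
    return "gray_wash" if has_gray else "black"


def cohort_summary(dataset: StudyDataset) -> pd.DataFrame:
    """Cohort composition counts, overall and by questionnaire arm.

    Color group is exclusive per participant (colored ≻ gray wash ≻ black;
    colored = any ink other than black/gray, white included) and its integer
    percentages are largest-remainder rounded so they sum to 100. Tattoo-age
    and expertise rows are multi-select: a participant contributes to every
    band/category present among their tattoos.
    """
    by_pid = dataset.records_by_participant()
    arm_of = {rep.participant_id: rep.dialect for rep in dataset.self_reports}
    pids = sorted(by_pid)
    arms = ["all", *DIALECTS]

    def members(arm: str) -> list[str]:
        if arm == "all":
            return pids
        return [p for p in pids if arm_of.get(p) == arm]

    rows = []
    groups = ("black", "gray_wash", "colored")
    group_of = {pid: _participant_color_group(by_pid[pid]) for pid in pids}
    for arm in arms:
        mem = members(arm)
        counts = [sum(1 for p in mem if group_of[p] == g) for g in groups]
        pcts = largest_remainder_percent(counts, len(mem))
        for g, c, pct in zip(groups, counts, pcts):
            rows.append({"section": "color", "category": g, "arm": arm, "n": c, "pct": pct})
    multiselect = {
        "tattoo_age": lambda recs: {r.age_band for r in recs if r.age_band},
        "expertise": lambda recs: {r.artist_expertise for r in recs if r.artist_expertise},
    }
    for section, extract in multiselect.items():
        cats = sorted({c for pid in pids for c in extract(by_pid[pid])})
        for arm in arms:
            mem = members(arm)
            for cat in cats:
                c = sum(1 for p in mem if cat in extract(by_pid[p]))
                pct = round(100.0 * c / len(mem)) if mem else 0
                rows.append(
                    {"section": section, "category": cat, "arm": arm, "n": c, "pct": pct}
                )
    for arm in arms:
        mem = members(arm)
        flags = {
            "any_foreign_tattoo": sum(
                1 for p in mem if any(r.country not in ("", "France") for r in by_pid[p])
            ),
            "any_complication": sum(1 for p in mem if any(r.complications for r in by_pid[p])),
        }
        for cat, c in flags.items():
            pct = round(100.0 * c / len(mem)) if mem else 0
            rows.append({"section": "flags", "category": cat, "arm": arm, "n": c, "pct": pct})
    return pd.DataFrame(rows)


def completion_summary(funnel: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Per-arm and overall completion percentages (one decimal place).

    ``funnel`` maps arm → (initiated, completed).
    """
    rows = []
    tot_init = tot_comp = 0
    for arm, (initiated, completed) in funnel.items():
        if completed > initiated:
            raise FunnelError(f"{arm}: completed {completed} > initiated {initiated}")
        if initiated < 0 or completed < 0:
            raise FunnelError(f"{arm}: negative funnel counts")
        tot_init += initiated
        tot_comp += completed
        rate = round(100.0 * completed / initiated, 1) if initiated else 0.0
        rows.append({"arm": arm, "initiated": initiated, "completed": completed, "pct": rate})
    overall = round(100.0 * tot_comp / tot_init, 1) if tot_init else 0.0
    rows.append({"arm": "overall", "initiated": tot_init, "completed": tot_comp, "pct": overall})
    return pd.DataFrame(rows)
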