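"""Delimited-text table dialects for participants, self-reports and tattoos.

All tables are plain CSV with a header row so synthetic fixtures double as
format documentation:

* participants: ``participant_id, sex, height_cm, weight_kg, hand_length_cm,
  hand_width_cm`` (hand columns empty when not measured);
* self-reports (long format): ``participant_id, dialect, entry_type,
  body_part, color, value`` where ``entry_type`` is ``color`` (unit count or
  Likert proportion), ``scenario`` (percent category, body schemes only) or
  ``coverage`` (percent category);
* validation records (one row per shape component): ``participant_id,
  tattoo_id, body_part, shape_kind, dim1_cm, dim2_cm, coverage_category,
  share_<raw color>..., age_band, expertise, country, complications``.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .anthropometry import ParticipantProfile
from .exposure import SHAPE_DIMS, SelfReport, TattooRecord


def write_participants(path, profiles: Sequence[ParticipantProfile]) -> None:
    rows = [
        {
            "participant_id": p.participant_id,
            "sex": p.sex,
            "height_cm": p.height_cm,
            "weight_kg": p.weight_kg,
            "hand_length_cm": p.hand_length_cm,
            "hand_width_cm": p.hand_width_cm,
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_participants(path) -> list[ParticipantProfile]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        hl = None if pd.isna(row.hand_length_cm) else float(row.hand_length_cm)
        hw = None if pd.isna(row.hand_width_cm) else float(row.hand_width_cm)
        out.append(
            ParticipantProfile(
                participant_id=str(row.participant_id),
                sex=str(row.sex),
                height_cm=float(row.height_cm),
                weight_kg=float(row.weight_kg),
                hand_length_cm=hl,
                hand_width_cm=hw,
            )
        )
    return out


def write_self_reports(path, reports: Sequence[SelfReport]) -> None:
    rows = []
    for rep in reports:
        for part, color, value in rep.entries:
            rows.append((rep.participant_id, rep.dialect, "color", part, color, value))
        for part, cat in rep.scenario_entries:
            rows.append((rep.participant_id, rep.dialect, "scenario", part, "", cat))
        for part, cat in rep.coverage_entries:
            rows.append((rep.participant_id, rep.dialect, "coverage", part, "", cat))
        if not rep.entries and not rep.scenario_entries and not rep.coverage_entries:
            rows.append((rep.participant_id, rep.dialect, "empty", "", "", 0))
    pd.DataFrame(
        rows,
        columns=["participant_id", "dialect", "entry_type", "body_part", "color", "value"],
    ).to_csv(path, index=False)


def read_self_reports(path) -> list[SelfReport]:
    df = pd.read_csv(path, keep_default_na=False)
    reports = []
    for (pid, dialect), grp in df.groupby(["participant_id", "dialect"], sort=True):
        entries, scen, cov = [], [], []
        for row in grp.itertuples(index=False):
            if row.entry_type == "color":
                entries.append((str(row.body_part), str(row.color), float(row.value)))
            elif row.entry_type == "scenario":
                scen.append((str(row.body_part), int(float(row.value))))
            elif row.entry_type == "coverage":
                cov.append((str(row.body_part), int(float(row.value))))
            elif row.entry_type != "empty":
                raise ValueError(f"unknown entry_type {row.entry_type!r} in {path}")
        reports.append(
            SelfReport(
                participant_id=str(pid),
                dialect=str(dialect),
                entries=tuple(entries),
                coverage_entries=tuple(cov),
                scenario_entries=tuple(scen),
            )
        )
    return reports


def write_validation_records(path, records: Sequence[TattooRecord]) -> None:
    colors = sorted({c for rec in records for c in rec.color_shares})
    rows = []
    for rec in records:
        for kind, dims in rec.shape_components:
            row = {
                "participant_id": rec.participant_id,
                "tattoo_id": rec.tattoo_id,
                "body_part": rec.body_part,
                "shape_kind": kind,
                "dim1_cm": dims[0],
                "dim2_cm": dims[1] if len(dims) > 1 else "",
                "coverage_category": rec.coverage_category,
            }
            for c in colors:
                row[f"share_{c}"] = rec.color_shares.get(c, 0.0)
            row.update(
                age_band=rec.age_band,
                expertise=rec.artist_expertise,
                country=rec.country,
                complications=int(rec.complications),
            )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_validation_records(path) -> list[TattooRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    share_cols = [c for c in df.columns if c.startswith("share_")]
    records = []
    for (pid, tid), grp in df.groupby(["participant_id", "tattoo_id"], sort=True):
        components = []
        for row in grp.itertuples(index=False):
            kind = str(row.shape_kind)
            dims = [float(row.dim1_cm)]
            if SHAPE_DIMS.get(kind, 1) > 1:
                dims.append(float(row.dim2_cm))
            components.append((kind, tuple(dims)))
        first = grp.iloc[0]
        shares = {
            c.removeprefix("share_"): float(first[c])
            for c in share_cols
            if float(first[c]) > 0
        }
        records.append(
            TattooRecord(
                participant_id=str(pid),
                tattoo_id=str(tid),
                body_part=str(first["body_part"]),
                shape_components=tuple(components),
                coverage_category=int(first["coverage_category"]),
                color_shares=shares,
                age_band=str(first["age_band"]),
                artist_expertise=str(first["expertise"]),
                country=str(first["country"]),
                complications=bool(int(first["complications"])),
            )
        )
    return records
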