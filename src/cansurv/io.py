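"""CSV dialects for registry records and aggregated survival series.

Survival series CSV (NORDCAN-style export)
    columns: country, sex, site, period_start, period_end, measure,
    estimate_pct, ci_low, ci_high, mode. Periods are half-open
    ``[start, end)`` calendar years; estimates are percent and may exceed
    100. Leading ``#`` comment lines (e.g. an embedded config hash) are
    ignored on read.

Records CSV
    one row per individual: id, sex, country, age_at_diagnosis,
    diagnosis_date, follow_up_time, event, true_net_event.

Both formats round-trip losslessly through their reader/writer pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .relsurv import SurvivalEstimate, SurvivalSeries, Z95
from .synthetic import IndividualRecord
from .lifetables import read_life_table, write_life_table  # noqa: F401

SERIES_COLUMNS = ["country", "sex", "site", "period_start", "period_end",
                  "measure", "estimate_pct", "ci_low", "ci_high", "mode"]
RECORD_COLUMNS = ["id", "sex", "country", "age_at_diagnosis",
                  "diagnosis_date", "follow_up_time", "event",
                  "true_net_event"]


def series_to_frame(series_list: list[SurvivalSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for p in s.points:
            rows.append({
                "country": s.country, "sex": s.sex, "site": s.site,
                "period_start": p.period[0], "period_end": p.period[1],
                "measure": s.measure, "estimate_pct": p.estimate,
                "ci_low": p.ci[0], "ci_high": p.ci[1], "mode": p.mode,
            })
    return pd.DataFrame(rows, columns=SERIES_COLUMNS)


def write_series_csv(series_list: list[SurvivalSeries], path,
                     header_comment: str | None = None) -> None:
    df = series_to_frame(series_list)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def frame_to_series(df: pd.DataFrame) -> list[SurvivalSeries]:
    out = []
    keys = ["country", "sex", "site", "measure"]
    for (country, sex, site, measure), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("period_start")
        points = []
        for _, row in grp.iterrows():
            a, b = float(row.period_start), float(row.period_end)
            mid = 0.5 * (a + b - 1)
            half = 0.5 * (float(row.ci_high) - float(row.ci_low))
            points.append(SurvivalEstimate(
                estimate=float(row.estimate_pct),
                variance=(half / Z95) ** 2,
                ci=(float(row.ci_low), float(row.ci_high)),
                n_contributing=0,
                period=(a, b), midpoint=mid, mode=str(row["mode"]),
            ))
        out.append(SurvivalSeries(country=str(country), sex=str(sex),
                                  site=str(site), measure=str(measure),
                                  points=points))
    return out


def read_series_csv(path) -> list[SurvivalSeries]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"series CSV missing columns: {missing}")
    bad = df.index[df["period_end"] <= df["period_start"]].tolist()
    if bad:
        raise ValueError(
            f"malformed period (end <= start) at row(s) {bad}"
        )
    neg = df.index[df["estimate_pct"] < 0].tolist()
    if neg:
        raise ValueError(f"negative survival estimate at row(s) {neg}")
    return frame_to_series(df)


def write_records_csv(records: list[IndividualRecord], path,
                      header_comment: str | None = None) -> None:
    df = pd.DataFrame([
        {
            "id": r.id, "sex": r.sex, "country": r.country,
            "age_at_diagnosis": r.age_at_diagnosis,
            "diagnosis_date": r.diagnosis_date,
            "follow_up_time": r.follow_up_time,
            "event": r.event, "true_net_event": r.true_net_event,
        }
        for r in records
    ], columns=RECORD_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_records_csv(path) -> list[IndividualRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(IndividualRecord(
                id=int(row.id), sex=str(row.sex), country=str(row.country),
                age_at_diagnosis=float(row.age_at_diagnosis),
                diagnosis_date=float(row.diagnosis_date),
                follow_up_time=float(row.follow_up_time),
                event=str(row.event),
                true_net_event=bool(row.true_net_event),
            ))
        except (ValueError, TypeError) as err:
            raise ValueError(f"invalid record at row {i}: {err}") from err
    return records
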