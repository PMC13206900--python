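"""CSV interchange formats and cohort directory layout.

The documented dialects stand in for proprietary device exports:

* ``eda.csv`` — ``timestamp`` (ISO-8601 UTC, 4 Hz), ``eda_us``,
  ``missing`` (0/1; missing samples have an empty value);
* ``minutes.csv`` — ``minute_start``, ``pulse_rate``, ``prv_ms``,
  ``resp_rate``, ``state`` (asleep / awake_in_bed / out_of_bed),
  ``missing``;
* ``diary.csv`` — ``participant_id``, ``date``, ``headache`` (0/1);
* ``proms.csv`` — one row per participant with WPI, SSS, FM score,
  MIDAS (may be empty) and PROMIS T-scores.

A cohort directory holds ``diary.csv``, ``proms.csv``, optionally
``truth.json`` and one ``<participant>/<night_date>/`` folder per
recorded night.  Reads validate monotone timestamps, the 4 Hz sample
rate (±1%) and state labels, and report offending line numbers;
absent minutes are flagged missing, never imputed.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import STATES, CohortTruth, NightRecording, NightTruth


class FormatError(ValueError):
    """A file violates the documented CSV dialect."""


def write_night(directory, rec: NightRecording) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ts = rec.start + pd.to_timedelta(np.arange(len(rec.eda)) / rec.fs, unit="s")
    eda = pd.DataFrame(
        {
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "eda_us": rec.eda,
            "missing": rec.eda_missing.astype(int),
        }
    )
    eda.to_csv(directory / "eda.csv", index=False, float_format="%.17g")
    m = rec.minutes.copy()
    m["minute_start"] = m["minute_start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    m["missing"] = m["missing"].astype(int)
    m.to_csv(directory / "minutes.csv", index=False, float_format="%.17g")
    temp = pd.DataFrame(
        {
            "timestamp": (rec.start + pd.to_timedelta(np.arange(len(rec.skin_temp)), unit="s")
                          ).strftime("%Y-%m-%dT%H:%M:%S"),
            "skin_temp_c": rec.skin_temp,
        }
    )
    temp.to_csv(directory / "skin_temp.csv", index=False, float_format="%.17g")


def _check_monotone(ts: pd.Series, path) -> None:
    diffs = ts.diff().dt.total_seconds().to_numpy()[1:]
    bad = np.flatnonzero(diffs <= 0)
    if bad.size:
        line = int(bad[0]) + 3  # 1-based, after header and first row
        raise FormatError(f"{path}: non-monotone or duplicated timestamp at line {line}")


def read_night(directory, participant_id: str | None = None) -> NightRecording:
    """Read one night folder back into a :class:`NightRecording`."""
    directory = Path(directory)
    eda_path = directory / "eda.csv"
    eda = pd.read_csv(eda_path, float_precision="round_trip")
    ts = pd.to_datetime(eda["timestamp"], utc=True, format="ISO8601")
    _check_monotone(ts, eda_path)
    step = ts.diff().dt.total_seconds().to_numpy()[1:]
    fs = 1.0 / np.median(step)
    if abs(fs - 4.0) / 4.0 > 0.01:
        raise FormatError(f"{eda_path}: sample rate {fs:.3f} Hz deviates >1% from 4 Hz")

    minutes_path = directory / "minutes.csv"
    minutes = pd.read_csv(minutes_path, float_precision="round_trip")
    minutes["minute_start"] = pd.to_datetime(minutes["minute_start"], utc=True, format="ISO8601")
    _check_monotone(minutes["minute_start"], minutes_path)
    bad_states = ~minutes["state"].isin(STATES)
    if bad_states.any():
        line = int(np.flatnonzero(bad_states)[0]) + 2
        raise FormatError(f"{minutes_path}: unknown state label at line {line}")

    # absent minutes are flagged missing, never imputed
    start = ts.iloc[0].floor("min")
    n_min = int(round(len(eda) / 4.0 / 60.0))
    full = pd.DataFrame({"minute_start": start + pd.to_timedelta(np.arange(n_min), unit="min")})
    minutes = full.merge(minutes, on="minute_start", how="left")
    absent = minutes["state"].isna()
    minutes.loc[absent, "state"] = "asleep"
    minutes["missing"] = minutes["missing"].fillna(1).astype(bool) | absent
    minutes["state"] = minutes["state"].astype(object)

    temp_path = directory / "skin_temp.csv"
    if temp_path.exists():
        skin_temp = pd.read_csv(temp_path, float_precision="round_trip")["skin_temp_c"].to_numpy(dtype=float)
    else:
        skin_temp = np.full(n_min * 60, np.nan)

    values = eda["eda_us"].to_numpy(dtype=float)
    missing = eda["missing"].to_numpy().astype(bool)
    values[missing] = np.nan
    night_date = (minutes["minute_start"].iloc[-1] + pd.Timedelta(minutes=1)).date()
    rec = NightRecording(
        participant_id=participant_id or directory.parent.name,
        night_date=night_date,
        start=ts.iloc[0],
        eda=values,
        eda_missing=missing,
        skin_temp=skin_temp,
        minutes=minutes,
        fs=4.0,
    )
    rec.validate()
    return rec


def write_diary(path, diary: pd.DataFrame) -> None:
    diary.to_csv(path, index=False)


def read_diary(path) -> pd.DataFrame:
    d = pd.read_csv(path)
    d["date"] = pd.to_datetime(d["date"]).dt.date
    d["headache"] = d["headache"].astype(int)
    if not d["headache"].isin((0, 1)).all():
        raise FormatError(f"{path}: headache must be 0/1")
    return d


def write_proms(path, proms: pd.DataFrame) -> None:
    proms.to_csv(path, index=False)


def read_proms(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(path, truth: CohortTruth) -> None:
    payload = {
        "betas": truth.betas,
        "participant_trait": truth.participant_trait,
        "nights": {
            pid: [
                {
                    "date": str(date),
                    "injected_peaks": [[float(t), float(a)] for t, a in nt.injected_peaks],
                    "storm_windows": [[float(s), float(e)] for s, e in nt.storm_windows],
                    "in_bed_minutes": nt.in_bed_minutes,
                    "nightly_storm_rate": nt.nightly_storm_rate,
                    "headache_probability": nt.headache_probability,
                }
                for date, nt in zip(truth.night_dates[pid], truth.nights[pid])
            ]
            for pid in truth.nights
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> CohortTruth:
    payload = json.loads(Path(path).read_text())
    truth = CohortTruth(betas=payload["betas"], participant_trait=payload["participant_trait"])
    for pid, nights in payload["nights"].items():
        truth.nights[pid] = [
            NightTruth(
                injected_peaks=[tuple(p) for p in n["injected_peaks"]],
                storm_windows=[tuple(w) for w in n["storm_windows"]],
                in_bed_minutes=n["in_bed_minutes"],
                nightly_storm_rate=n["nightly_storm_rate"],
                headache_probability=n["headache_probability"],
            )
            for n in nights
        ]
        truth.night_dates[pid] = [dt.date.fromisoformat(n["date"]) for n in nights]
    return truth


def write_cohort(directory, recordings: dict, diary: pd.DataFrame, proms: pd.DataFrame,
                 truth: CohortTruth | None = None) -> None:
    """Write a full cohort directory (one folder per recorded night)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_diary(directory / "diary.csv", diary)
    write_proms(directory / "proms.csv", proms)
    if truth is not None:
        write_truth(directory / "truth.json", truth)
    for (pid, date), rec in recordings.items():
        if rec is not None:
            write_night(directory / pid / str(date), rec)


def read_cohort(directory) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Read a cohort directory; unrecorded diary nights map to None."""
    directory = Path(directory)
    diary = read_diary(directory / "diary.csv")
    proms_path = directory / "proms.csv"
    proms = read_proms(proms_path) if proms_path.exists() else pd.DataFrame()
    recordings: dict = {}
    for _, row in diary.iterrows():
        night_dir = directory / str(row["participant_id"]) / str(row["date"])
        if (night_dir / "eda.csv").exists():
            recordings[(row["participant_id"], row["date"])] = read_night(
                night_dir, participant_id=str(row["participant_id"])
            )
        else:
            recordings[(row["participant_id"], row["date"])] = None
    return recordings, diary, proms
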