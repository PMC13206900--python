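"""Night QC, 5-min block construction, featurization and label alignment.

A night is usable when its in-bed minute missingness is strictly below
30% and a diary entry exists for the morning it ends on.  Usable nights
are tiled into non-overlapping 5-min blocks (each fully inside a
maximal in-bed run; trailing partial blocks dropped) and each block is
described by four statistics (median, min, max, sd) of nine channels:
cleaned total EDA, skin temperature, pulse rate, PRV, respiratory rate,
and the four per-minute time-in-state indicators.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import CleanEDASignal, NightQC, NightRecording

BLOCK_MIN = 5

CHANNELS = (
    "total_eda",
    "skin_temp",
    "pulse_rate",
    "prv",
    "resp_rate",
    "time_in_bed",
    "time_asleep",
    "time_awake_in_bed",
    "time_out_of_bed",
)
STATS = ("median", "min", "max", "sd")

#: the 36 block feature columns, in canonical order
FEATURE_COLUMNS = [f"{ch}_{st}" for ch in CHANNELS for st in STATS]


def _stats(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return {"median": np.nan, "min": np.nan, "max": np.nan, "sd": np.nan}
    return {
        "median": float(np.median(values)),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
    }


def qc_night(
    rec: NightRecording | None,
    diary: pd.DataFrame,
    participant_id: str | None = None,
    night_date=None,
    max_missing_fraction: float = 0.30,
) -> NightQC:
    """Apply the night-level QC rule.

    ``missing_fraction`` is missing in-bed minutes over expected in-bed
    minutes; usable requires strictly less than 30% missingness plus a
    diary entry for the night's morning date.  A night with no
    recording (device not worn) or no in-bed minutes is unusable.
    """
    pid = participant_id if rec is None else rec.participant_id
    date = night_date if rec is None else rec.night_date
    mask = (diary["participant_id"] == pid) & (diary["date"] == date)
    has_diary = bool(mask.any())

    if rec is None:
        return NightQC(pid, date, 1.0, has_diary, False, "no_recording")
    in_bed = rec.in_bed_minute_mask()
    expected = int(in_bed.sum())
    if expected == 0:
        return NightQC(pid, date, 1.0, has_diary, False, "no_in_bed_minutes")
    missing = int((rec.minutes["missing"].to_numpy() & in_bed).sum())
    frac = missing / expected
    usable = frac < max_missing_fraction and has_diary
    reason = None
    if not usable:
        reason = "missingness" if frac >= max_missing_fraction else "no_diary"
    return NightQC(pid, date, frac, has_diary, usable, reason)


def _block_ranges(rec: NightRecording) -> list[tuple[int, int]]:
    """5-min blocks [start_min, end_min) tiling each maximal in-bed run."""
    out = []
    for lo_s, hi_s in rec.in_bed_intervals():
        lo, hi = int(lo_s // 60), int(hi_s // 60)
        for b in range(lo, hi - BLOCK_MIN + 1, BLOCK_MIN):
            out.append((b, b + BLOCK_MIN))
    return out


def make_blocks(rec: NightRecording, clean: CleanEDASignal) -> pd.DataFrame:
    """Build the unlabeled 36-feature rows for one QC-passing night.

    EDA statistics use only valid cleaned samples; minute channels skip
    missing minutes; the time-in-state channels are per-minute 0/1
    indicators summarized like any other channel (their block sums are
    the minutes-per-state counts).  Blocks with any undefined feature
    (e.g. no valid EDA sample) are dropped so the analytic feature table
    has no missing values.
    """
    spm = 60 * int(clean.fs)
    states = rec.minutes["state"].to_numpy()
    minute_missing = rec.minutes["missing"].to_numpy()
    rows = []
    ranges = _block_ranges(rec)
    if not ranges:
        warnings.warn(f"night {rec.participant_id}/{rec.night_date}: no complete 5-min in-bed block")
        return pd.DataFrame(columns=["participant_id", "night_date", "block_index", *FEATURE_COLUMNS])

    for block_index, (m0, m1) in enumerate(ranges):
        eda = clean.values[m0 * spm : m1 * spm]
        eda = eda[clean.valid[m0 * spm : m1 * spm]]
        temp = rec.skin_temp[m0 * 60 : m1 * 60]
        keep = ~minute_missing[m0:m1]
        st = states[m0:m1]
        chans = {
            "total_eda": eda,
            "skin_temp": temp,
            "pulse_rate": rec.minutes["pulse_rate"].to_numpy()[m0:m1][keep],
            "prv": rec.minutes["prv_ms"].to_numpy()[m0:m1][keep],
            "resp_rate": rec.minutes["resp_rate"].to_numpy()[m0:m1][keep],
            "time_in_bed": (st != "out_of_bed").astype(float),
            "time_asleep": (st == "asleep").astype(float),
            "time_awake_in_bed": (st == "awake_in_bed").astype(float),
            "time_out_of_bed": (st == "out_of_bed").astype(float),
        }
        row = {
            "participant_id": rec.participant_id,
            "night_date": rec.night_date,
            "block_index": block_index,
        }
        for ch, vals in chans.items():
            for stat, v in _stats(vals).items():
                row[f"{ch}_{stat}"] = v
        rows.append(row)

    df = pd.DataFrame(rows)
    return df.dropna(subset=FEATURE_COLUMNS).reset_index(drop=True)


def make_lmm_blocks(rec: NightRecording) -> pd.DataFrame:
    """5-min block means of the per-minute channels for group statistics.

    Each block value is the mean of its (up to 5) present 1-min bucket
    values; a block with more than 2 of its 5 minutes missing is
    dropped.
    """
    minute_missing = rec.minutes["missing"].to_numpy()
    rows = []
    for block_index, (m0, m1) in enumerate(_block_ranges(rec)):
        keep = ~minute_missing[m0:m1]
        if keep.sum() < 3:  # > 2 of 5 missing
            continue
        row = {
            "participant_id": rec.participant_id,
            "night_date": rec.night_date,
            "block_index": block_index,
        }
        for col in ("pulse_rate", "prv_ms", "resp_rate"):
            row[col] = float(rec.minutes[col].to_numpy()[m0:m1][keep].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def label_nights(blocks: pd.DataFrame, diary: pd.DataFrame) -> pd.DataFrame:
    """Attach the next-day headache label to every block.

    A night ending on morning date D receives the diary entry for D
    (the day the participant wakes into).  Nights without an entry are
    excluded; conflicting duplicate entries for one (participant, date)
    raise.
    """
    dup = diary.groupby(["participant_id", "date"])["headache"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()
        raise ValueError(f"conflicting diary entries for {bad}")
    d = diary.drop_duplicates(["participant_id", "date"]).rename(
        columns={"date": "night_date", "headache": "label"}
    )
    merged = blocks.merge(d[["participant_id", "night_date", "label"]],
                          on=["participant_id", "night_date"], how="inner")
    merged["label"] = merged["label"].astype(int)
    return merged
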