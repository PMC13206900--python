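"""Core domain containers shared across the pipeline.

Times inside a night are float seconds from the recording start (the
in-bed start); absolute timestamps are derived from
:attr:`NightRecording.start`.  A "night" is keyed by the calendar date
of the morning it ends on, so the "next day" of a night is that same
date.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: allowed per-minute body/sleep states
STATES = ("asleep", "awake_in_bed", "out_of_bed")


@dataclass
class NightRecording:
    """One participant-night of raw and per-minute aggregate channels.

    Attributes
    ----------
    participant_id : str
    night_date : datetime.date
        Morning the night ends on.
    start : pandas.Timestamp
        UTC timestamp of the first sample (in-bed start).
    eda : ndarray
        4 Hz skin conductance in µS; NaN where missing.
    eda_missing : ndarray of bool
        Sample-level missingness flags (device dropouts).
    skin_temp : ndarray
        1 Hz skin temperature, °C.
    minutes : DataFrame
        One row per minute: ``minute_start`` (Timestamp), ``pulse_rate``
        (bpm), ``prv_ms`` (ms), ``resp_rate`` (breaths/min), ``state``
        (one of :data:`STATES`) and ``missing`` (bool).
    """

    participant_id: str
    night_date: dt.date
    start: pd.Timestamp
    eda: np.ndarray
    eda_missing: np.ndarray
    skin_temp: np.ndarray
    minutes: pd.DataFrame
    fs: float = 4.0

    @property
    def n_minutes(self) -> int:
        return len(self.minutes)

    @property
    def duration_s(self) -> float:
        return len(self.eda) / self.fs

    def in_bed_minute_mask(self) -> np.ndarray:
        """Boolean per minute: participant in bed (asleep or awake)."""
        return (self.minutes["state"] != "out_of_bed").to_numpy()

    def in_bed_intervals(self) -> list[tuple[float, float]]:
        """Maximal in-bed runs as (start_s, end_s) from recording start."""
        mask = self.in_bed_minute_mask()
        out: list[tuple[float, float]] = []
        i = 0
        n = len(mask)
        while i < n:
            if mask[i]:
                j = i
                while j < n and mask[j]:
                    j += 1
                out.append((i * 60.0, j * 60.0))
                i = j
            else:
                i += 1
        return out

    def validate(self) -> None:
        if len(self.eda) != len(self.eda_missing):
            raise ValueError("eda and eda_missing length mismatch")
        if len(self.eda) != self.n_minutes * 60 * int(self.fs):
            raise ValueError("eda length inconsistent with minute count")
        bad = set(self.minutes["state"]) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")
        vals = self.eda[~self.eda_missing]
        if np.any(vals < 0):
            raise ValueError("EDA values must be >= 0 µS where not missing")

    def copy(self) -> "NightRecording":
        return NightRecording(
            participant_id=self.participant_id,
            night_date=self.night_date,
            start=self.start,
            eda=self.eda.copy(),
            eda_missing=self.eda_missing.copy(),
            skin_temp=self.skin_temp.copy(),
            minutes=self.minutes.copy(),
            fs=self.fs,
        )


@dataclass
class CleanEDASignal:
    """Cleaned 4 Hz EDA with validity mask and tonic/phasic split.

    ``tonic + phasic == values`` at every valid sample; invalid samples
    are NaN in all three arrays.  ``step_log`` records each cleaning
    step with the number of samples it affected.
    """

    values: np.ndarray
    valid: np.ndarray
    tonic: np.ndarray
    phasic: np.ndarray
    step_log: list[tuple[str, int]]
    fs: float
    usable: bool = True
    unusable_reason: str | None = None

    @property
    def valid_hours(self) -> float:
        return float(self.valid.sum()) / self.fs / 3600.0


@dataclass(frozen=True)
class SCRPeak:
    """A skin-conductance response detected by trough-to-peak dynamics."""

    peak_time: float  # s from recording start
    trough_time: float
    amplitude: float  # µS, peak value - preceding trough value
    peak_value: float  # µS (phasic scale)


@dataclass(frozen=True)
class EDAStorm:
    """A merged run of 30-s epochs each containing >= 3 SCR peaks."""

    start_time: float  # s
    end_time: float
    n_epochs: int
    n_peaks: int

    @property
    def duration_min(self) -> float:
        return (self.end_time - self.start_time) / 60.0


@dataclass
class NightPhasicSummary:
    """Per-night phasic EDA summary used by the group analyses."""

    median_total_eda: float  # µS
    scr_peak_rate: float  # peaks per valid in-bed hour
    mean_scr_amplitude: float  # µS; 0 with no_peaks flag when empty
    storm_count: int
    storm_rate: float  # storms per valid in-bed hour
    mean_storm_duration: float  # min
    total_storm_duration: float  # min
    valid_in_bed_hours: float
    no_peaks: bool = False

    def as_dict(self) -> dict:
        return {
            "median_total_eda": self.median_total_eda,
            "scr_peak_rate": self.scr_peak_rate,
            "mean_scr_amplitude": self.mean_scr_amplitude,
            "storm_count": self.storm_count,
            "storm_rate": self.storm_rate,
            "mean_storm_duration": self.mean_storm_duration,
            "total_storm_duration": self.total_storm_duration,
            "valid_in_bed_hours": self.valid_in_bed_hours,
        }


@dataclass
class NightQC:
    """Night-level usability: missingness rule plus diary coverage."""

    participant_id: str
    night_date: dt.date
    missing_fraction: float
    has_diary: bool
    usable: bool
    reason: str | None = None


@dataclass
class NightTruth:
    """Ground truth for one simulated night."""

    injected_peaks: list[tuple[float, float]]  # (peak_time_s, amplitude µS)
    storm_windows: list[tuple[float, float]]  # (start_s, end_s)
    in_bed_minutes: int
    nightly_storm_rate: float  # storms per in-bed hour
    arousal: float = 1.0  # nightly sympathetic-arousal multiplier (mean 1)
    headache_probability: float = float("nan")


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort.

    ``nights[pid]`` is the ordered list of :class:`NightTruth` for that
    participant; ``betas`` are the generative logit coefficients of the
    next-day headache model; ``participant_trait`` the latent scalar
    behind between-participant storm-burden differences.
    """

    betas: dict = field(default_factory=dict)
    participant_trait: dict = field(default_factory=dict)
    nights: dict = field(default_factory=dict)  # pid -> list[NightTruth]
    night_dates: dict = field(default_factory=dict)  # pid -> list[date]
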