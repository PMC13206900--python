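"""Synthetic nocturnal cohort generator with known ground truth.

Each night is built in two stages so statistical tests can stay cheap:

1. *event truth* — in-bed duration, storm windows, SCR event times and
   amplitudes, and the night's storm rate (fast, no waveform);
2. *waveform synthesis* — 4 Hz EDA = slowly drifting tonic level
   + sum of SCR kernels (linear rise, exponential decay) + white noise,
   plus per-minute aggregate channels (pulse rate, PRV, respiratory
   rate, sleep state) as stationary AR(1) series.

Next-day headache labels follow a logistic model in the within-
participant z-score of the nightly storm rate; participant-level PROMs
are linked to mean storm burden through a Gaussian copula calibrated to
a target Spearman correlation.  Identical (config, seed) reproduces
every array bit for bit.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CohortConfig
from .types import CohortTruth, NightRecording, NightTruth

_BASE_DATE = dt.date(2024, 3, 1)  # first morning of the simulated study


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def _draw_in_bed_minutes(config: CohortConfig, rng: np.random.Generator) -> int:
    """Gaussian in-bed duration, redrawn below the 3 h floor."""
    while True:
        hours = rng.normal(config.in_bed_hours_mean, config.in_bed_hours_sd)
        if hours >= config.in_bed_hours_min:
            return int(round(hours * 60.0))


def _simulate_events(
    config: CohortConfig, participant_trait: float, rng: np.random.Generator
) -> NightTruth:
    """Draw the two-state (base/storm) Poisson SCR train for one night."""
    n_min = _draw_in_bed_minutes(config, rng)
    dur_s = n_min * 60.0
    hours = dur_s / 3600.0

    # nightly sympathetic arousal: a mean-one lognormal multiplier that
    # jointly elevates background SCRs and storm propensity, so storm-prone
    # nights show raised phasic activity throughout the night
    arousal = float(
        np.exp(config.arousal_sd * rng.normal() - 0.5 * config.arousal_sd**2)
    )

    # storm windows: Poisson count, trait- and arousal-scaled rate, non-overlapping
    storm_rate = (
        config.storm_rate * arousal * float(np.exp(config.storm_trait_scale * participant_trait))
    )
    n_storms = rng.poisson(storm_rate)
    windows: list[tuple[float, float]] = []
    for _ in range(n_storms):
        length = rng.uniform(*config.storm_len_min) * 60.0
        if length >= dur_s:
            continue
        for _try in range(50):
            start = rng.uniform(0.0, dur_s - length)
            if all(start >= e or start + length <= s for s, e in windows):
                windows.append((start, start + length))
                break
    windows.sort()

    # event onsets: homogeneous background plus elevated rate inside storms
    margin = config.scr_rise_s + 5.0 * config.scr_decay_s
    hi = max(dur_s - margin, 1.0)
    times = list(rng.uniform(0.0, hi, size=rng.poisson(config.scr_base_rate * arousal * hours)))
    for s, e in windows:
        length_min = (e - s) / 60.0
        n_extra = rng.poisson(config.storm_elevated_rate * length_min)
        times.extend(np.minimum(rng.uniform(s, e, size=n_extra), hi))
    times = np.sort(np.asarray(times, dtype=float))
    # sudomotor refractory: thin events closer than scr_refractory_s
    if times.size and config.scr_refractory_s > 0:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= config.scr_refractory_s:
                kept.append(t)
        times = np.asarray(kept)
    amps = rng.lognormal(config.scr_amplitude_log_mean, config.scr_amplitude_log_sd, len(times))

    peaks = [(t + config.scr_rise_s, a) for t, a in zip(times, amps)]
    return NightTruth(
        injected_peaks=peaks,
        storm_windows=windows,
        in_bed_minutes=n_min,
        nightly_storm_rate=len(windows) / hours,
        arousal=arousal,
    )


def _scr_kernel(amplitude: float, config: CohortConfig, fs: float) -> np.ndarray:
    """Linear rise to ``amplitude`` over rise_s, then exponential decay."""
    n_rise = max(int(round(config.scr_rise_s * fs)), 1)
    n_decay = int(round(5.0 * config.scr_decay_s * fs))
    rise = np.linspace(0.0, amplitude, n_rise + 1)[1:]
    decay = amplitude * np.exp(-np.arange(1, n_decay + 1) / fs / config.scr_decay_s)
    return np.concatenate([rise, decay])


def draw_vitals(rng: np.random.Generator) -> dict:
    """Participant-level vital-sign set-points."""
    return {
        "pr_mu": rng.normal(58.0, 4.0),
        "prv_mu": rng.normal(45.0, 8.0),
        "rr_mu": rng.normal(14.0, 1.0),
        "temp_mu": rng.normal(33.5, 0.5),
    }


def _ar1(rng: np.random.Generator, n: int, mu: float, sd: float, phi: float = 0.9) -> np.ndarray:
    e = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), n)
    x = np.empty(n)
    x[0] = mu + rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = mu + phi * (x[i - 1] - mu) + e[i]
    return x


def _synthesize_recording(
    truth: NightTruth,
    config: CohortConfig,
    rng: np.random.Generator,
    participant_id: str = "sim",
    night_date: dt.date | None = None,
    tonic_level: float | None = None,
    vitals: dict | None = None,
) -> NightRecording:
    fs = config.eda_fs
    n_min = truth.in_bed_minutes
    n_samp = n_min * 60 * int(fs)

    # tonic: participant baseline with night-to-night jitter, plus a
    # smooth random-walk drift at 1-min knots (baseline conductance is a
    # stable individual trait; nights differ only modestly)
    if tonic_level is None:
        tonic_level = rng.uniform(*config.tonic_level_range)
    level = (
        tonic_level
        * truth.arousal**config.tonic_arousal_gamma
        * float(np.exp(rng.normal(0.0, config.tonic_night_jitter_sd)))
    )
    steps = rng.normal(0.0, config.tonic_drift_sd / np.sqrt(60.0), n_min + 1)
    knots = level + np.cumsum(steps) - steps[0]
    t_samp = np.arange(n_samp) / fs
    tonic = np.interp(t_samp, np.arange(n_min + 1) * 60.0, knots)
    tonic = np.clip(tonic, 0.05, None)

    # band-limited (AR(1)) measurement noise with marginal SD noise_sd;
    # conductance sensors are smooth at 4 Hz, white noise is not realistic
    phi = config.noise_ar1_phi
    white = rng.normal(0.0, 1.0, n_samp)
    from scipy.signal import lfilter

    noise = lfilter([np.sqrt(1.0 - phi**2)], [1.0, -phi], white) * config.noise_sd
    eda = tonic + noise
    for peak_t, amp in truth.injected_peaks:
        onset = peak_t - config.scr_rise_s
        i0 = int(round(onset * fs))
        kern = _scr_kernel(amp, config, fs)
        i1 = min(i0 + len(kern), n_samp)
        if i0 < n_samp:
            eda[i0:i1] += kern[: i1 - i0]
    eda = np.clip(eda, 0.0, None)

    # vitals: participant-level set-points with small night-to-night
    # jitter (resting heart rate etc. are stable individual traits),
    # plus stationary AR(1) variation within the night
    if vitals is None:
        vitals = draw_vitals(rng)
    skin_temp = _ar1(rng, n_min * 60, mu=vitals["temp_mu"] + rng.normal(0.0, 0.2), sd=0.3, phi=0.995)
    pr = _ar1(rng, n_min, mu=vitals["pr_mu"] + rng.normal(0.0, 1.5), sd=3.0)
    prv = np.clip(_ar1(rng, n_min, mu=vitals["prv_mu"] + rng.normal(0.0, 3.0), sd=8.0), 5.0, None)
    rr = np.clip(_ar1(rng, n_min, mu=vitals["rr_mu"] + rng.normal(0.0, 0.4), sd=1.0), 6.0, None)

    # sleep state: early settling period awake, then brief awakenings
    state = np.full(n_min, "asleep", dtype=object)
    state[: min(5, n_min)] = "awake_in_bed"
    for _ in range(rng.poisson(2.0)):
        start = rng.integers(0, n_min)
        state[start : start + int(rng.integers(1, 6))] = "awake_in_bed"

    night_date = night_date or _BASE_DATE
    jitter_min = int(rng.integers(-60, 61))
    start = (
        pd.Timestamp(night_date - dt.timedelta(days=1), tz="UTC")
        + pd.Timedelta(hours=23)
        + pd.Timedelta(minutes=jitter_min)
    )
    minutes = pd.DataFrame(
        {
            "minute_start": start + pd.to_timedelta(np.arange(n_min), unit="min"),
            "pulse_rate": pr,
            "prv_ms": prv,
            "resp_rate": rr,
            "state": state,
            "missing": np.zeros(n_min, dtype=bool),
        }
    )
    return NightRecording(
        participant_id=participant_id,
        night_date=night_date,
        start=start,
        eda=eda,
        eda_missing=np.zeros(n_samp, dtype=bool),
        skin_temp=skin_temp,
        minutes=minutes,
        fs=fs,
    )


def simulate_night(
    config: CohortConfig,
    participant_trait: float = 0.0,
    seed: int = 0,
    participant_id: str = "sim",
    night_date: dt.date | None = None,
) -> tuple[NightRecording, NightTruth]:
    """Simulate one uncorrupted participant-night.

    Returns the recording together with its ground truth (injected SCR
    peak times/amplitudes, storm windows, nightly storm rate).  The
    headache probability on the truth is NaN until labels are generated
    cohort-wide (the logistic model standardizes the storm rate across a
    participant's nights).
    """
    config.validate()
    rng = _rng_for(seed, 0)
    truth = _simulate_events(config, participant_trait, rng)
    rec = _synthesize_recording(
        truth, config, _rng_for(seed, 1), participant_id=participant_id, night_date=night_date
    )
    return rec, truth


def generate_headache_labels(
    truths: list[NightTruth], config: CohortConfig, seed: int = 0
) -> np.ndarray:
    """Draw next-day headache labels for one participant's nights.

    ``P(headache) = logistic(beta0 + beta_storm * z)`` with ``z`` the
    within-participant z-score of the nightly storm rate (zero when the
    rate is constant across nights).  Fills ``headache_probability`` on
    each truth and returns the 0/1 labels.
    """
    if len(truths) == 0:
        raise ValueError("need at least one night")
    rates = np.array([t.nightly_storm_rate for t in truths], dtype=float)
    sd = rates.std()
    z = (rates - rates.mean()) / sd if sd > 0 else np.zeros_like(rates)
    p = expit(config.headache_beta0 + config.headache_beta_storm * z)
    for t, pi in zip(truths, p):
        t.headache_probability = float(pi)
    rng = _rng_for(seed, 2)
    return (rng.uniform(size=len(p)) < p).astype(int)


def _refresh_minute_missing(rec: NightRecording) -> None:
    """A minute counts as missing when >50% of its EDA samples are."""
    spm = 60 * int(rec.fs)
    frac = rec.eda_missing[: rec.n_minutes * spm].reshape(rec.n_minutes, spm).mean(axis=1)
    rec.minutes["missing"] = frac > 0.5


def insert_dropout(rec: NightRecording, start_s: float, length_s: float) -> None:
    """Flag ``length_s`` seconds of EDA from ``start_s`` as missing (in place)."""
    i0 = int(round(start_s * rec.fs))
    i1 = min(i0 + int(round(length_s * rec.fs)), len(rec.eda))
    rec.eda[i0:i1] = np.nan
    rec.eda_missing[i0:i1] = True
    _refresh_minute_missing(rec)


def insert_out_of_bed(rec: NightRecording, start_min: int, length_min: int, eda_offset: float) -> None:
    """Flip minutes to out-of-bed and add a motion offset to EDA (in place)."""
    end_min = min(start_min + length_min, rec.n_minutes)
    idx = rec.minutes.index[start_min:end_min]
    rec.minutes.loc[idx, "state"] = "out_of_bed"
    spm = 60 * int(rec.fs)
    rec.eda[start_min * spm : end_min * spm] += eda_offset


def corrupt_recording(rec: NightRecording, config: CohortConfig, seed: int = 0) -> NightRecording:
    """Apply realistic defects: dropouts, spike artifacts, out-of-bed excursions.

    Returns a corrupted copy; the caller's recording and the night's
    ground truth are unchanged.
    """
    rng = _rng_for(seed, 3)
    out = rec.copy()
    hours = out.duration_s / 3600.0
    n_samp = len(out.eda)

    for _ in range(rng.poisson(config.dropout_rate * hours)):
        length = rng.uniform(*config.dropout_len_s)
        start = rng.uniform(0.0, max(out.duration_s - length, 1.0))
        i0 = int(round(start * out.fs))
        i1 = min(i0 + int(round(length * out.fs)), n_samp)
        out.eda[i0:i1] = np.nan
        out.eda_missing[i0:i1] = True

    # isolated motion spikes: fast excursions the cleaner must mask
    for _ in range(rng.poisson(config.artifact_rate * hours)):
        i0 = rng.integers(0, n_samp)
        width = int(rng.integers(1, 4))
        out.eda[i0 : min(i0 + width, n_samp)] += rng.uniform(1.5, 4.0)

    if config.out_of_bed_excursions > 0 and out.n_minutes > 4:
        starts: list[tuple[int, int]] = []
        for _ in range(config.out_of_bed_excursions):
            length = int(round(rng.uniform(*config.out_of_bed_len_min)))
            length = max(min(length, out.n_minutes - 2), 1)
            for _try in range(50):
                s = int(rng.integers(1, out.n_minutes - length))
                if all(s >= e or s + length <= b for b, e in starts):
                    starts.append((s, s + length))
                    insert_out_of_bed(out, s, length, config.out_of_bed_eda_offset)
                    break

    _refresh_minute_missing(out)
    return out


def _prom_table(
    participant_ids: list[str],
    mean_storm_rates: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Participant PROMs with FM score rank-linked to storm burden.

    Uses a Gaussian copula: with a bivariate-normal latent of Pearson
    correlation ``2*sin(pi*rho_s/6)`` the population Spearman
    correlation is ``rho_s``; FM is a monotone integer map of the
    latent (median ≈ 11, range 0–31) so the target survives rounding.
    """
    n = len(participant_ids)
    if n < 3 and config.prom_link_rho != 0.0:
        raise ValueError("prom_link_rho != 0 needs >= 3 participants")
    # normal scores of the realized storm-burden ranks
    order = np.argsort(np.argsort(mean_storm_rates, kind="stable"), kind="stable")
    from scipy.stats import norm

    z_s = norm.ppf((order + 1.0) / (n + 1.0))
    rho_p = 2.0 * np.sin(np.pi * config.prom_link_rho / 6.0)
    latent = rho_p * z_s + np.sqrt(max(1.0 - rho_p**2, 0.0)) * rng.normal(size=n)

    fm = np.clip(np.round(11.0 + 4.5 * latent), 0, 31).astype(int)
    wpi_raw = np.round(0.6 * fm + rng.normal(0.0, 1.0, n))
    wpi = np.clip(wpi_raw, np.maximum(0, fm - 12), np.minimum(19, fm)).astype(int)
    sss = fm - wpi

    midas = np.round(np.exp(rng.normal(2.5, 0.8, n))).astype(float)
    midas[rng.uniform(size=n) < config.midas_missing_prob] = np.nan
    fatigue = 52.0 + 7.0 * (0.3 * z_s + np.sqrt(1 - 0.3**2) * rng.normal(size=n))
    sleep_t = 54.0 + 7.0 * (0.3 * z_s + np.sqrt(1 - 0.3**2) * rng.normal(size=n))
    return pd.DataFrame(
        {
            "participant_id": participant_ids,
            "wpi": wpi,
            "sss": sss,
            "fm_score": fm,
            "midas": midas,
            "promis_fatigue_t": np.round(fatigue, 1),
            "promis_sleep_t": np.round(sleep_t, 1),
        }
    )


def simulate_cohort(
    config: CohortConfig, signals: bool = True
) -> tuple[dict, pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Simulate a full cohort.

    Returns ``(recordings, diary, proms, truth)``:

    * ``recordings`` maps ``(participant_id, night_date)`` to a
      (corrupted) :class:`NightRecording`, or ``None`` for nights the
      device was not worn;
    * ``diary`` has one row per (participant, date) with the 0/1
      next-day headache entry;
    * ``proms`` one row per participant;
    * ``truth`` the full generative ground truth.

    With ``signals=False`` only event-level truth, labels and PROMs are
    generated (every recording is ``None``) — sufficient for the
    statistical calibration checks and orders of magnitude faster.
    """
    config.validate()
    base_seed = config.seed
    truth = CohortTruth(
        betas={"beta0": config.headache_beta0, "beta_storm": config.headache_beta_storm}
    )
    recordings: dict[tuple[str, dt.date], NightRecording | None] = {}
    diary_rows = []
    mean_rates = []
    pids = [f"P{i + 1:03d}" for i in range(config.n_participants)]

    trait_rng = _rng_for(base_seed, 10)
    traits = trait_rng.normal(0.0, 1.0, config.n_participants)

    for p_idx, pid in enumerate(pids):
        trait = float(traits[p_idx])
        truth.participant_trait[pid] = trait
        participant_rng = _rng_for(base_seed, 14, p_idx)
        tonic_level = float(participant_rng.uniform(*config.tonic_level_range))
        vitals = draw_vitals(participant_rng)
        night_truths: list[NightTruth] = []
        dates: list[dt.date] = []
        for n_idx in range(config.nights_per_participant):
            night_seed_rng = _rng_for(base_seed, 11, p_idx, n_idx)
            night_seed = int(night_seed_rng.integers(0, 2**31 - 1))
            date = _BASE_DATE + dt.timedelta(days=n_idx)
            rng = _rng_for(night_seed, 0)
            nt = _simulate_events(config, trait, rng)
            night_truths.append(nt)
            dates.append(date)
            worn = _rng_for(night_seed, 4).uniform() >= config.missing_night_prob
            if signals and worn:
                rec = _synthesize_recording(
                    nt, config, _rng_for(night_seed, 1), participant_id=pid,
                    night_date=date, tonic_level=tonic_level, vitals=vitals,
                )
                rec = corrupt_recording(rec, config, seed=night_seed)
                recordings[(pid, date)] = rec
            else:
                recordings[(pid, date)] = None
        labels = generate_headache_labels(
            night_truths, config, seed=int(_rng_for(base_seed, 12, p_idx).integers(0, 2**31 - 1))
        )
        for date, lab in zip(dates, labels):
            diary_rows.append({"participant_id": pid, "date": date, "headache": int(lab)})
        truth.nights[pid] = night_truths
        truth.night_dates[pid] = dates
        mean_rates.append(np.mean([t.nightly_storm_rate for t in night_truths]))

    diary = pd.DataFrame(diary_rows)
    proms = _prom_table(pids, np.asarray(mean_rates), config, _rng_for(base_seed, 13))
    return recordings, diary, proms, truth
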