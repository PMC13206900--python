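"""EDA cleaning, tonic/phasic decomposition, SCR peak and storm detection.

The cleaning pipeline applies, in order: out-of-bed exclusion, slope
artifact masking (with padding), range-outlier removal, linear
interpolation of brief gaps, removal of residual short valid segments,
and tonic/phasic decomposition by a centered 8-s moving median.  SCR
peaks are detected from the phasic component by local trough-to-peak
dynamics with an amplitude floor and a refractory separation; EDA
storms are merged runs of 30-s epochs each containing at least three
peaks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CleaningConfig
from .types import CleanEDASignal, EDAStorm, NightPhasicSummary, NightRecording, SCRPeak


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``mask`` is True."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def decompose(
    values: np.ndarray,
    valid: np.ndarray,
    fs: float,
    tonic_window_s: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a cleaned signal into tonic and phasic components.

    Tonic is a centered moving median (window ``tonic_window_s``,
    edge-truncated) computed independently on each valid run; phasic is
    the residual, so ``tonic + phasic == values`` at every valid sample.
    Invalid samples are NaN in both outputs.
    """
    if not valid.any():
        raise ValueError("cannot decompose an all-invalid signal")
    window = int(round(tonic_window_s * fs)) | 1  # odd, centered
    tonic = np.full_like(values, np.nan, dtype=float)
    for i0, i1 in _runs(valid):
        seg = pd.Series(values[i0:i1])
        tonic[i0:i1] = seg.rolling(window, center=True, min_periods=1).median().to_numpy()
    phasic = values - tonic
    return tonic, phasic


def clean_eda(rec: NightRecording, config: CleaningConfig | None = None) -> CleanEDASignal:
    """Clean a night's raw 4 Hz EDA and decompose it.

    Steps (each logged with the number of samples it newly affected):

    1. invalidate samples in out-of-bed minutes;
    2. invalidate slope artifacts (|dEDA/dt| above the limit) padded by
       2 s on each side;
    3. invalidate range outliers outside the plausible µS band;
    4. linearly interpolate invalid runs of at most 5 s with valid
       neighbours on both sides;
    5. invalidate residual valid segments shorter than 30 s;
    6. decompose the surviving signal into tonic and phasic.

    A night retaining less than 30 min of valid in-bed signal is flagged
    unusable (``usable=False``) but still returned.
    """
    cfg = config or CleaningConfig()
    fs = rec.fs
    values = rec.eda.astype(float).copy()
    valid = ~rec.eda_missing & np.isfinite(values)
    log: list[tuple[str, int]] = []
    spm = 60 * int(fs)

    # 1. out-of-bed minutes
    out_min = ~rec.in_bed_minute_mask()
    out_samples = np.repeat(out_min, spm)[: values.size]
    n = int((valid & out_samples).sum())
    valid &= ~out_samples
    log.append(("out_of_bed", n))

    # 2. slope artifacts, padded
    slope = np.abs(np.diff(values)) * fs
    with np.errstate(invalid="ignore"):
        jump = slope > cfg.artifact_slope_us_per_s
    hit = np.zeros_like(valid)
    hit[:-1] |= jump
    hit[1:] |= jump
    pad = int(round(cfg.artifact_pad_s * fs))
    if hit.any() and pad > 0:
        kernel = np.ones(2 * pad + 1, dtype=int)
        hit = np.convolve(hit.astype(int), kernel, mode="same") > 0
    n = int((valid & hit).sum())
    valid &= ~hit
    log.append(("artifact", n))

    # 3. range outliers
    with np.errstate(invalid="ignore"):
        bad = (values < cfg.range_min_us) | (values > cfg.range_max_us)
    n = int((valid & bad).sum())
    valid &= ~bad
    log.append(("range_outlier", n))

    # 4. interpolate brief invalid runs (valid neighbours required)
    max_gap = int(round(cfg.max_interp_gap_s * fs))
    n_interp = 0
    for i0, i1 in _runs(~valid):
        if i1 - i0 <= max_gap and i0 > 0 and i1 < values.size and valid[i0 - 1] and valid[i1]:
            x0, x1 = values[i0 - 1], values[i1]
            frac = np.arange(1, i1 - i0 + 1) / (i1 - i0 + 1)
            values[i0:i1] = x0 + frac * (x1 - x0)
            valid[i0:i1] = True
            n_interp += i1 - i0
    log.append(("interpolated", n_interp))

    # 5. drop residual short valid segments
    min_seg = int(round(cfg.min_segment_s * fs))
    n_short = 0
    for i0, i1 in _runs(valid):
        if i1 - i0 < min_seg:
            valid[i0:i1] = False
            n_short += i1 - i0
    log.append(("short_segment", n_short))

    values[~valid] = np.nan
    usable = valid.sum() / fs / 60.0 >= cfg.min_valid_in_bed_min
    reason = None if usable else "insufficient_valid_in_bed_signal"

    if valid.any():
        tonic, phasic = decompose(values, valid, fs, cfg.tonic_window_s)
    else:
        tonic = np.full_like(values, np.nan)
        phasic = np.full_like(values, np.nan)
    log.append(("decomposed", int(valid.sum())))

    return CleanEDASignal(
        values=values,
        valid=valid,
        tonic=tonic,
        phasic=phasic,
        step_log=log,
        fs=fs,
        usable=usable,
        unusable_reason=reason,
    )


def detect_scr_peaks(
    phasic: np.ndarray,
    valid: np.ndarray,
    fs: float,
    min_amplitude: float = 0.005,
    min_separation: float = 1.0,
) -> list[SCRPeak]:
    """Detect SCR peaks on the phasic component.

    Candidates are strict local maxima within a valid run; each is paired
    with the most recent local minimum on the same run (the run start
    counts as a minimum), and kept when the trough-to-peak amplitude
    reaches ``min_amplitude``.  Accepted peaks closer together than
    ``min_separation`` are pruned keeping the larger amplitude (ties:
    the earlier peak).  Peaks never span invalid gaps.
    """
    peaks: list[SCRPeak] = []
    for i0, i1 in _runs(valid):
        x = phasic[i0:i1]
        if x.size < 3:
            continue
        interior = np.arange(1, x.size - 1)
        is_max = (x[interior] > x[interior - 1]) & (x[interior] > x[interior + 1])
        is_min = (x[interior] < x[interior - 1]) & (x[interior] < x[interior + 1])
        max_idx = interior[is_max]
        min_idx = np.concatenate([[0], interior[is_min]])
        if max_idx.size == 0:
            continue
        # most recent minimum before each maximum
        pos = np.searchsorted(min_idx, max_idx) - 1
        candidates = []
        for m, p in zip(max_idx, pos):
            trough = min_idx[max(p, 0)]
            amp = x[m] - x[trough]
            if amp >= min_amplitude:
                candidates.append((float(amp), int(m), int(trough)))
        # refractory pruning: larger amplitude wins, ties to the earlier peak
        candidates.sort(key=lambda c: (-c[0], c[1]))
        kept_times: list[float] = []
        kept: list[tuple[float, int, int]] = []
        min_sep = min_separation
        for amp, m, trough in candidates:
            t = m / fs
            if all(abs(t - kt) >= min_sep for kt in kept_times):
                kept_times.append(t)
                kept.append((amp, m, trough))
        for amp, m, trough in sorted(kept, key=lambda c: c[1]):
            peaks.append(
                SCRPeak(
                    peak_time=(i0 + m) / fs,
                    trough_time=(i0 + trough) / fs,
                    amplitude=amp,
                    peak_value=float(x[m]),
                )
            )
    peaks.sort(key=lambda p: p.peak_time)
    return peaks


def detect_storms(
    peaks: list[SCRPeak],
    in_bed_intervals: list[tuple[float, float]],
    epoch_len: float = 30.0,
    min_peaks: int = 3,
    merge_gap_min: float = 5.0,
) -> list[EDAStorm]:
    """Detect EDA storms from accepted SCR peaks.

    Each maximal in-bed interval is tiled with consecutive half-open
    ``epoch_len``-second epochs anchored at the interval start (a
    trailing partial epoch is truncated at the interval end).  An epoch
    is positive when it contains at least ``min_peaks`` peak times;
    positive epochs whose gap (end of one to start of the next) is at
    most ``merge_gap_min`` minutes are merged into a single storm.
    Storms never bridge separate in-bed intervals.
    """
    times = np.asarray([p.peak_time for p in peaks], dtype=float)
    merge_gap_s = merge_gap_min * 60.0
    storms: list[EDAStorm] = []
    for lo, hi in in_bed_intervals:
        if hi <= lo:
            continue
        edges = np.arange(lo, hi, epoch_len)
        bounds = np.append(edges, hi)
        counts, _ = np.histogram(times, bins=bounds)
        pos = np.flatnonzero(counts >= min_peaks)
        if pos.size == 0:
            continue
        groups: list[list[int]] = [[int(pos[0])]]
        for e in pos[1:]:
            prev_end = bounds[groups[-1][-1] + 1]
            if bounds[e] - prev_end <= merge_gap_s:
                groups[-1].append(int(e))
            else:
                groups.append([int(e)])
        for g in groups:
            start = float(bounds[g[0]])
            end = float(bounds[g[-1] + 1])
            n_pk = int(((times >= start) & (times < end)).sum())
            storms.append(EDAStorm(start_time=start, end_time=end, n_epochs=len(g), n_peaks=n_pk))
    storms.sort(key=lambda s: s.start_time)
    return storms


def summarize_night(
    clean: CleanEDASignal,
    peaks: list[SCRPeak],
    storms: list[EDAStorm],
) -> NightPhasicSummary:
    """Summarize a cleaned night's phasic activity.

    Rates are normalized by valid in-bed hours; the mean SCR amplitude
    of a peak-free night is reported as 0 with ``no_peaks=True``.
    """
    hours = clean.valid_hours
    if hours <= 0:
        raise ValueError("no valid in-bed signal to summarize")
    vals = clean.values[clean.valid]
    durations = [s.duration_min for s in storms]
    return NightPhasicSummary(
        median_total_eda=float(np.median(vals)),
        scr_peak_rate=len(peaks) / hours,
        mean_scr_amplitude=float(np.mean([p.amplitude for p in peaks])) if peaks else 0.0,
        storm_count=len(storms),
        storm_rate=len(storms) / hours,
        mean_storm_duration=float(np.mean(durations)) if durations else 0.0,
        total_storm_duration=float(np.sum(durations)) if durations else 0.0,
        valid_in_bed_hours=hours,
        no_peaks=not peaks,
    )


def process_night(
    rec: NightRecording, config: CleaningConfig | None = None
) -> tuple[CleanEDASignal, list[SCRPeak], list[EDAStorm], NightPhasicSummary | None]:
    """Convenience: clean, detect peaks and storms, and summarize one night."""
    cfg = config or CleaningConfig()
    clean = clean_eda(rec, cfg)
    if not clean.valid.any():
        return clean, [], [], None
    peaks = detect_scr_peaks(
        clean.phasic, clean.valid, clean.fs, cfg.scr_min_amplitude_us, cfg.scr_min_separation_s
    )
    storms = detect_storms(
        peaks,
        rec.in_bed_intervals(),
        epoch_len=cfg.storm_epoch_s,
        min_peaks=cfg.storm_min_peaks,
        merge_gap_min=cfg.storm_merge_gap_min,
    )
    summary = summarize_night(clean, peaks, storms) if clean.usable else None
    return clean, peaks, storms, summary
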