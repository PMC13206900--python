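"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from nighteda.config import CohortConfig
from nighteda.features import label_nights, make_blocks, qc_night
from nighteda.signal import process_night
from nighteda.simulate import simulate_cohort


# ---------------------------------------------------------------------------
# independent oracles (deliberately separate from the implementation)


def oracle_match_counts(truth_peaks, detected, tol=2.0):
    """Greedy one-to-one peak matching within ±tol seconds.

    Returns ``(tp, n_detected, n_truth)`` so F1 can be pooled across nights.
    """
    det_t = np.array([p.peak_time for p in detected])
    used = np.zeros(len(det_t), bool)
    tp = 0
    for t, _amp in truth_peaks:
        if det_t.size == 0:
            break
        d = np.abs(det_t - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            tp += 1
            used[j] = True
    return tp, len(det_t), len(truth_peaks)


def oracle_f1(truth_peaks, detected, tol=2.0):
    tp, n_det, n_truth = oracle_match_counts(truth_peaks, detected, tol)
    prec = tp / n_det if n_det else 0.0
    rec = tp / n_truth if n_truth else 1.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def oracle_storms(times, lo, hi, epoch=30.0, k=3, gap_s=300.0):
    """Brute-force storm finder: scan every epoch, then merge intervals."""
    positive = []
    t = lo
    while t < hi:
        e = min(t + epoch, hi)
        count = sum(1 for x in times if t <= x < e)
        if count >= k:
            positive.append((t, e))
        t += epoch
    merged = []
    for s, e in positive:
        if merged and s - merged[-1][1] <= gap_s:
            merged[-1][1] = e
            merged[-1][2] += 1
        else:
            merged.append([s, e, 1])
    return [(s, e, n) for s, e, n in merged]


def oracle_auroc(labels, scores):
    """Pairwise AUROC with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# fixtures


def build_participant_blocks(seed, nights=40, beta_storm=1.5):
    """Simulate one participant end-to-end to labeled block rows."""
    cfg = dataclasses.replace(
        CohortConfig(),
        n_participants=1,
        nights_per_participant=nights,
        headache_beta_storm=beta_storm,
        prom_link_rho=0.0,
        seed=seed,
    )
    recordings, diary, _proms, truth = simulate_cohort(cfg)
    frames = []
    for (pid, date), rec in recordings.items():
        if rec is None or not qc_night(rec, diary).usable:
            continue
        clean, _peaks, _storms, summary = process_night(rec)
        if summary is None:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frames.append(make_blocks(rec, clean))
    blocks = label_nights(pd.concat(frames, ignore_index=True), diary)
    return blocks, truth


@pytest.fixture(scope="session")
def participant_blocks_40():
    """One 40-night synthetic participant with an injected storm effect."""
    blocks, truth = build_participant_blocks(seed=7)
    return blocks


@pytest.fixture(scope="session")
def small_cohort():
    """A small fully-simulated cohort shared across IO/pipeline tests."""
    cfg = dataclasses.replace(
        CohortConfig(),
        n_participants=3,
        nights_per_participant=5,
        prom_link_rho=0.0,
        seed=11,
    )
    return simulate_cohort(cfg) + (cfg,)


def make_feature_blocks(night_labels, blocks_per_night=4, signal=1.0, seed=0):
    """Fabricate a labeled block table with one informative feature.

    ``total_eda_sd`` carries ``signal`` times the night label plus noise;
    all other feature columns are pure noise.  Useful for fast model
    tests that do not need the waveform pipeline.
    """
    from nighteda.features import FEATURE_COLUMNS

    rng = np.random.default_rng(seed)
    rows = []
    for i, lab in enumerate(night_labels):
        for b in range(blocks_per_night):
            row = {
                "participant_id": "P001",
                "night_date": pd.Timestamp("2024-03-01").date() + pd.Timedelta(days=i),
                "block_index": b,
                "label": int(lab),
            }
            for c in FEATURE_COLUMNS:
                row[c] = rng.normal()
            row["total_eda_sd"] += signal * lab
            rows.append(row)
    return pd.DataFrame(rows)
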