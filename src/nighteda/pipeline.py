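"""End-to-end orchestration: simulate → qc → process-eda → featurize →
predict → stats → report, with a reproducible run manifest.

All randomness flows from a single seed through named per-stage
substreams; rerunning with the same config and seed reproduces every
output file byte for byte (manifests record SHA-256 digests and row
counts so this is checkable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import CleaningConfig, CohortConfig, ModelConfig, config_to_dict
from .features import label_nights, make_blocks, qc_night
from .group_stats import (
    NightlyContrastLMM,
    participant_summaries,
    spearman_with_proms,
)
from .prediction import NextDayHeadacheModel, SingleClassError
from .signal import process_night
from .simulate import simulate_cohort

log = logging.getLogger("nighteda")

PHASIC_FEATURES = (
    "median_total_eda",
    "scr_peak_rate",
    "mean_scr_amplitude",
    "storm_rate",
    "mean_storm_duration",
    "total_storm_duration",
)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    learners: tuple[str, ...] = ("elastic_net", "random_forest", "gbm")
    model_grids: dict | None = None  # learner -> grid override
    max_inner_pairs: int | None = 12
    seed: int = 0


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    version: str
    stages: list = field(default_factory=list)
    skipped_participants: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict[str, Path]) -> None:
        entry = {"name": name, "outputs": {}}
        for label, path in outputs.items():
            data = Path(path).read_bytes()
            rows = max(data.count(b"\n") - 1, 0)
            entry["outputs"][label] = {
                "file": str(path),
                "sha256": hashlib.sha256(data).hexdigest(),
                "rows": rows,
            }
        self.stages.append(entry)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def compliance_table(qc_rows: list, diary: pd.DataFrame) -> pd.DataFrame:
    """Wear-compliance tile table: participant × night → status.

    Status is ``missing`` for nights failing QC (not worn or too much
    missingness), otherwise ``headache`` / ``no_pain`` from the diary.
    """
    d = diary.set_index(["participant_id", "date"])["headache"]
    rows = []
    for qc in qc_rows:
        key = (qc.participant_id, qc.night_date)
        if not qc.usable:
            status = "missing"
        else:
            status = "headache" if int(d.loc[key]) == 1 else "no_pain"
        rows.append(
            {"participant_id": qc.participant_id, "night_date": qc.night_date, "status": status}
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the full workflow on a synthetic cohort.

    Participants whose usable nights all share one label are skipped
    with a logged notice (their model cannot be computed) but still
    appear in the compliance report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    cohort_cfg = dataclasses.replace(config.cohort, seed=seed)
    manifest = RunManifest(
        config={
            "cohort": config_to_dict(cohort_cfg),
            "cleaning": config_to_dict(config.cleaning),
            "learners": list(config.learners),
            "max_inner_pairs": config.max_inner_pairs,
        },
        seed=seed,
        version=__version__,
    )

    # 1. simulate
    log.info("stage simulate: %d participants x %d nights",
             cohort_cfg.n_participants, cohort_cfg.nights_per_participant)
    recordings, diary, proms, truth = simulate_cohort(cohort_cfg)
    manifest.add_stage("simulate", {"diary": _write(diary, out / "diary.csv"),
                                    "proms": _write(proms, out / "proms.csv")})

    # 2. qc
    qc_rows = [
        qc_night(rec, diary, participant_id=pid, night_date=date)
        for (pid, date), rec in sorted(recordings.items())
    ]
    qc_df = pd.DataFrame([dataclasses.asdict(q) for q in qc_rows])
    manifest.add_stage("qc", {"qc": _write(qc_df, out / "qc.csv")})

    # 3. process-eda (usable nights only)
    usable = [q for q in qc_rows if q.usable]
    peak_rows, storm_rows, summary_rows = [], [], []
    cleans = {}
    for q in sorted(usable, key=lambda q: (q.participant_id, q.night_date)):
        rec = recordings[(q.participant_id, q.night_date)]
        try:
            clean, peaks, storms, summary = process_night(rec, config.cleaning)
        except ValueError as exc:
            raise RuntimeError(
                f"stage process-eda failed for night "
                f"{q.participant_id}/{q.night_date}: {exc}"
            ) from exc
        if summary is None:
            manifest.warnings.append(
                f"{q.participant_id}/{q.night_date}: unusable after cleaning"
            )
            continue
        cleans[(q.participant_id, q.night_date)] = clean
        key = {"participant_id": q.participant_id, "night_date": q.night_date}
        peak_rows += [
            {**key, "peak_time_s": p.peak_time, "trough_time_s": p.trough_time,
             "amplitude_us": p.amplitude} for p in peaks
        ]
        storm_rows += [
            {**key, "start_s": s.start_time, "end_s": s.end_time, "n_epochs": s.n_epochs,
             "n_peaks": s.n_peaks, "duration_min": s.duration_min} for s in storms
        ]
        summary_rows.append({**key, **summary.as_dict()})
    night_summary = pd.DataFrame(summary_rows)
    manifest.add_stage(
        "process-eda",
        {
            "peaks": _write(pd.DataFrame(peak_rows), out / "peaks.csv"),
            "storms": _write(pd.DataFrame(storm_rows), out / "storms.csv"),
            "night_summary": _write(night_summary, out / "night_summary.csv"),
        },
    )

    # 4. featurize
    block_frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for key, clean in cleans.items():
            block_frames.append(make_blocks(recordings[key], clean))
    blocks = pd.concat(block_frames, ignore_index=True) if block_frames else pd.DataFrame()
    labeled = label_nights(blocks, diary) if not blocks.empty else blocks
    manifest.add_stage("featurize", {"blocks": _write(labeled, out / "blocks.csv")})

    # 5. predict (per participant, best of the configured learners)
    pred_rows, eval_entries = [], {}
    for pid in sorted(labeled["participant_id"].unique()) if not labeled.empty else []:
        sub = labeled[labeled["participant_id"] == pid]
        results = {}
        try:
            for learner in config.learners:
                grid = (config.model_grids or {}).get(learner)
                cfg = ModelConfig(
                    learner=learner, grid=grid, seed=seed,
                    max_inner_pairs=config.max_inner_pairs,
                )
                results[learner] = NextDayHeadacheModel(sub, config=cfg).fit()
        except SingleClassError:
            manifest.skipped_participants.append(pid)
            log.info("participant %s skipped: single-class nights, model cannot be computed", pid)
            continue
        best = max(results, key=lambda k: results[k].auroc)
        res = results[best]
        for _, r in res.nightly.iterrows():
            pred_rows.append(
                {"participant_id": pid, "night_date": r["night_date"], "score": r["score"],
                 "label": r["label"], "n_blocks": r["n_blocks"], "learner": best}
            )
        eval_entries[pid] = {
            "best_learner": best,
            "per_learner": {
                k: {"auroc": v.auroc, "auprc": v.auprc, "prevalence": v.prevalence,
                    "clinically_informative": v.clinically_informative}
                for k, v in results.items()
            },
            "threshold_table": res.evaluation.threshold_table.to_dict("records"),
        }
    pred_path = _write(pd.DataFrame(pred_rows), out / "predictions.csv")
    eval_path = out / "evaluation.json"
    eval_path.write_text(json.dumps(eval_entries, indent=2, default=str))
    manifest.add_stage("predict", {"predictions": pred_path, "evaluation": eval_path})

    # 6. stats
    lmm_rows = []
    if not night_summary.empty:
        for feat in PHASIC_FEATURES:
            try:
                res = NightlyContrastLMM.from_night_summaries(night_summary, diary, feat).fit()
                lmm_rows.append(res.as_dict())
            except ValueError as exc:
                manifest.warnings.append(f"lmm {feat}: {exc}")
    summaries = participant_summaries(night_summary) if not night_summary.empty else pd.DataFrame()
    corr = (
        spearman_with_proms(summaries, proms, wearable_metrics=list(PHASIC_FEATURES))
        if not summaries.empty else pd.DataFrame()
    )
    manifest.add_stage(
        "stats",
        {
            "lmm": _write(pd.DataFrame(lmm_rows), out / "lmm_results.csv"),
            "correlations": _write(corr, out / "correlations.csv"),
        },
    )

    # 7. report
    compliance = compliance_table(qc_rows, diary)
    manifest.add_stage("report", {"compliance": _write(compliance, out / "compliance.csv")})

    manifest.write(out / "manifest.json")
    return manifest
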