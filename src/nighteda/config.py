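"""Configuration dataclasses for simulation, cleaning and modelling.

Every tunable constant of the pipeline lives here with its default, so a
run is fully described by (config, seed).  Configs round-trip through
plain dicts / YAML (see :func:`load_config`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml


@dataclass
class CohortConfig:
    """Generative settings for a synthetic nocturnal cohort.

    Defaults emulate a small tertiary-care migraine cohort wearing a
    wrist device during sleep for about a month: ~8.5 h in bed per night
    (SD 1.8 h), 4 Hz skin conductance with a slowly drifting tonic level,
    spontaneous SCRs as a two-state (background / storm) Poisson train,
    and a logistic dependence of next-day headache on the night's storm
    rate.
    """

    n_participants: int = 10
    nights_per_participant: int = 30

    # in-bed duration (hours); redrawn until >= min
    in_bed_hours_mean: float = 8.5
    in_bed_hours_sd: float = 1.8
    in_bed_hours_min: float = 3.0

    # tonic (baseline) skin conductance, µS
    eda_fs: float = 4.0
    tonic_level_range: tuple[float, float] = (0.3, 2.0)  # participant-level baseline
    tonic_night_jitter_sd: float = 0.15  # night-to-night log-scale jitter of the baseline
    tonic_drift_sd: float = 0.10  # µS per sqrt(hour), random-walk scale

    # SCR event process
    scr_base_rate: float = 12.0  # events per in-bed hour outside storms
    storm_rate: float = 2.0  # expected storms per night
    #: log-scale SD of the nightly sympathetic-arousal latent that jointly
    #: scales the background SCR rate and the storm rate (mean-one multiplier)
    arousal_sd: float = 1.0
    #: elasticity of the tonic baseline to nightly arousal (sympathetic tone
    #: raises baseline conductance); level multiplier = arousal ** gamma
    tonic_arousal_gamma: float = 0.5
    storm_elevated_rate: float = 10.0  # extra events per minute inside a storm
    storm_len_min: tuple[float, float] = (2.0, 8.0)  # storm window length, minutes
    storm_trait_scale: float = 0.4  # log-scale effect of participant trait on storm rate

    # SCR kernel: linear rise then exponential decay; lognormal amplitudes
    scr_rise_s: float = 1.0
    scr_decay_s: float = 3.0
    scr_refractory_s: float = 1.5  # min spacing of generated events (sudomotor refractory)
    scr_amplitude_log_mean: float = -3.0  # ln µS; median exp(-3.0) ≈ 0.05 µS
    scr_amplitude_log_sd: float = 0.7

    noise_sd: float = 0.003  # µS, marginal SD of additive measurement noise
    noise_ar1_phi: float = 0.99  # lag-1 autocorrelation (band-limited sensor noise)

    # corruption / missingness
    dropout_rate: float = 1.0  # dropouts per hour
    dropout_len_s: tuple[float, float] = (5.0, 60.0)
    artifact_rate: float = 2.0  # spike artifacts per hour
    out_of_bed_excursions: int = 1  # per night
    out_of_bed_len_min: tuple[float, float] = (2.0, 10.0)
    out_of_bed_eda_offset: float = 0.5  # µS motion offset while out of bed
    missing_night_prob: float = 0.08  # whole night unrecorded

    # next-day headache generative model (logit scale)
    headache_beta0: float = -0.32  # logit of ~0.42 baseline prevalence
    headache_beta_storm: float = 1.0  # per within-participant SD of nightly storm rate

    # participant-level PROM linkage
    prom_link_rho: float = 0.7  # target Spearman rho between FM score and storm burden
    midas_missing_prob: float = 0.2

    seed: int = 0

    def validate(self) -> None:
        rates = {
            "scr_base_rate": self.scr_base_rate,
            "storm_rate": self.storm_rate,
            "storm_elevated_rate": self.storm_elevated_rate,
            "dropout_rate": self.dropout_rate,
            "artifact_rate": self.artifact_rate,
        }
        for name, value in rates.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.in_bed_hours_sd < 0:
            raise ValueError("in_bed_hours_sd must be >= 0")
        for name in ("missing_night_prob", "midas_missing_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not -1.0 <= self.prom_link_rho <= 1.0:
            raise ValueError("prom_link_rho must be in [-1, 1]")
        if self.out_of_bed_excursions < 0:
            raise ValueError("out_of_bed_excursions must be >= 0")
        if self.n_participants < 1 or self.nights_per_participant < 1:
            raise ValueError("cohort must have >= 1 participant and >= 1 night")


@dataclass
class CleaningConfig:
    """EDA cleaning and event-detection thresholds.

    The artifact slope limit and the plausible-range bounds are standard
    wearable-EDA QC heuristics; the SCR amplitude / refractory settings
    are the sensitivity-analysis thresholds adopted as package defaults.
    """

    artifact_slope_us_per_s: float = 5.0
    artifact_pad_s: float = 2.0
    range_min_us: float = 0.01
    range_max_us: float = 60.0
    max_interp_gap_s: float = 5.0
    min_segment_s: float = 30.0
    min_valid_in_bed_min: float = 30.0
    tonic_window_s: float = 8.0

    scr_min_amplitude_us: float = 0.005
    scr_min_separation_s: float = 1.0

    storm_epoch_s: float = 30.0
    storm_min_peaks: int = 3
    storm_merge_gap_min: float = 5.0


#: hyperparameter grids per learner; "penalty" is the elastic-net lambda
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "elastic_net": [
        {"l1_ratio": m, "penalty": lam}
        for m in (0.1, 0.5, 0.9)
        for lam in (0.001, 0.01, 0.1, 1.0)
    ],
    "random_forest": [
        {"n_estimators": 200, "max_depth": d, "max_features": f}
        for d in (2, 4, None)
        for f in ("sqrt", None)
    ],
    "gbm": [
        {"n_estimators": n, "learning_rate": lr, "max_depth": d}
        for n in (100, 300)
        for lr in (0.05, 0.1)
        for d in (2, 3)
    ],
}

LEARNERS = tuple(DEFAULT_GRIDS)


@dataclass
class ModelConfig:
    """Settings for one personalized prediction model."""

    learner: str = "elastic_net"
    grid: Sequence[dict] = None  # None -> DEFAULT_GRIDS[learner]
    seed: int = 0
    class_weighting: bool = True
    scale: bool = True
    #: evaluate at most this many (seeded) inner pairs per outer fold;
    #: None evaluates the exhaustive enumeration
    max_inner_pairs: int | None = None

    def __post_init__(self) -> None:
        if self.learner not in DEFAULT_GRIDS:
            raise ValueError(f"unknown learner {self.learner!r}; expected one of {LEARNERS}")
        if self.grid is None:
            self.grid = [dict(g) for g in DEFAULT_GRIDS[self.learner]]
        if len(self.grid) == 0:
            raise ValueError("hyperparameter grid must be non-empty")


def config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    kwargs = dict(d)
    for k in ("tonic_level_range", "storm_len_min", "dropout_len_s", "out_of_bed_len_min"):
        if k in kwargs and kwargs[k] is not None:
            kwargs[k] = tuple(kwargs[k])
    cfg = CohortConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path) -> CohortConfig:
    """Load a :class:`CohortConfig` from a YAML file (flat mapping)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return cohort_config_from_dict(data)


def save_config(cfg: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
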