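"""Personalized next-day headache prediction under nested night-level CV.

One model per participant: 5-min block features predict the next-day
headache label, all blocks of a night travel together through every
split.  The outer loop is leave-one-night-out; within each outer
training set, hyperparameters are tuned on balanced inner folds that
hold out one headache night and one non-headache night at a time
(enumerated exhaustively), selecting the grid point with the best mean
block-level AUPRC.  Block probabilities of the held-out night are
averaged into a single nightly score; nightly scores are evaluated by
AUROC (midrank/pairwise rule), AUPRC (average precision) and fixed
probability thresholds.

The public surface follows the fitted-model idiom::

    model = NextDayHeadacheModel(labeled_blocks, learner="random_forest")
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .config import ModelConfig
from .features import FEATURE_COLUMNS


class SingleClassError(ValueError):
    """All nights share one label; a discriminative model cannot be fit."""


# ---------------------------------------------------------------------------
# metrics


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUROC by the pairwise rank rule with half credit for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUROC needs both classes")
    r = rankdata(scores)  # midranks
    return float((r[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def average_precision(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUPRC as step-wise average precision (ties grouped per threshold)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    if n_pos == 0 or n_pos == len(labels):
        raise SingleClassError("average precision needs both classes")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    # keep only the last index of each tied score group
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def rates_to_metrics(
    prevalence: float, sensitivity: float, specificity: float
) -> tuple[float, float]:
    """Precision and accuracy implied by (prevalence, sensitivity, specificity).

    ``precision = p*se / (p*se + (1-p)*(1-sp))`` (NaN when no positives
    are predicted) and ``accuracy = p*se + (1-p)*sp``.
    """
    for name, v in (("prevalence", prevalence), ("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    tp = prevalence * sensitivity
    fp = (1.0 - prevalence) * (1.0 - specificity)
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    accuracy = tp + (1.0 - prevalence) * specificity
    return precision, accuracy


# ---------------------------------------------------------------------------
# fold planning


@dataclass
class FoldPlan:
    """Outer leave-one-night-out plan with exhaustive balanced inner pairs."""

    outer: list[tuple[object, list]]  # (held-out night, training nights)
    inner_pairs: dict  # held-out night -> [(headache night, non-headache night), ...]


def plan_folds(night_labels: pd.Series) -> FoldPlan:
    """Plan nested night-level cross-validation.

    ``night_labels`` maps night key -> 0/1 label.  Raises
    :class:`SingleClassError` when only one class is present overall
    (the model cannot be computed for such a participant).
    """
    nights = list(night_labels.index)
    labels = night_labels.to_dict()
    classes = set(labels.values())
    if len(nights) < 2 or classes != {0, 1}:
        raise SingleClassError("need >= 2 nights with both headache and headache-free nights")
    outer = []
    inner: dict = {}
    for held in nights:
        train = [n for n in nights if n != held]
        pos = [n for n in train if labels[n] == 1]
        neg = [n for n in train if labels[n] == 0]
        outer.append((held, train))
        inner[held] = list(itertools.product(pos, neg))
    return FoldPlan(outer=outer, inner_pairs=inner)


def class_weights(night_labels: pd.Series, enabled: bool = True) -> dict[int, float]:
    """Inverse-frequency class weights at night frequency: N / (2 * N_c)."""
    if not enabled:
        return {0: 1.0, 1: 1.0}
    n = len(night_labels)
    counts = night_labels.value_counts()
    if set(counts.index) != {0, 1}:
        raise SingleClassError("class weights need both classes")
    return {c: n / (2.0 * counts[c]) for c in (0, 1)}


# ---------------------------------------------------------------------------
# learners


def _make_estimator(learner: str, params: dict, seed: int):
    if learner == "elastic_net":
        return LogisticRegression(
            solver="saga",
            l1_ratio=params["l1_ratio"],
            C=1.0 / params["penalty"],
            max_iter=200,
            tol=1e-3,
            random_state=seed,
        )
    if learner == "random_forest":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            max_features=params["max_features"],
            random_state=seed,
            n_jobs=1,
        )
    if learner == "gbm":
        return HistGradientBoostingClassifier(
            max_iter=params["n_estimators"],
            learning_rate=params["learning_rate"],
            max_depth=params["max_depth"],
            max_bins=64,
            early_stopping=False,
            random_state=seed,
        )
    raise ValueError(f"unknown learner {learner!r}")


def _complexity(learner: str, params: dict) -> tuple:
    """Ordering used to break AUPRC ties toward the simpler grid point."""
    if learner == "elastic_net":
        return (-params["penalty"], params["l1_ratio"])
    if learner == "random_forest":
        depth = params["max_depth"] if params["max_depth"] is not None else np.inf
        feat = 0 if params["max_features"] == "sqrt" else 1
        return (depth, params["n_estimators"], feat)
    if learner == "gbm":
        return (params["max_depth"], params["n_estimators"], params["learning_rate"])
    raise ValueError(learner)


def _build_pipeline(config: ModelConfig, params: dict):
    est = _make_estimator(config.learner, params, config.seed)
    if config.scale:
        return Pipeline([("scaler", StandardScaler()), ("clf", est)])
    return Pipeline([("clf", est)])


# ---------------------------------------------------------------------------
# nested CV


def _night_arrays(blocks: pd.DataFrame) -> dict:
    """Cache per-night feature matrices and labels."""
    out = {}
    for night, g in blocks.groupby("night_date", sort=True):
        out[night] = (g[FEATURE_COLUMNS].to_numpy(dtype=float), int(g["label"].iloc[0]))
    return out


def _stack(cache: dict, nights: list, weights: dict[int, float]):
    xs, ys, ws = [], [], []
    for n in nights:
        X, lab = cache[n]
        xs.append(X)
        ys.append(np.full(len(X), lab))
        ws.append(np.full(len(X), weights[lab]))
    return np.vstack(xs), np.concatenate(ys), np.concatenate(ws)


def tune_and_fit(
    cache: dict,
    train_nights: list,
    pairs: list[tuple],
    config: ModelConfig,
    fold_seed: int = 0,
) -> tuple[Pipeline, dict]:
    """Tune hyperparameters on balanced inner folds and refit.

    For each grid point, fits on the outer training set minus each
    held-out (headache, non-headache) night pair and scores that pair's
    blocks; the grid point with the highest mean block-level AUPRC wins
    (ties: simpler point, then grid order).  When no balanced pair can
    be formed, tuning is skipped and the grid midpoint is used.  The
    winning point is refit on the full outer training set; centering /
    scaling statistics come from training blocks only and are frozen
    inside the fitted pipeline.

    ``config.max_inner_pairs`` caps the evaluated pairs with a seeded
    draw from the exhaustive enumeration (None evaluates them all).
    """
    grid = list(config.grid)
    labels = pd.Series({n: cache[n][1] for n in train_nights})
    weights = class_weights(labels, config.class_weighting)

    use_pairs = list(pairs)
    if config.max_inner_pairs is not None and len(use_pairs) > config.max_inner_pairs:
        rng = np.random.default_rng((config.seed, fold_seed))
        idx = rng.choice(len(use_pairs), size=config.max_inner_pairs, replace=False)
        use_pairs = [use_pairs[i] for i in sorted(idx)]

    chosen = None
    if len(grid) == 1:
        chosen = grid[0]
    elif not use_pairs:
        warnings.warn("no balanced inner pair available; using grid midpoint")
        chosen = grid[len(grid) // 2]
    else:
        best = None
        for gi, params in enumerate(grid):
            scores = []
            for pos_n, neg_n in use_pairs:
                inner_train = [n for n in train_nights if n not in (pos_n, neg_n)]
                inner_labels = {cache[n][1] for n in inner_train}
                if inner_labels != {0, 1}:
                    continue
                w = class_weights(pd.Series({n: cache[n][1] for n in inner_train}), config.class_weighting)
                X, y, sw = _stack(cache, inner_train, w)
                pipe = _build_pipeline(config, params)
                pipe.fit(X, y, clf__sample_weight=sw)
                Xh = np.vstack([cache[pos_n][0], cache[neg_n][0]])
                yh = np.r_[np.ones(len(cache[pos_n][0])), np.zeros(len(cache[neg_n][0]))]
                prob = pipe.predict_proba(Xh)[:, 1]
                scores.append(average_precision(yh, prob))
            if not scores:
                continue
            key = (-float(np.mean(scores)), _complexity(config.learner, params), gi)
            if best is None or key < best[0]:
                best = (key, params)
        chosen = best[1] if best is not None else grid[len(grid) // 2]

    X, y, sw = _stack(cache, train_nights, weights)
    pipe = _build_pipeline(config, chosen)
    pipe.fit(X, y, clf__sample_weight=sw)
    return pipe, chosen


def predict_night(model: Pipeline, blocks_X: np.ndarray) -> float:
    """Nightly score: arithmetic mean of per-block headache probabilities."""
    if len(blocks_X) == 0:
        raise ValueError("night has no valid blocks")
    return float(model.predict_proba(blocks_X)[:, 1].mean())


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationResult:
    """Nightly-score evaluation with the interpretive benchmark."""

    auroc: float
    auprc: float
    prevalence: float
    clinically_informative: bool
    threshold_table: pd.DataFrame

    @staticmethod
    def from_scores(
        labels: np.ndarray, scores: np.ndarray, thresholds=(0.25, 0.50, 0.75)
    ) -> "EvaluationResult":
        labels = np.asarray(labels)
        scores = np.asarray(scores, dtype=float)
        auroc = roc_auc(labels, scores)
        auprc = average_precision(labels, scores)
        prevalence = float((labels == 1).mean())
        rows = []
        for t in thresholds:
            pred = scores >= t
            tp = int((pred & (labels == 1)).sum())
            fp = int((pred & (labels == 0)).sum())
            fn = int((~pred & (labels == 1)).sum())
            tn = int((~pred & (labels == 0)).sum())
            rows.append(
                {
                    "threshold": t,
                    "precision": tp / (tp + fp) if tp + fp else float("nan"),
                    "accuracy": (tp + tn) / len(labels),
                    "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
                    "specificity": tn / (tn + fp) if tn + fp else float("nan"),
                }
            )
        return EvaluationResult(
            auroc=auroc,
            auprc=auprc,
            prevalence=prevalence,
            clinically_informative=bool(auroc >= 0.70 and auprc >= prevalence + 0.10),
            threshold_table=pd.DataFrame(rows),
        )


@dataclass
class HeadacheModelResults:
    """Results of one participant's nested leave-one-night-out evaluation."""

    participant_id: str
    learner: str
    nightly: pd.DataFrame  # night_date, score, label, n_blocks
    evaluation: EvaluationResult
    chosen_params: dict  # held-out night -> tuned hyperparameters
    config: ModelConfig = field(repr=False, default=None)

    @property
    def auroc(self) -> float:
        return self.evaluation.auroc

    @property
    def auprc(self) -> float:
        return self.evaluation.auprc

    @property
    def prevalence(self) -> float:
        return self.evaluation.prevalence

    @property
    def clinically_informative(self) -> bool:
        return self.evaluation.clinically_informative

    def summary(self) -> str:
        e = self.evaluation
        lines = [
            "Next-day headache prediction (leave-one-night-out)",
            "=" * 52,
            f"participant:            {self.participant_id}",
            f"learner:                {self.learner}",
            f"nights evaluated:       {len(self.nightly)}",
            f"headache prevalence:    {e.prevalence:.3f}",
            f"AUROC (nightly scores): {e.auroc:.3f}",
            f"AUPRC (nightly scores): {e.auprc:.3f}",
            f"clinically informative: {'yes' if e.clinically_informative else 'no'}"
            "  (AUROC >= 0.70 and AUPRC >= prevalence + 0.10)",
            "",
            e.threshold_table.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


class NextDayHeadacheModel:
    """Personalized next-day headache model for one participant.

    Parameters
    ----------
    blocks : DataFrame
        Labeled 5-min block table of a single participant (the 36
        feature columns plus ``night_date`` and ``label``).
    learner : str
        ``elastic_net``, ``random_forest`` or ``gbm``.
    config : ModelConfig, optional
        Full modelling configuration; overrides ``learner`` if given.
    """

    def __init__(
        self,
        blocks: pd.DataFrame,
        learner: str = "elastic_net",
        config: ModelConfig | None = None,
    ):
        if blocks.empty:
            raise ValueError("no blocks provided")
        pids = blocks["participant_id"].unique()
        if len(pids) != 1:
            raise ValueError("blocks must belong to a single participant")
        missing = [c for c in FEATURE_COLUMNS if c not in blocks.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing[:3]}...")
        self.participant_id = str(pids[0])
        self.blocks = blocks.reset_index(drop=True)
        self.config = config or ModelConfig(learner=learner)

    @classmethod
    def from_cohort_blocks(cls, blocks: pd.DataFrame, participant_id: str, **kw):
        sub = blocks[blocks["participant_id"] == participant_id]
        return cls(sub, **kw)

    def fit(self) -> HeadacheModelResults:
        """Run the full nested leave-one-night-out procedure."""
        cache = _night_arrays(self.blocks)
        night_labels = pd.Series({n: lab for n, (_, lab) in cache.items()}).sort_index()
        plan = plan_folds(night_labels)

        rows = []
        chosen_params = {}
        for fold_i, (held, train) in enumerate(plan.outer):
            model, params = tune_and_fit(
                cache, train, plan.inner_pairs[held], self.config, fold_seed=fold_i
            )
            Xh, lab = cache[held]
            rows.append(
                {
                    "night_date": held,
                    "score": predict_night(model, Xh),
                    "label": lab,
                    "n_blocks": len(Xh),
                }
            )
            chosen_params[held] = params
        nightly = pd.DataFrame(rows)
        evaluation = EvaluationResult.from_scores(
            nightly["label"].to_numpy(), nightly["score"].to_numpy()
        )
        return HeadacheModelResults(
            participant_id=self.participant_id,
            learner=self.config.learner,
            nightly=nightly,
            evaluation=evaluation,
            chosen_params=chosen_params,
            config=self.config,
        )


def compare_learners(
    blocks: pd.DataFrame,
    learners=("elastic_net", "random_forest", "gbm"),
    configs: dict | None = None,
    seed: int = 0,
    **config_kw,
) -> dict[str, HeadacheModelResults]:
    """Fit one model per learner on the same participant's blocks.

    ``configs`` may supply a full :class:`ModelConfig` per learner;
    otherwise defaults (optionally overridden by ``config_kw``) are
    used.  Returns a dict learner -> results; the best model is the one
    maximizing nightly AUROC.
    """
    out = {}
    for learner in learners:
        cfg = (configs or {}).get(learner) or ModelConfig(learner=learner, seed=seed, **config_kw)
        out[learner] = NextDayHeadacheModel(blocks, config=cfg).fit()
    return out
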