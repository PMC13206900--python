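"""Group-level night comparisons and PROM correlations.

Nightly wearable measures are compared between nights preceding
headache vs headache-free days with a linear mixed model
``value ~ headache + (1 | participant)`` fit by REML, the fixed effect
tested with Satterthwaite denominator degrees of freedom, and the
difference standardized as Hedges' g against the total model variance
(random-intercept + residual).  Right-skewed outcomes are
log(1 + x)-transformed and reported on the transformed scale.
Participant-level means of the wearable metrics are correlated with
patient-reported outcomes by Spearman's rank correlation, with an exact
permutation p-value at small n and no multiplicity correction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf


# ---------------------------------------------------------------------------
# linear mixed model


def _satterthwaite_df(
    X: np.ndarray,
    groups: np.ndarray,
    sigma_a2: float,
    sigma_e2: float,
    contrast: np.ndarray,
) -> tuple[float, float]:
    """Satterthwaite denominator df for ``contrast @ beta``.

    Returns ``(var_contrast, df)`` for a random-intercept model with
    variance components ``(sigma_a2, sigma_e2)``, using the expected
    REML information of the components:
    ``df = 2 g^2 / (grad' I^{-1} grad)`` with ``g = Var(c'beta)``.
    """
    n = len(X)
    uniq = pd.unique(groups)
    Vinv = np.zeros((n, n))
    Z = np.zeros((n, len(uniq)))
    sigma_e2 = max(sigma_e2, 1e-10)
    for j, g in enumerate(uniq):
        idx = np.flatnonzero(groups == g)
        ni = len(idx)
        Z[idx, j] = 1.0
        # (sigma_e2 I + sigma_a2 J)^-1 via Sherman-Morrison
        block = np.eye(ni) / sigma_e2 - (
            sigma_a2 / (sigma_e2 * (sigma_e2 + ni * sigma_a2))
        ) * np.ones((ni, ni))
        Vinv[np.ix_(idx, idx)] = block

    XtVinv = X.T @ Vinv
    A = np.linalg.inv(XtVinv @ X)
    var_c = float(contrast @ A @ contrast)

    # dV/d(sigma_a2) = Z Z', dV/d(sigma_e2) = I
    dV = [Z @ Z.T, np.eye(n)]
    grad = np.array([float(contrast @ A @ (XtVinv @ dVj @ XtVinv.T) @ A @ contrast) for dVj in dV])

    P = Vinv - XtVinv.T @ A @ XtVinv
    info = np.empty((2, 2))
    PdV = [P @ dVj for dVj in dV]
    for j in range(2):
        for k in range(j, 2):
            info[j, k] = info[k, j] = 0.5 * float(np.trace(PdV[j] @ PdV[k]))
    try:
        denom = float(grad @ np.linalg.solve(info, grad))
    except np.linalg.LinAlgError:
        denom = np.nan
    df = 2.0 * var_c**2 / denom if denom and denom > 0 else float(n - X.shape[1])
    return var_c, df


def hedges_g(
    estimate: float, random_intercept_var: float, residual_var: float, df: float
) -> float:
    """Hedges' g with the small-sample correction ``J = 1 - 3/(4 df - 1)``.

    The standardizer is the total model SD,
    ``sqrt(random_intercept_var + residual_var)`` — the mixed-model
    analogue of a pooled SD.  Zero total variance yields NaN with a
    warning.
    """
    if random_intercept_var < 0 or residual_var < 0:
        raise ValueError("variances must be >= 0")
    total = random_intercept_var + residual_var
    if total <= 0:
        warnings.warn("total variance is zero; Hedges' g undefined")
        return float("nan")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(j * estimate / math.sqrt(total))


@dataclass
class LMMResult:
    """One feature's mixed-model contrast (headache minus headache-free)."""

    feature: str
    transform: str  # identity | log1p
    estimate: float  # on the analysis scale
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    df_method: str
    hedges_g: float
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_participants: int

    def summary(self) -> str:
        scale = "log(1+x) scale" if self.transform == "log1p" else "original scale"
        return (
            f"{self.feature} ({scale}): headache-minus-no-headache difference "
            f"{self.estimate:.4f} (95% CI {self.ci_low:.4f} to {self.ci_high:.4f}), "
            f"p={self.p_value:.3f} (Satterthwaite df={self.df:.1f}), "
            f"Hedges' g={self.hedges_g:.3f} "
            f"[var(intercept)={self.random_intercept_var:.4f}, "
            f"var(resid)={self.residual_var:.4f}, "
            f"n={self.n_obs} nights / {self.n_participants} participants]"
        )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


class NightlyContrastLMM:
    """Random-intercept mixed model for one night-level wearable measure.

    Parameters
    ----------
    data : DataFrame
        Columns ``value``, ``headache`` (0/1 for the following day) and
        ``participant``.
    transform : {"auto", "identity", "log1p"}
        ``auto`` applies log1p when the sample skewness of ``value``
        exceeds 1 (clear right skew), otherwise the original scale.
    feature : str
        Name used in reports.
    """

    SKEW_THRESHOLD = 1.0

    def __init__(self, data: pd.DataFrame, transform: str = "auto", feature: str = "value"):
        req = {"value", "headache", "participant"}
        if not req <= set(data.columns):
            raise ValueError(f"data must have columns {sorted(req)}")
        self.data = data.dropna(subset=["value", "headache", "participant"]).copy()
        if self.data["headache"].nunique() < 2:
            raise ValueError("both headache and headache-free nights are required")
        self.feature = feature
        if transform == "auto":
            transform = (
                "log1p"
                if stats.skew(self.data["value"].to_numpy(), bias=False) > self.SKEW_THRESHOLD
                else "identity"
            )
        if transform not in ("identity", "log1p"):
            raise ValueError("transform must be auto, identity or log1p")
        self.transform = transform

    @classmethod
    def from_night_summaries(
        cls, summaries: pd.DataFrame, diary: pd.DataFrame, feature: str, transform: str = "auto"
    ) -> "NightlyContrastLMM":
        d = diary.rename(columns={"date": "night_date"})
        merged = summaries.merge(
            d[["participant_id", "night_date", "headache"]],
            on=["participant_id", "night_date"],
            how="inner",
        )
        return cls(
            merged.rename(
                columns={feature: "value", "participant_id": "participant"}
            )[["value", "headache", "participant"]],
            transform=transform,
            feature=feature,
        )

    def fit(self) -> LMMResult:
        d = self.data.copy()
        if self.transform == "log1p":
            if (d["value"] < 0).any():
                raise ValueError("log1p transform requires non-negative values")
            d["value"] = np.log1p(d["value"])
        n_groups = d["participant"].nunique()
        if n_groups < 2:
            warnings.warn("single participant: random-intercept variance is degenerate")

        if float(d["value"].std()) == 0.0:
            # constant outcome: difference is exactly 0 with no variance
            return LMMResult(
                feature=self.feature, transform=self.transform, estimate=0.0, se=0.0,
                ci_low=0.0, ci_high=0.0, p_value=1.0, df=float(len(d) - 2),
                df_method="satterthwaite", hedges_g=0.0, random_intercept_var=0.0,
                residual_var=0.0, n_obs=len(d), n_participants=n_groups,
            )

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("value ~ headache", d, groups=d["participant"])
            # Powell is slower but reliably reaches the REML optimum where
            # the default gradient method can stall near a variance boundary
            res = md.fit(reml=True, method="powell")
        est = float(res.fe_params["headache"])
        sigma_a2 = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
        sigma_e2 = float(res.scale)

        X = np.column_stack([np.ones(len(d)), d["headache"].to_numpy(dtype=float)])
        var_c, df = _satterthwaite_df(
            X, d["participant"].to_numpy(), sigma_a2, sigma_e2, np.array([0.0, 1.0])
        )
        se = math.sqrt(var_c)
        tval = est / se if se > 0 else np.inf
        p = float(2.0 * stats.t.sf(abs(tval), df))
        tq = float(stats.t.ppf(0.975, df))
        g = hedges_g(est, sigma_a2, sigma_e2, df)
        return LMMResult(
            feature=self.feature,
            transform=self.transform,
            estimate=est,
            se=se,
            ci_low=est - tq * se,
            ci_high=est + tq * se,
            p_value=p,
            df=float(df),
            df_method="satterthwaite",
            hedges_g=g,
            random_intercept_var=sigma_a2,
            residual_var=sigma_e2,
            n_obs=len(d),
            n_participants=n_groups,
        )


def fit_night_lmm(
    values: pd.Series | np.ndarray,
    headache: pd.Series | np.ndarray,
    participants: pd.Series | np.ndarray,
    transform: str = "auto",
    feature: str = "value",
) -> LMMResult:
    """Array-style convenience wrapper around :class:`NightlyContrastLMM`."""
    data = pd.DataFrame(
        {"value": np.asarray(values, dtype=float),
         "headache": np.asarray(headache),
         "participant": np.asarray(participants)}
    )
    return NightlyContrastLMM(data, transform=transform, feature=feature).fit()


# ---------------------------------------------------------------------------
# participant-level correlations


def participant_summaries(
    night_summaries: pd.DataFrame, qc: pd.DataFrame | None = None, metrics=None
) -> pd.DataFrame:
    """Average nightly wearable metrics over usable nights per participant."""
    df = night_summaries
    if qc is not None:
        usable = qc[qc["usable"]][["participant_id", "night_date"]]
        df = df.merge(usable, on=["participant_id", "night_date"], how="inner")
    if metrics is None:
        metrics = [
            c
            for c in df.columns
            if c not in ("participant_id", "night_date") and pd.api.types.is_numeric_dtype(df[c])
        ]
    return df.groupby("participant_id", as_index=False)[list(metrics)].mean()


def spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman's rho.

    Enumerates all n! assignments of y to x (midrank ties preserved);
    p is the fraction with |rho| >= |observed rho|.  Intended for
    n <= 8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(_rank_corr(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(_rank_corr(rx, ry[list(perm)]))
        count += r >= obs - 1e-12
        total += 1
    return count / total


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = float(np.sqrt((rx_c**2).sum() * (ry_c**2).sum()))
    if denom == 0:
        return float("nan")
    return float((rx_c * ry_c).sum() / denom)


def spearman_with_proms(
    summaries: pd.DataFrame,
    proms: pd.DataFrame,
    wearable_metrics=None,
    prom_cols=("wpi", "sss", "fm_score", "midas", "promis_fatigue_t", "promis_sleep_t"),
    exact_max_n: int = 8,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Spearman correlations of participant-level means against PROMs.

    Missing PROMs (e.g. MIDAS "N/A") are dropped pairwise; each
    correlation needs at least 3 complete pairs.  p-values are
    two-sided and by default uncorrected (exploratory convention):
    exact permutation enumeration at ``n <= exact_max_n``, the t
    approximation otherwise.  ``bonferroni=True`` adds a
    ``p_adjusted`` column (p times the number of defined tests, capped
    at 1).  Constant vectors yield NaN rho with ``defined=False``.
    """
    merged = summaries.merge(proms, on="participant_id", how="inner")
    if wearable_metrics is None:
        wearable_metrics = [
            c
            for c in summaries.columns
            if c != "participant_id" and pd.api.types.is_numeric_dtype(summaries[c])
        ]
    rows = []
    for metric in wearable_metrics:
        for prom in prom_cols:
            sub = merged[[metric, prom]].dropna()
            n = len(sub)
            if n < 3:
                rows.append(
                    {"metric": metric, "prom": prom, "rho": np.nan, "p_value": np.nan,
                     "n": n, "defined": False}
                )
                continue
            x = sub[metric].to_numpy(dtype=float)
            y = sub[prom].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append(
                    {"metric": metric, "prom": prom, "rho": np.nan, "p_value": np.nan,
                     "n": n, "defined": False}
                )
                continue
            rho = _rank_corr(stats.rankdata(x), stats.rankdata(y))
            if n <= exact_max_n:
                p = spearman_exact_p(x, y)
            else:
                p = float(stats.spearmanr(x, y).pvalue)
            rows.append(
                {"metric": metric, "prom": prom, "rho": rho, "p_value": p, "n": n,
                 "defined": True}
            )
    out = pd.DataFrame(rows)
    if bonferroni and not out.empty:
        m = int(out["defined"].sum())
        out["p_adjusted"] = np.minimum(out["p_value"] * m, 1.0)
    return out


def correlation_matrix(correlations: pd.DataFrame, value: str = "rho") -> pd.DataFrame:
    """Pivot the long correlation table into a metric × PROM matrix."""
    return correlations.pivot(index="metric", columns="prom", values=value)
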