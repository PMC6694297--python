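"""Longitudinal statistics on the network metric tables.

The central model is the linear mixed-effects regression

    y_s = b0 + b1*group + b2*age + b3*group*age + b4_s + e

with a subject random intercept ``b4_s`` and residual ``e``, fitted by REML;
fixed-effect p-values are two-sided Wald tests.  When the interaction is
significant (p < 0.05) each group is refitted separately with age as the only
predictor.  Cross-sectional group differences per timepoint use
Kruskal-Wallis tests with Benjamini-Hochberg FDR correction (tendency at
corrected p < 0.1, significance at corrected p < 0.05), and brain-behavior
association uses Spearman correlation per group x timepoint (significant at
uncorrected p < 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LMEResult",
    "GroupTestResult",
    "fit_lme",
    "fit_lme_per_group",
    "analyze_metric",
    "kruskal_wallis",
    "bh_fdr",
    "significance_tier",
    "group_tests",
    "spearman_behavior",
    "fisher_z",
]

ALPHA = 0.05
TENDENCY = 0.1


@dataclass
class LMEResult:
    """Fixed effects, their SEs and Wald p-values, and the variance
    components of one mixed-model fit."""

    response: str
    terms: tuple[str, ...]
    estimates: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    sigma_subject: float
    sigma_resid: float
    n_obs: int
    n_subjects: int
    converged: bool

    def as_dict(self) -> dict:
        out = {"response": self.response, "n_obs": self.n_obs,
               "n_subjects": self.n_subjects, "converged": self.converged,
               "sigma_subject": self.sigma_subject,
               "sigma_resid": self.sigma_resid}
        for i, t in enumerate(self.terms):
            out[f"beta_{t}"] = float(self.estimates[i])
            out[f"se_{t}"] = float(self.std_errors[i])
            out[f"p_{t}"] = float(self.p_values[i])
        return out

    def p(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])

    def beta(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])


def _fit_mixed(df: pd.DataFrame, exog: np.ndarray, terms: tuple[str, ...],
               response: str, value_col: str) -> LMEResult:
    y = df[value_col].to_numpy(dtype=float)
    groups = df["subject_id"].to_numpy()
    model = MixedLM(y, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance warnings are expected
        res = model.fit(reml=True)
    k = exog.shape[1]
    return LMEResult(
        response=response,
        terms=terms,
        estimates=np.asarray(res.params[:k], dtype=float),
        std_errors=np.asarray(res.bse[:k], dtype=float),
        p_values=np.asarray(res.pvalues[:k], dtype=float),
        sigma_subject=float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0))),
        sigma_resid=float(np.sqrt(max(res.scale, 0.0))),
        n_obs=int(len(y)),
        n_subjects=int(pd.unique(groups).size),
        converged=bool(getattr(res, "converged", True)),
    )


def _check_lme_input(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    df = df.dropna(subset=[value_col])
    counts = df.groupby("subject_id").size()
    if (counts >= 2).sum() < 2:
        raise ValueError(
            "need at least 2 subjects with at least 2 observations each")
    if not set(df["group"].unique()) <= {0, 1}:
        raise ValueError("group must be coded 0 (WT) / 1 (Tg)")
    return df


def fit_lme(df: pd.DataFrame, value_col: str = "amplitude",
            response: str | None = None, center_age: bool = False) -> LMEResult:
    """Fit ``value ~ group + age + group:age`` with a subject random
    intercept (REML).  ``df`` holds one network x metric in long format with
    columns subject_id, group, age_months and the value column; rows with a
    missing value are excluded."""
    df = _check_lme_input(df, value_col)
    age = df["age_months"].to_numpy(dtype=float)
    if center_age:
        age = age - age.mean()
    grp = df["group"].to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(df)), grp, age, grp * age])
    return _fit_mixed(df, exog, ("intercept", "group", "age", "group_x_age"),
                      response or value_col, value_col)


def fit_lme_per_group(df: pd.DataFrame, value_col: str = "amplitude",
                      response: str | None = None) -> LMEResult:
    """Age-only mixed model for the rows of a single group."""
    if df["group"].nunique() != 1:
        raise ValueError("per-group fit expects rows of exactly one group")
    df = df.dropna(subset=[value_col])
    age = df["age_months"].to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(df)), age])
    return _fit_mixed(df, exog, ("intercept", "age"),
                      response or value_col, value_col)


def analyze_metric(df: pd.DataFrame, value_col: str = "amplitude",
                   alpha: float = ALPHA) -> dict:
    """Full-cohort LME plus, only when the interaction is significant at
    ``alpha``, the per-group age-only follow-up fits."""
    full = fit_lme(df, value_col)
    out = {"full": full, "per_group": {}}
    if full.p("group_x_age") < alpha:
        for g, sub in df.groupby("group"):
            out["per_group"][int(g)] = fit_lme_per_group(sub, value_col)
    return out


def kruskal_wallis(*samples: np.ndarray, exact: bool = False
                   ) -> tuple[float, float]:
    """Rank-based H test with tie correction.

    By default p comes from the chi-square approximation (df = k-1); with
    ``exact=True`` (two samples of <= 8 each) p is the exact permutation
    tail probability P(H >= h) over all label assignments — the small-sample
    oracle.  When every value is identical across samples the statistic is 0
    and the conventional p = 1 is returned (with a warning).
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 samples with n >= 2 each")
    if np.unique(np.concatenate(arrays)).size == 1:
        warnings.warn("all values identical; H = 0, p = 1 by convention")
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    if exact:
        if len(arrays) != 2 or max(a.size for a in arrays) > 8:
            raise ValueError("exact mode supports two samples of <= 8 each")
        from itertools import combinations
        pooled = np.concatenate(arrays)
        n1 = arrays[0].size
        count = total = 0
        for idx in combinations(range(pooled.size), n1):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(idx)] = True
            h_perm, _ = sps.kruskal(pooled[mask], pooled[~mask])
            total += 1
            if h_perm >= h - 1e-12:
                count += 1
        p = count / total
    return float(h), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_tier(p_fdr: float, alpha: float = ALPHA,
                      tendency: float = TENDENCY) -> str:
    if p_fdr < alpha:
        return "significant"
    if p_fdr < tendency:
        return "tendency"
    return "none"


@dataclass
class GroupTestResult:
    timepoint: str
    network: str
    metric: str
    h_statistic: float
    p_raw: float
    p_fdr: float = math.nan
    tier: str = "none"


def group_tests(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = ("amplitude", "shape"),
    alpha: float = ALPHA,
    tendency: float = TENDENCY,
) -> pd.DataFrame:
    """Per-timepoint WT-vs-Tg Kruskal-Wallis tests for each network and
    metric, with BH-FDR applied across timepoints within one
    network x metric family."""
    results: list[GroupTestResult] = []
    for metric in metrics:
        for network, sub in table.groupby("network", sort=True):
            fam: list[GroupTestResult] = []
            for tp, tpsub in sub.groupby("timepoint", sort=True):
                a = tpsub.loc[tpsub["group"] == 0, metric].dropna().to_numpy()
                b = tpsub.loc[tpsub["group"] == 1, metric].dropna().to_numpy()
                if a.size < 2 or b.size < 2:
                    warnings.warn(
                        f"{network}/{metric}/{tp}: insufficient data, skipped")
                    continue
                h, p = kruskal_wallis(a, b)
                fam.append(GroupTestResult(tp, network, metric, h, p))
            if not fam:
                continue
            adj = bh_fdr([r.p_raw for r in fam])
            for r, q in zip(fam, adj):
                r.p_fdr = float(q)
                r.tier = significance_tier(q, alpha, tendency)
            results.extend(fam)
    return pd.DataFrame([r.__dict__ for r in results])


def spearman_behavior(
    metric_table: pd.DataFrame,
    behavior: pd.DataFrame,
    metrics: tuple[str, ...] = ("amplitude", "shape"),
    measures: tuple[str, ...] = ("n_trials", "correct_ratio"),
    alpha: float = ALPHA,
    min_n: int = 4,
) -> pd.DataFrame:
    """Spearman rank correlation between network metrics and behavioral
    scores, stratified by group x timepoint x network; flagged at
    uncorrected p < ``alpha``.  Strata with fewer than ``min_n`` matched
    subjects are skipped with a warning."""
    merged = metric_table.merge(behavior, on=["subject_id", "timepoint"],
                                how="inner")
    rows = []
    for (g, tp, net), sub in merged.groupby(["group", "timepoint", "network"],
                                            sort=True):
        for metric in metrics:
            for meas in measures:
                ok = sub[[metric, meas]].dropna()
                if len(ok) < min_n:
                    warnings.warn(
                        f"group {g}/{tp}/{net}: n={len(ok)} < {min_n}, skipped")
                    continue
                rho, p = sps.spearmanr(ok[metric], ok[meas])
                rows.append({
                    "group": int(g), "timepoint": tp, "network": net,
                    "metric": metric, "measure": meas,
                    "spearman_rho": float(rho), "p_value": float(p),
                    "significant": bool(p < alpha),
                })
    return pd.DataFrame(rows)


def fisher_z(r) -> np.ndarray:
    """Fisher z-transform for correlation responses entering the LME."""
    return np.arctanh(np.clip(np.asarray(r, dtype=float), -0.999999, 0.999999))
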