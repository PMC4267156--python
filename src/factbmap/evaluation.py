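"""Goodness-of-fit and validation statistics for utility mappings.

Because R² is only well defined for OLS, model accuracy is summarized by the
squared Pearson correlation r² between observed and predicted utilities
(equal to R² under OLS), penalized for complexity as

    adjusted r² = 1 - (n - 1)/(n - p - 1) * (1 - r²),

with p the number of covariates excluding the intercept, plus the mean
squared error and mean absolute deviation of observed - predicted.

Validation against an external wave compares observed and predicted
utilities within self-assessed performance-status groups (0, 1, 2, "3 or 4"):
Wilcoxon signed-rank tests within groups, Cuzick's nonparametric trend test
of the predictions across groups, and group-mean discrepancies judged
against the minimally important difference (MID) of the EQ-5D for cancer
patients (0.08 for the UK value set, 0.06 for the US one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import DegenerateGroupsError, SchemaError, UndefinedCorrelationError
from .estimators import Cohort, FittedMapping, build_design, predict

#: minimally important differences of the EQ-5D utility for cancer patients
MID_THRESHOLDS = {"UK": 0.08, "US": 0.06}

#: performance-status groups used for validation; 3 and 4 are merged
STATUS_GROUPS: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("0", (0,)),
    ("1", (1,)),
    ("2", (2,)),
    ("3 or 4", (3, 4)),
)


# ---------------------------------------------------------------------------
# goodness of fit


@dataclass(frozen=True)
class GofReport:
    r2: float
    adjusted_r2: float
    mse: float
    mad: float
    n: int
    p: int

    def as_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "mse": self.mse,
            "mad": self.mad,
            "n": self.n,
            "p": self.p,
        }


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Complexity-penalized r²; p counts covariates excluding the intercept."""
    if n <= p + 1:
        raise SchemaError(f"adjusted r² undefined for n={n}, p={p}")
    return 1.0 - (n - 1) / (n - p - 1) * (1.0 - r2)


def gof(observed: Sequence[float], predicted: Sequence[float], p: int) -> GofReport:
    """Goodness-of-fit report from paired observed/predicted utilities.

    r² is the squared Pearson correlation (symmetric in its arguments);
    MSE/MAD are moments of observed − predicted.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise SchemaError("observed and predicted must be equal-length vectors")
    n = len(obs)
    if n <= p + 1:
        raise SchemaError(f"need n > p + 1 (n={n}, p={p})")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    r = np.corrcoef(obs, pred)[0, 1]
    r2 = float(r * r)
    resid = obs - pred
    return GofReport(
        r2=r2,
        adjusted_r2=float(adjusted_r2(r2, n, p)),
        mse=float(np.mean(resid**2)),
        mad=float(np.mean(np.abs(resid))),
        n=n,
        p=p,
    )


def describe(values: Sequence[float], floor: float | None = None) -> dict[str, float]:
    """Distribution summary: mean, SD, min, P10, Q1, median, Q3, P90, max,
    and the fractions exactly at the floor and at the ceiling 1 (within 1e-12)."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise SchemaError("cannot describe an empty vector")
    out = {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "min": float(np.min(v)),
        "p10": float(np.percentile(v, 10)),
        "q1": float(np.percentile(v, 25)),
        "median": float(np.median(v)),
        "q3": float(np.percentile(v, 75)),
        "p90": float(np.percentile(v, 90)),
        "max": float(np.max(v)),
        "ceiling_fraction": float(np.mean(np.abs(v - 1.0) <= 1e-12)),
    }
    out["floor_fraction"] = (
        float(np.mean(np.abs(v - floor) <= 1e-12)) if floor is not None else 0.0
    )
    return out


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test (exact branch via DP over doubled midranks)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p under the sign-flip null: P(|W+ - S/2| >= |w - S/2|).

    Works with tied (mid)ranks: ranks are doubled to integers and the null
    distribution of 2·W+ is built by dynamic programming over sign vectors.
    """
    r2 = np.rint(2 * ranks).astype(int)
    S2 = int(r2.sum())
    counts = np.zeros(S2 + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: S2 + 1 - r]
        counts = counts + shifted
    total = counts.sum()  # 2^n
    w2 = int(round(2 * w_plus))
    dev = abs(2 * w2 - S2)  # |2W+ - S| doubled-scale deviation from center
    devs = np.abs(2 * np.arange(S2 + 1) - S2)
    return float(counts[devs >= dev].sum() / total)


def signed_rank_test(
    observed: Sequence[float], predicted: Sequence[float], exact_limit: int = 25
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired vectors.

    Zero differences are dropped before ranking (Wilcoxon convention); if all
    differences are zero the test returns p = 1. The exact null distribution
    (enumeration of sign flips, tie-aware) is used for up to ``exact_limit``
    nonzero pairs, the normal approximation with continuity and tie
    correction beyond.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size == 0:
        raise SchemaError("paired vectors of equal nonzero length required")
    d = obs - pred
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        return _signed_rank_exact_p(ranks, w_plus)
    mean_w = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    dev = abs(w_plus - mean_w)
    z = max(dev - 0.5, 0.0) / np.sqrt(var_w)  # continuity correction toward the mean
    return float(2 * norm.sf(z))


# ---------------------------------------------------------------------------
# Cuzick's nonparametric test for trend across ordered groups


def cuzick_trend(
    values: Sequence[float],
    group_scores: Sequence[float],
    n_permutations: int | None = None,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Cuzick's rank test for trend across ordered groups.

    ``group_scores`` assigns each observation its group's ordinal score.
    The statistic T = sum(score_i * rank_i) is standardized by its exact
    null moments under random permutation of the (mid)ranks, which
    tie-corrects the variance. Returns ``(z, p_two_sided, p_one_sided)``;
    the one-sided p is for trend in the direction of the observed z.

    By default p-values use the asymptotic normal reference (the test's
    usual form). Pass ``n_permutations`` to replace them with a seeded
    Monte-Carlo permutation null — preferable for very small groups, where
    the normal tail approximation is poor.
    """
    v = np.asarray(values, float)
    g = np.asarray(group_scores, float)
    if v.shape != g.shape or v.ndim != 1:
        raise SchemaError("values and group_scores must be equal-length vectors")
    scores = np.unique(g)
    if len(scores) < 2:
        raise DegenerateGroupsError("trend test needs at least 2 distinct groups")
    N = len(v)
    ranks = rankdata(v)
    T = float(np.sum(g * ranks))
    rank_mean = ranks.mean()  # (N+1)/2
    rank_var = float(np.sum((ranks - rank_mean) ** 2)) / (N - 1)
    sum_l = float(g.sum())
    sum_l2 = float(np.sum(g**2))
    mean_T = rank_mean * sum_l
    var_T = rank_var * (sum_l2 - sum_l**2 / N)
    if var_T <= 0:
        return 0.0, 1.0, 1.0
    z = (T - mean_T) / np.sqrt(var_T)
    if n_permutations is not None:
        rng = np.random.default_rng(seed)
        perms = np.array([(g * rng.permutation(ranks)).sum() for _ in range(n_permutations)])
        dev = np.abs(T - mean_T)
        p_two = float(np.mean(np.abs(perms - mean_T) >= dev - 1e-12))
        p_one = float(np.mean(np.sign(z) * (perms - mean_T) >= dev - 1e-12))
        return float(z), p_two, p_one
    p_two = float(2 * norm.sf(abs(z)))
    p_one = float(norm.sf(abs(z)))
    return float(z), p_two, p_one


# ---------------------------------------------------------------------------
# validation by performance status


@dataclass
class ValidationTable:
    """Observed vs predicted mean utilities by performance-status group."""

    table: pd.DataFrame  # one row per (model, group)
    trend: pd.DataFrame  # one row per model: z, p for trend of predictions
    max_abs_discrepancy: float
    mid_flags: pd.DataFrame  # discrepancy vs MID thresholds
    skipped_groups: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def validate_by_status(
    cohort: Cohort | pd.DataFrame,
    mappings: Mapping[str, FittedMapping] | Sequence[FittedMapping],
    mid_thresholds: Mapping[str, float] = MID_THRESHOLDS,
) -> ValidationTable:
    """Validation battery on a cohort with a performance-status column.

    For each mapping and status group (0, 1, 2, "3 or 4"): group means of
    observed and predicted utility on the same subjects, the signed-rank
    p-value of their paired differences, Cuzick's trend test of predictions
    across groups (scores 0,1,2,3 with the merged group scored 3), the
    table-wide max |observed − predicted| group-mean discrepancy, and flags
    of each discrepancy against the MID thresholds.
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    if "status" not in df.columns:
        raise SchemaError("validation cohort needs a 'status' column")
    if isinstance(mappings, Mapping):
        named = dict(mappings)
    else:
        named = {f"{m.method}:{m.spec.name or i}": m for i, m in enumerate(mappings)}

    rows = []
    trend_rows = []
    skipped: list[str] = []
    max_disc = 0.0
    mid_rows = []
    for name, mapping in named.items():
        needed = list(mapping.spec.terms) + ["utility", "status"]
        sub = df[needed].dropna()
        pred = np.asarray(predict(mapping, sub[list(mapping.spec.terms)]), float)
        obs = sub["utility"].to_numpy(float)
        status = sub["status"].to_numpy(int)
        group_score = np.empty(len(sub), float)
        group_label = np.empty(len(sub), object)
        for score, (label, levels) in enumerate(STATUS_GROUPS):
            in_g = np.isin(status, levels)
            group_score[in_g] = score
            group_label[in_g] = label
        for score, (label, levels) in enumerate(STATUS_GROUPS):
            in_g = np.isin(status, levels)
            if not in_g.any():
                if label not in skipped:
                    skipped.append(label)
                continue
            disc = float(np.mean(obs[in_g]) - np.mean(pred[in_g]))
            max_disc = max(max_disc, abs(disc))
            rows.append(
                {
                    "model": name,
                    "group": label,
                    "n": int(in_g.sum()),
                    "observed_mean": float(np.mean(obs[in_g])),
                    "predicted_mean": float(np.mean(pred[in_g])),
                    "discrepancy": disc,
                    "signed_rank_p": signed_rank_test(obs[in_g], pred[in_g]),
                }
            )
            for region, thr in mid_thresholds.items():
                mid_rows.append(
                    {
                        "model": name,
                        "group": label,
                        "mid": region,
                        "threshold": thr,
                        "within_mid": bool(abs(disc) < thr),
                    }
                )
        z, p_two, p_one = cuzick_trend(pred, group_score)
        trend_rows.append({"model": name, "z": z, "p_two_sided": p_two, "p_one_sided": p_one})
    return ValidationTable(
        table=pd.DataFrame(rows),
        trend=pd.DataFrame(trend_rows),
        max_abs_discrepancy=max_disc,
        mid_flags=pd.DataFrame(mid_rows),
        skipped_groups=skipped,
    )


def max_group_mean_discrepancy(table: pd.DataFrame) -> float:
    """Largest |observed − predicted| over a wide table of group means.

    ``table`` must contain one ``observed`` row (method column == 'observed')
    and model rows sharing the same group-mean columns — the layout of the
    published follow-up means shipped with the package.
    """
    value_cols = [c for c in table.columns if c.startswith("status")]
    if not value_cols or "method" not in table.columns:
        raise SchemaError("expected a 'method' column and status_* group-mean columns")
    obs = table[table["method"] == "observed"]
    if len(obs) != 1:
        raise SchemaError("expected exactly one observed row")
    obs_vals = obs[value_cols].to_numpy(float)[0]
    models = table[table["method"] != "observed"]
    diffs = np.abs(models[value_cols].to_numpy(float) - obs_vals)
    return float(diffs.max())
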