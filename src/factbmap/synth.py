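"""Synthetic breast-cancer cohorts for testing and simulation.

The generator emulates the marginal structure of a baseline survey of
breast-cancer patients: FACT-B subscale scores with realistic means and
spreads, an EQ-5D-5L utility bounded at 1 with a substantial ceiling mass,
and a self-assessed performance status (0-4) that decreases in health.

Generative model (all randomness behind one seed):

1. Correlated latent well-being: a 5-vector with exchangeable correlation
   rho across subscales, scaled to the configured subscale means/SDs, then
   rounded half-up and clamped to each subscale's integer range.
2. Latent utility = intercept + sum(coef * subscale) + Gaussian noise,
   using a configurable "true" mapping (default: the published OLS Model 4
   coefficient set).
3. Ceiling: under the default ``latent-censor`` rule the top
   ``target_ceiling_fraction`` of latent utilities is mapped to exactly 1
   (censoring at the empirical quantile), mimicking the gap between full
   health and the next-best value-set state; ``clip`` instead top-codes at
   1 and the ceiling mass is whatever the linear model implies.
4. Performance status by cutting the latent utility at quantiles matched to
   the target status mix (worst group split half/half into statuses 3 and 4).

Cohorts carry both the bounded ``utility`` and the uncensored
``latent_utility``, so parameter-recovery experiments can target whichever
scale an estimator is consistent for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .estimators import Cohort, FittedMapping, published_mapping
from .scoring import SUBSCALE_MAXIMA, SUBSCALES, ItemManifest, default_manifest

#: baseline subscale means and SDs the defaults emulate (PWB,SWB,EWB,FWB,BCS)
DEFAULT_SUBSCALE_MEANS = (21.1, 22.2, 18.0, 20.0, 21.7)
DEFAULT_SUBSCALE_SDS = (6.0, 6.1, 4.74, 6.70, 6.15)

#: baseline self-assessed performance-status mix for groups 0,1,2,"3 or 4"
DEFAULT_STATUS_FREQUENCIES = (0.408, 0.483, 0.071, 0.038)


@dataclass
class SynthConfig:
    """Configuration of the synthetic cohort generator (defaults = the
    baseline study conditions)."""

    n: int = 238
    seed: int = 0
    subscale_means: tuple[float, ...] = DEFAULT_SUBSCALE_MEANS
    subscale_sds: tuple[float, ...] = DEFAULT_SUBSCALE_SDS
    subscale_correlation: float = 0.4
    true_mapping: Optional[FittedMapping] = None  # None -> published OLS Model 4
    noise_sd: float = 0.08
    ceiling_rule: str = "latent-censor"  # or "clip"
    target_ceiling_fraction: float = 0.248
    status_frequencies: tuple[float, ...] = DEFAULT_STATUS_FREQUENCIES
    status_cutpoints: Optional[tuple[float, float, float]] = None  # ascending, latent scale

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if len(self.subscale_means) != 5 or len(self.subscale_sds) != 5:
            raise ConfigError("need 5 subscale means and 5 SDs")
        if not 0 <= self.subscale_correlation < 1:
            raise ConfigError("subscale_correlation must be in [0, 1)")
        if self.ceiling_rule not in ("latent-censor", "clip"):
            raise ConfigError(f"unknown ceiling_rule {self.ceiling_rule!r}")
        if not 0 <= self.target_ceiling_fraction < 1:
            raise ConfigError("target_ceiling_fraction must be in [0, 1)")
        if len(self.status_frequencies) != 4 or abs(sum(self.status_frequencies) - 1) > 1e-9:
            raise ConfigError("status_frequencies must be 4 values summing to 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def resolved_mapping(self) -> FittedMapping:
        return self.true_mapping if self.true_mapping is not None else published_mapping("ols", 4)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def generate_cohort(cfg: SynthConfig) -> Cohort:
    """Draw a fully reproducible synthetic cohort under ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    mapping = cfg.resolved_mapping()
    rho = cfg.subscale_correlation
    common = rng.standard_normal((cfg.n, 1))
    indiv = rng.standard_normal((cfg.n, 5))
    z = np.sqrt(rho) * common + np.sqrt(1 - rho) * indiv
    scores = {}
    for j, sub in enumerate(SUBSCALES):
        raw = cfg.subscale_means[j] + cfg.subscale_sds[j] * z[:, j]
        scores[sub] = np.clip(_round_half_up(raw), 0, SUBSCALE_MAXIMA[sub])
    df = pd.DataFrame(scores)
    noise = rng.normal(0.0, cfg.noise_sd, cfg.n) if cfg.noise_sd > 0 else np.zeros(cfg.n)
    latent = mapping.linear_index(df[list(mapping.spec.terms)].to_numpy(float)) + noise

    if cfg.ceiling_rule == "latent-censor" and cfg.target_ceiling_fraction > 0:
        threshold = float(np.quantile(latent, 1.0 - cfg.target_ceiling_fraction))
        if threshold >= 1.0:
            warnings.warn(
                "latent utilities already reach 1 below the target ceiling quantile; "
                "censoring at 1 instead",
                stacklevel=2,
            )
            threshold = 1.0
        at_ceiling = latent >= threshold
        if cfg.n > 1 and (at_ceiling.all() or not at_ceiling.any()):
            warnings.warn("ceiling target infeasible under this configuration", stacklevel=2)
        utility = np.where(at_ceiling, 1.0, latent)
    else:
        threshold = 1.0
        utility = np.minimum(latent, 1.0)

    cuts = cfg.status_cutpoints
    if cuts is None:
        f = cfg.status_frequencies
        qs = (f[3], f[3] + f[2], f[3] + f[2] + f[1])
        cuts = tuple(float(np.quantile(latent, q)) for q in qs)
    c1, c2, c3 = cuts
    if not c1 <= c2 <= c3:
        raise ConfigError("status cutpoints must be ascending")
    status = np.select([latent < c1, latent < c2, latent < c3], [3, 2, 1], default=0)
    # split the worst group into statuses 3 and 4: bottom half of its latent -> 4
    worst = status == 3
    if worst.sum() > 1:
        med = np.median(latent[worst])
        status[worst & (latent < med)] = 4

    out = pd.DataFrame(
        {
            "subject_id": np.arange(cfg.n),
            **{s: scores[s].astype(int) for s in SUBSCALES},
            "utility": utility,
            "latent_utility": latent,
            "status": status.astype(int),
        }
    )
    return Cohort(
        out,
        meta={
            "config": cfg,
            "censor_threshold": threshold,
            "status_cutpoints": cuts,
            "latent_sd": float(np.std(latent, ddof=1)) if cfg.n > 1 else 0.0,
        },
    )


def generate_followup(
    cohort: Cohort,
    cfg: SynthConfig,
    attrition: float = 0.07,
    drift_sd: float = 0.05,
) -> Cohort:
    """A follow-up wave: random retention plus small within-subject drift.

    Each retained subject's latent utility shifts by delta ~ N(0, drift_sd);
    subscales shift coherently by delta scaled to their own SDs (one latent
    utility SD corresponds to one subscale SD), then are re-rounded and
    clamped; the utility is re-censored at the baseline ceiling threshold and
    status re-derived from the baseline cutpoints. With attrition 0 and
    drift 0 the wave equals the baseline exactly.
    """
    if not 0 <= attrition < 1:
        raise ConfigError("attrition must be in [0, 1)")
    if drift_sd < 0:
        raise ConfigError("drift_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 982451653]))
    df = cohort.data
    keep = rng.random(len(df)) >= attrition if attrition > 0 else np.ones(len(df), bool)
    sub = df[keep].copy()
    latent = sub["latent_utility"].to_numpy(float)
    if drift_sd > 0:
        delta = rng.normal(0.0, drift_sd, len(sub))
        latent = latent + delta
        latent_sd = cohort.meta.get("latent_sd") or max(float(np.std(latent, ddof=1)), 1e-9)
        for j, s in enumerate(SUBSCALES):
            drifted = sub[s].to_numpy(float) + delta * cfg.subscale_sds[j] / latent_sd
            sub[s] = np.clip(_round_half_up(drifted), 0, SUBSCALE_MAXIMA[s]).astype(int)
    threshold = cohort.meta.get("censor_threshold", 1.0)
    utility = np.where(latent >= threshold, 1.0, np.minimum(latent, 1.0))
    cuts = cohort.meta.get("status_cutpoints")
    if cuts is not None:
        c1, c2, c3 = cuts
        status = np.select([latent < c1, latent < c2, latent < c3], [3, 2, 1], default=0)
        worst = status == 3
        if worst.sum() > 1:
            med = np.median(latent[worst])
            status[worst & (latent < med)] = 4
        sub["status"] = status.astype(int)
    sub["utility"] = utility
    sub["latent_utility"] = latent
    return Cohort(
        sub.reset_index(drop=True),
        meta=cohort.meta | {"wave": "follow-up", "attrition": attrition, "drift_sd": drift_sd},
    )


def generate_item_responses(
    profile_scores: Sequence[float],
    manifest: ItemManifest | None = None,
    seed: int = 0,
) -> dict[str, int]:
    """Raw item responses consistent with target subscale scores.

    For each subscale, a random composition of the (rounded) target total
    over its items is drawn, then converted to raw responses by undoing the
    reverse-scoring of negatively worded items. Intended for exercising the
    scoring pipeline, not for emulating realistic inter-item structure.
    """
    if manifest is None:
        manifest = default_manifest()
    rng = np.random.default_rng(seed)
    responses: dict[str, int] = {}
    for sub, target in zip(SUBSCALES, profile_scores):
        items = [it for it in manifest.items if it.subscale == sub]
        total = int(np.clip(round(target), 0, 4 * len(items)))
        vals = np.full(len(items), total // len(items))
        vals[: total % len(items)] += 1
        # random repair walk keeps the sum while spreading values over 0..4
        for _ in range(3 * len(items)):
            i, j = rng.integers(0, len(items), 2)
            if vals[i] < 4 and vals[j] > 0 and i != j:
                vals[i] += 1
                vals[j] -= 1
        assert vals.sum() == total and vals.min() >= 0 and vals.max() <= 4
        for it, v in zip(items, vals):
            responses[it.item_id] = int(4 - v if it.negatively_worded else v)
    return responses
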