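"""Grouped summaries, percent-change effect sizes and model-table export.

With only a handful of replicate pots per design cell, normal-theory
intervals are fragile; group summaries therefore carry percentile-bootstrap
confidence intervals (default 2,000 resamples over pots within the group).
The plain percentile interval is known to undercover at small n — it acts
like a z-interval built on the biased (ddof-0) standard deviation — so the
default applies Hesterberg's *expanded* percentile correction: the quantile
levels are widened from α/2 to Φ(−√(n/(n−1)) · t₁₋α/₂,ₙ₋₁), which restores
near-nominal coverage for means of small samples while remaining a pure
percentile-of-the-bootstrap-distribution interval.
The mixed-model layer itself (pot-level random intercepts, post-hoc
contrasts) is deliberately exported rather than fitted: ``export_model_table``
emits a tidy long-format table directly consumable by external mixed-model
software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryError",
    "GroupSummary",
    "bootstrap_ci",
    "group_summary",
    "group_summary_frame",
    "percent_change",
    "export_model_table",
]


class SummaryError(ValueError):
    """An ill-posed summary request (zero reference, duplicated pots, ...)."""


@dataclass
class GroupSummary:
    """Mean, SD and percentile-bootstrap CI of one variable in one group."""

    keys: dict[str, object]
    variable: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float


def bootstrap_ci(
    values: np.ndarray,
    reps: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    expand: bool = True,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean, deterministic given the seed.

    With ``expand=True`` (default) the quantile levels carry the small-sample
    expansion α/2 → Φ(−√(n/(n−1)) · t₁₋α/₂,ₙ₋₁), which corrects the plain
    percentile interval's undercoverage for means of small samples;
    ``expand=False`` gives the classical percentile interval.  For n = 1 no
    expansion is possible and the plain levels are used.

    With ``reps = 1`` the interval degenerates to a single resampled mean
    (both bounds equal); this is flagged at WARN level rather than rejected.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise SummaryError("cannot bootstrap an empty sample")
    if reps < 1:
        raise SummaryError("bootstrap reps must be >= 1")
    if reps == 1:
        logger.warning("bootstrap with reps=1 yields a degenerate (point) interval")
    n = values.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    if expand and n > 1:
        alpha = float(stats.norm.cdf(-np.sqrt(n / (n - 1)) * stats.t.ppf(1 - alpha, n - 1)))
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def group_summary(
    table: pd.DataFrame,
    keys: list[str],
    variable: str,
    bootstrap_reps: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> list[GroupSummary]:
    """Per-group mean, sample SD and bootstrap CI of one numeric variable.

    Groups are the distinct key combinations present in the table; rows with
    a missing value of the variable are dropped from their group, and groups
    left empty are omitted with a log entry.  Each group's bootstrap stream
    is seeded independently (derived from ``seed`` and the group order), so
    summaries are deterministic and independent of other groups' sizes.
    """
    for k in keys:
        if k not in table.columns:
            raise SummaryError(f"grouping key {k!r} not in table")
    if variable not in table.columns:
        raise SummaryError(f"variable {variable!r} not in table")
    summaries: list[GroupSummary] = []
    grouped = table.groupby(keys, sort=True, dropna=False)
    for gi, (key, sub) in enumerate(grouped):
        key_tuple = key if isinstance(key, tuple) else (key,)
        vals = sub[variable].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            logger.warning("group %s has no observations of %s; omitted", key_tuple, variable)
            continue
        child = int(np.random.SeedSequence(seed, spawn_key=(gi,)).generate_state(1)[0] % 2**31)
        lo, hi = bootstrap_ci(vals, reps=bootstrap_reps, seed=child, level=level)
        summaries.append(
            GroupSummary(
                keys=dict(zip(keys, key_tuple)),
                variable=variable,
                n=int(vals.size),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                ci_low=lo,
                ci_high=hi,
            )
        )
    return summaries


def group_summary_frame(
    table: pd.DataFrame,
    keys: list[str],
    variables: list[str],
    bootstrap_reps: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Tidy frame of :func:`group_summary` over several variables."""
    rows = []
    for vi, variable in enumerate(variables):
        child = int(
            np.random.SeedSequence(seed, spawn_key=(1000 + vi,)).generate_state(1)[0] % 2**31
        )
        for s in group_summary(table, keys, variable, bootstrap_reps, child, level):
            rows.append({**s.keys, "variable": s.variable, "n": s.n, "mean": s.mean,
                         "sd": s.sd, "ci_low": s.ci_low, "ci_high": s.ci_high})
    return pd.DataFrame(rows)


def percent_change(ref_mean: float, cmp_mean: float) -> float:
    """Percent change of a comparison mean against a reference mean.

    ``100 · (cmp − ref) / ref`` — the "x% greater" style of effect size.
    Undefined (raises) for a zero reference.
    """
    if ref_mean == 0:
        raise SummaryError("percent change undefined for a zero reference mean")
    return 100.0 * (cmp_mean - ref_mean) / ref_mean


#: pot-level response variables exported to the model table, in order
POT_RESPONSES = [
    "total_biomass_g",
    "mean_height_cm",
    "mean_sla_mm2_mg",
    "mean_srl_cm_g",
    "mean_rsr",
]
EFFECT_RESPONSES = ["nbe_g", "ce_g", "se_g"]


def export_model_table(
    pot_traits: pd.DataFrame, effects: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Tidy long table for external mixed-model fitting.

    One row per pot × response variable, with richness and treatment factors
    and the pot id as the grouping unit.  Pot-level trait/biomass responses
    come from ``pot_traits`` (all pots); partition effects, when supplied,
    add rows for the mixture pots.
    """
    if pot_traits["pot_id"].duplicated().any():
        dups = pot_traits.loc[pot_traits["pot_id"].duplicated(), "pot_id"].tolist()
        raise SummaryError(f"duplicated pot_id in pot table: {dups}")
    id_cols = ["pot_id", "richness", "drought", "biochar", "replicate"]
    missing = set(id_cols) - set(pot_traits.columns)
    if missing:
        raise SummaryError(f"pot table missing columns: {sorted(missing)}")
    responses = [c for c in POT_RESPONSES if c in pot_traits.columns]
    long = pot_traits.melt(
        id_vars=id_cols, value_vars=responses, var_name="variable", value_name="value"
    )
    if effects is not None and not effects.empty:
        if effects["pot_id"].duplicated().any():
            dups = effects.loc[effects["pot_id"].duplicated(), "pot_id"].tolist()
            raise SummaryError(f"duplicated pot_id in effects table: {dups}")
        eff = effects.merge(pot_traits[["pot_id", "replicate"]], on="pot_id", how="left")
        eff_long = eff.melt(
            id_vars=id_cols,
            value_vars=[c for c in EFFECT_RESPONSES if c in effects.columns],
            var_name="variable",
            value_name="value",
        )
        long = pd.concat([long, eff_long], ignore_index=True)
    return long.sort_values(["variable", "pot_id"], ignore_index=True)
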