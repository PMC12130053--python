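"""Synthetic greenhouse experiments with known biodiversity-effect structure.

The generator emulates the data-generating setting the analysis assumes: a
small species pool with species-specific monoculture biomass baselines μᵢ,
multiplicative drought (d ≤ 1) and biochar (b ≥ 1) treatment effects, a
per-richness complementarity boost γ(N) on per-capita yield, a dominance
skew s that biases mixture yields toward low- or high-baseline species
(injecting a selection effect of either sign), and multiplicative lognormal
measurement noise with a given coefficient of variation.

Species-level pot yield model (treatment-matched baselines cancel the
treatment multipliers inside the partition, so γ and s alone set the true
effects)::

    Y_oi = (1/N) · μᵢ · d^drought · b^biochar · γ(N) · wᵢ(s) · εᵢ

with wᵢ(s) ∝ exp(s · zᵢ), zᵢ the standardized rank of μᵢ within the
composition, normalized to mean 1, and εᵢ lognormal with mean 1 and CV = cv.
Monocultures use N = 1, γ = 1, w = 1.  Ground truth (the partition of the
noiseless yields) is exported alongside every generated table so parameter
recovery can be tested against it.

Traits are generated as species-level constants under the same multiplicative
noise; the root-to-shoot ratio is inflated under drought.  Traits do not feed
back into yields.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import DesignConfig, PotRecord, Treatment, enumerate_design
from .partition import (
    PartitionResult,
    partition,
    partition_dataset,
    partition_results_to_frames,
)
from .traits import INDIVIDUAL_COLUMNS, aggregate_pots

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorError",
    "PairingError",
    "GeneratorConfig",
    "SyntheticTruth",
    "default_config",
    "dominance_weights",
    "lognormal_noise",
    "generate_experiment",
    "recovery_report",
    "monte_carlo_recovery",
]


class GeneratorError(ValueError):
    """Invalid generator configuration."""


class PairingError(ValueError):
    """Estimates and truth come from incompatible configurations."""


# Defaults emulate a five-species arid-greenhouse pool: pot-level monoculture
# biomass of a few grams to ~15 g, drought cutting yield to 60%, biochar
# raising it by 30%, mild overyielding that grows with richness, and a
# negative dominance skew (low-baseline species overperform in mixture, so
# the selection effect is negative while complementarity stays positive).
_DEFAULT_MU = {"S1": 14.0, "S2": 11.0, "S3": 9.0, "S4": 7.0, "S5": 5.0}
_DEFAULT_HEIGHT = {"S1": 40.0, "S2": 34.0, "S3": 28.0, "S4": 22.0, "S5": 16.0}
_DEFAULT_SLA = {"S1": 12.0, "S2": 15.0, "S3": 18.0, "S4": 22.0, "S5": 26.0}
_DEFAULT_SRL = {"S1": 900.0, "S2": 1100.0, "S3": 1400.0, "S4": 1800.0, "S5": 2300.0}
_DEFAULT_RSR = {"S1": 0.35, "S2": 0.40, "S3": 0.45, "S4": 0.50, "S5": 0.55}
_DEFAULT_LEAF_MG = {"S1": 45.0, "S2": 38.0, "S3": 32.0, "S4": 26.0, "S5": 20.0}


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic experiment."""

    design: DesignConfig = field(default_factory=DesignConfig)
    mu_g: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MU))
    drought_mult: float = 0.6
    biochar_mult: float = 1.3
    gamma: dict[int, float] = field(default_factory=lambda: {1: 1.0, 2: 1.2, 4: 1.4})
    skew: float = -0.4
    cv: float = 0.15
    height_cm: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_HEIGHT))
    sla_mm2_mg: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SLA))
    srl_cm_g: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SRL))
    rsr: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RSR))
    leaf_dry_mass_mg: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_LEAF_MG))
    rsr_drought_inflation: float = 1.35
    seed: int = 0

    def validate(self) -> None:
        self.design.validate()
        pool = set(self.design.species_pool)
        for name in ("mu_g", "height_cm", "sla_mm2_mg", "srl_cm_g", "rsr", "leaf_dry_mass_mg"):
            table = getattr(self, name)
            missing = pool - set(table)
            if missing:
                raise GeneratorError(f"{name} missing species {sorted(missing)}")
            if any(v <= 0 for k, v in table.items() if k in pool):
                raise GeneratorError(f"{name} values must be strictly positive")
        if not (0 < self.drought_mult <= 1):
            raise GeneratorError("drought_mult must lie in (0, 1]")
        if self.biochar_mult < 1:
            raise GeneratorError("biochar_mult must be >= 1")
        if self.cv < 0:
            raise GeneratorError("cv must be >= 0")
        if any(g <= 0 for g in self.gamma.values()):
            raise GeneratorError("gamma multipliers must be strictly positive")
        if self.gamma.get(1, 1.0) != 1.0:
            raise GeneratorError("gamma(1) must equal 1 (monocultures have no boost)")
        if self.rsr_drought_inflation <= 0:
            raise GeneratorError("rsr_drought_inflation must be positive")
        if self.design.individuals_per_pot < max(self.design.richness_levels):
            raise GeneratorError(
                "individuals_per_pot must cover every species of the richest mixture"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = dataclasses.asdict(self.design)
        d["design"]["species_pool"] = list(self.design.species_pool)
        d["design"]["richness_levels"] = list(self.design.richness_levels)
        d["gamma"] = {int(k): float(v) for k, v in self.gamma.items()}
        return d

    @staticmethod
    def from_dict(data: dict) -> "GeneratorConfig":
        data = dict(data)
        design = data.pop("design", {})
        if isinstance(design, dict):
            design = DesignConfig(**design)
        gamma = data.pop("gamma", None)
        cfg = GeneratorConfig(design=design, **data)
        if gamma is not None:
            cfg.gamma = {int(k): float(v) for k, v in gamma.items()}
        return cfg


def default_config(seed: int = 0) -> GeneratorConfig:
    """The canonical five-species, {1,2,4}-richness, 2×2-treatment setting."""
    return GeneratorConfig(design=DesignConfig(seed=seed), seed=seed)


def dominance_weights(mu: np.ndarray, skew: float) -> np.ndarray:
    """Yield-bias weights w ∝ exp(skew · z), z the standardized rank of μ.

    Normalized to mean 1 across the composition, so the weights redistribute
    yield between species without changing the community-mean boost; skew < 0
    favours low-baseline species (negative selection effect), skew > 0
    high-baseline ones.  All-equal μ (or a single species) gives unit weights.
    """
    mu = np.asarray(mu, dtype=float)
    n = mu.size
    if n == 1 or skew == 0:
        return np.ones(n)
    ranks = rankdata(mu)
    sd = ranks.std()  # population sd; zero iff all mu tie
    if sd == 0:
        return np.ones(n)
    z = (ranks - ranks.mean()) / sd
    w = np.exp(skew * z)
    return w / w.mean()


def lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and CV = cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated experiment.

    ``per_pot`` holds the noiseless partition of every mixture pot;
    ``per_cell`` its mean over the replicate mixtures of each
    richness × treatment cell.  Both are what the pipeline would estimate at
    cv = 0, computed by running the partition itself on the noiseless yields.
    """

    per_pot: pd.DataFrame
    per_cell: pd.DataFrame
    params: dict

    def to_json(self, path) -> None:
        payload = {
            "params": self.params,
            "per_pot": self.per_pot.to_dict(orient="records"),
            "per_cell": self.per_cell.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @staticmethod
    def from_json(path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return SyntheticTruth(
            per_pot=pd.DataFrame(payload["per_pot"]),
            per_cell=pd.DataFrame(payload["per_cell"]),
            params=payload["params"],
        )


def _species_pot_yields(
    config: GeneratorConfig, pot: PotRecord, rng: np.random.Generator, cv: float
) -> dict[str, float]:
    """Noisy species-level yields of one pot under the generative model."""
    members = pot.composition.sorted_members()
    n = len(members)
    mu = np.array([config.mu_g[s] for s in members])
    gamma = 1.0 if n == 1 else config.gamma.get(n, 1.0)
    w = np.ones(n) if n == 1 else dominance_weights(mu, config.skew)
    tmult = (config.drought_mult if pot.treatment.drought else 1.0) * (
        config.biochar_mult if pot.treatment.biochar else 1.0
    )
    eps = lognormal_noise(rng, cv, n)
    y = mu * tmult * gamma * w * eps / n
    return dict(zip(members, y))


def _seedling_counts(n_species: int, individuals_per_pot: int) -> list[int]:
    base, extra = divmod(individuals_per_pot, n_species)
    return [base + (1 if i < extra else 0) for i in range(n_species)]


def _generate_individuals(
    config: GeneratorConfig, pots: list[PotRecord], cv: float, seed: int
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for pot in pots:
        yields = _species_pot_yields(config, pot, rng, cv)
        members = pot.composition.sorted_members()
        counts = _seedling_counts(len(members), config.design.individuals_per_pot)
        for species, k in zip(members, counts):
            per_plant = yields[species] / k
            rsr_base = config.rsr[species] * (
                config.rsr_drought_inflation if pot.treatment.drought else 1.0
            )
            for _ in range(k):
                e_h, e_r, e_lm, e_sla, e_srl = lognormal_noise(rng, cv, 5)
                rsr = rsr_base * e_r
                root = per_plant * rsr / (1 + rsr)
                shoot = per_plant / (1 + rsr)
                leaf_mg = config.leaf_dry_mass_mg[species] * e_lm
                rows.append(
                    {
                        "pot_id": pot.pot_id,
                        "species": species,
                        "height_cm": config.height_cm[species] * e_h,
                        "leaf_area_mm2": config.sla_mm2_mg[species] * e_sla * leaf_mg,
                        "leaf_dry_mass_mg": leaf_mg,
                        "root_length_cm": config.srl_cm_g[species] * e_srl * root,
                        "root_dry_mass_g": root,
                        "shoot_dry_mass_g": shoot,
                    }
                )
    return pd.DataFrame(rows, columns=INDIVIDUAL_COLUMNS)


def _truth_from_noiseless(
    config: GeneratorConfig, pots: list[PotRecord], noiseless: pd.DataFrame
) -> SyntheticTruth:
    species_biomass, _ = aggregate_pots(noiseless, pots)
    results, skips = partition_dataset(species_biomass, design=pots)
    if skips:  # pragma: no cover - cannot happen for a valid generator design
        raise GeneratorError(f"noiseless partition skipped pots: {skips}")
    effects, _ = partition_results_to_frames(results)
    per_pot = effects[
        ["pot_id", "richness", "drought", "biochar", "nbe_g", "ce_g", "se_g"]
    ].rename(columns={"nbe_g": "true_nbe_g", "ce_g": "true_ce_g", "se_g": "true_se_g"})
    per_cell = (
        per_pot.groupby(["richness", "drought", "biochar"], as_index=False)[
            ["true_nbe_g", "true_ce_g", "true_se_g"]
        ]
        .mean()
        .sort_values(["richness", "drought", "biochar"], ignore_index=True)
    )
    return SyntheticTruth(per_pot=per_pot, per_cell=per_cell, params=config.to_dict())


def generate_experiment(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate one experiment: individual-level table plus ground truth.

    The table holds one row per planted seedling (individuals_per_pot rows
    per pot, split as evenly as possible among the pot's species); seedlings
    of one species share their species' pot yield equally, and shoot/root
    masses reconstruct it exactly.  Identical seeds reproduce identical
    tables.  Truth is the noiseless partition of the same design (same
    compositions, cv = 0), so at cv = 0 pipeline estimates equal truth.
    """
    config.validate()
    pots = enumerate_design(config.design)
    individuals = _generate_individuals(config, pots, cv=config.cv, seed=config.seed)
    noiseless = (
        individuals
        if config.cv == 0
        else _generate_individuals(config, pots, cv=0.0, seed=config.seed)
    )
    truth = _truth_from_noiseless(config, pots, noiseless)
    logger.info(
        "generated %d individuals across %d pots (cv=%.3g)",
        len(individuals),
        len(pots),
        config.cv,
    )
    return individuals, truth


def recovery_report(
    truth: SyntheticTruth,
    estimates: list[PartitionResult],
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Bias of estimated effects against ground truth, per richness × treatment.

    For every cell: the mean estimated NBE/CE/SE over its replicate mixture
    pots, the Monte-Carlo standard error of that mean, the bias against the
    cell's truth, and a flag for |bias| > 3 MCSE.
    """
    if truth.params.get("seed") != config.seed or truth.params.get("cv") != config.cv:
        raise PairingError("truth was generated under a different configuration")
    effects, _ = partition_results_to_frames(estimates)
    if effects.empty:
        raise PairingError("no partition estimates supplied")
    grouped = effects.groupby(["richness", "drought", "biochar"])
    rows = []
    for key, sub in grouped:
        cell = truth.per_cell[
            (truth.per_cell["richness"] == key[0])
            & (truth.per_cell["drought"] == key[1])
            & (truth.per_cell["biochar"] == key[2])
        ]
        if cell.empty:
            raise PairingError(f"cell {key} absent from truth")
        row = {"richness": key[0], "drought": key[1], "biochar": key[2], "n": len(sub)}
        for effect, truth_col in (
            ("nbe_g", "true_nbe_g"),
            ("ce_g", "true_ce_g"),
            ("se_g", "true_se_g"),
        ):
            vals = sub[effect].to_numpy()
            mean = float(vals.mean())
            mcse = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            true_val = float(cell[truth_col].iloc[0])
            bias = mean - true_val
            row[f"mean_{effect}"] = mean
            row[f"mcse_{effect}"] = mcse
            row[f"true_{effect}"] = true_val
            row[f"bias_{effect}"] = bias
            row[f"flag_{effect}"] = bool(abs(bias) > 3 * mcse) if mcse > 0 else bias != 0
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["richness", "drought", "biochar"], ignore_index=True
    )


def monte_carlo_recovery(
    mu: tuple[float, ...],
    gamma: float,
    skew: float = 0.0,
    cv: float = 0.1,
    n_reps: int = 200,
    seed: int = 0,
    n_mono_pots: int = 5,
) -> dict:
    """Replicate-mixture Monte Carlo: recover injected CE/SE through the partition.

    Each replicate is an independent mini-experiment on one mixture of the
    given species baselines: monoculture baselines are estimated as the mean
    of ``n_mono_pots`` noisy monoculture pots per species, the mixture's
    species yields are drawn from the generative model, and the pot is
    partitioned with planted proportions.  Truth is the partition of the
    noiseless yields against the exact baselines.

    Returns a dict with true effects, per-effect Monte-Carlo means, standard
    errors and biases, and the replicate-level results.
    """
    mu_arr = np.asarray(mu, dtype=float)
    n = mu_arr.size
    if n < 2:
        raise GeneratorError("a mixture needs at least two species")
    if np.any(mu_arr <= 0):
        raise GeneratorError("baselines must be strictly positive")
    species = [f"S{i + 1}" for i in range(n)]
    w = dominance_weights(mu_arr, skew)
    true_yields = gamma * w * mu_arr / n
    truth = partition(
        dict(zip(species, true_yields)),
        dict(zip(species, mu_arr)),
        pot_id="truth",
    )

    rng = np.random.default_rng(seed)
    results: list[PartitionResult] = []
    for rep in range(n_reps):
        m_hat = np.array(
            [
                float(m * lognormal_noise(rng, cv, n_mono_pots).mean())
                for m in mu_arr
            ]
        )
        y = true_yields * lognormal_noise(rng, cv, n)
        results.append(
            partition(
                dict(zip(species, y)),
                dict(zip(species, m_hat)),
                pot_id=f"rep{rep}",
            )
        )

    out: dict = {
        "n_reps": n_reps,
        "true_nbe_g": truth.nbe_g,
        "true_ce_g": truth.ce_g,
        "true_se_g": truth.se_g,
        "results": results,
    }
    for effect, attr in (("nbe", "nbe_g"), ("ce", "ce_g"), ("se", "se_g")):
        vals = np.array([getattr(r, attr) for r in results])
        mean = float(vals.mean())
        mcse = float(vals.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
        out[f"mean_{effect}_g"] = mean
        out[f"mcse_{effect}_g"] = mcse
        out[f"bias_{effect}_g"] = mean - out[f"true_{effect}_g"]
    return out
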