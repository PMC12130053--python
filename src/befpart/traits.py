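"""Per-individual plant functional traits and pot-level aggregation.

Traits follow the standard morphometric definitions: specific leaf area
(SLA, mm² mg⁻¹) is leaf area over leaf dry mass; specific root length
(SRL, cm g⁻¹) is root length over root dry mass; the root-to-shoot ratio
(RSR, dimensionless) is root dry mass over shoot dry mass.  "Total biomass"
defaults to shoot + root dry mass per individual; an ``aboveground`` option
restricts it to shoot mass, since partition baselines are sometimes computed
on aboveground yield only.

Missing measurements are carried as NaN and excluded per-trait from pot
means — never imputed, never zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PotRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TraitDomainError",
    "PotIntegrityError",
    "EmptyPotError",
    "PotAggregate",
    "compute_sla",
    "compute_srl",
    "compute_rsr",
    "compute_traits",
    "aggregate_pot",
    "aggregate_pots",
    "INDIVIDUAL_COLUMNS",
]

#: canonical individual-level CSV columns, in order
INDIVIDUAL_COLUMNS = [
    "pot_id",
    "species",
    "height_cm",
    "leaf_area_mm2",
    "leaf_dry_mass_mg",
    "root_length_cm",
    "root_dry_mass_g",
    "shoot_dry_mass_g",
]


class TraitDomainError(ValueError):
    """A trait ratio was requested for a non-positive measurement."""


class PotIntegrityError(ValueError):
    """Individuals are inconsistent with the pot's design record."""


class EmptyPotError(ValueError):
    """A pot aggregate was requested for a pot with no individuals."""


def _ratio(numer, denom, name_n: str, name_d: str) -> np.ndarray | float:
    """Elementwise positive ratio with NaN pass-through for missing values."""
    n = np.asarray(numer, dtype=float)
    d = np.asarray(denom, dtype=float)
    for arr, name in ((n, name_n), (d, name_d)):
        bad = ~np.isnan(arr) & (arr <= 0)
        if np.any(bad):
            raise TraitDomainError(
                f"{name} must be strictly positive; got "
                f"{np.asarray(arr)[bad].ravel()[0]!r}"
            )
    out = n / d
    return float(out) if out.ndim == 0 else out


def compute_sla(leaf_area_mm2, leaf_dry_mass_mg):
    """Specific leaf area, mm² mg⁻¹: leaf area / leaf dry mass.

    Both inputs must be strictly positive (NaN propagates as missing).
    Leaf area and mass are each the mean of the sampled leaves of one
    individual, so the ratio is the individual's mean per-leaf SLA.
    """
    return _ratio(leaf_area_mm2, leaf_dry_mass_mg, "leaf_area_mm2", "leaf_dry_mass_mg")


def compute_srl(root_length_cm, root_dry_mass_g):
    """Specific root length, cm g⁻¹: root length / root dry mass."""
    return _ratio(root_length_cm, root_dry_mass_g, "root_length_cm", "root_dry_mass_g")


def compute_rsr(root_dry_mass_g, shoot_dry_mass_g):
    """Root-to-shoot ratio (dimensionless): root dry mass / shoot dry mass."""
    return _ratio(root_dry_mass_g, shoot_dry_mass_g, "root_dry_mass_g", "shoot_dry_mass_g")


def compute_traits(individuals: pd.DataFrame, biomass: str = "total") -> pd.DataFrame:
    """Derive the trait table from raw individual measurements.

    Parameters
    ----------
    individuals
        Table with the :data:`INDIVIDUAL_COLUMNS` schema; empty cells are NaN.
    biomass
        ``"total"`` (shoot + root dry mass, default) or ``"aboveground"``
        (shoot dry mass only) for the ``total_biomass_g`` column.

    Returns a copy with ``height_cm``, ``sla_mm2_mg``, ``srl_cm_g``, ``rsr``
    and ``total_biomass_g`` columns.
    """
    if biomass not in ("total", "aboveground"):
        raise ValueError(f"biomass must be 'total' or 'aboveground', got {biomass!r}")
    missing = set(INDIVIDUAL_COLUMNS) - set(individuals.columns)
    if missing:
        raise PotIntegrityError(f"individual table missing columns: {sorted(missing)}")
    out = individuals.copy()
    out["sla_mm2_mg"] = compute_sla(
        out["leaf_area_mm2"].to_numpy(), out["leaf_dry_mass_mg"].to_numpy()
    )
    out["srl_cm_g"] = compute_srl(
        out["root_length_cm"].to_numpy(), out["root_dry_mass_g"].to_numpy()
    )
    out["rsr"] = compute_rsr(
        out["root_dry_mass_g"].to_numpy(), out["shoot_dry_mass_g"].to_numpy()
    )
    shoot = out["shoot_dry_mass_g"].to_numpy(dtype=float)
    root = out["root_dry_mass_g"].to_numpy(dtype=float)
    out["total_biomass_g"] = shoot + root if biomass == "total" else shoot
    return out


@dataclass
class PotAggregate:
    """Pot-level summary: per-species biomass totals plus trait means."""

    pot_id: str
    species_biomass_g: dict[str, float]
    total_biomass_g: float
    n_individuals: int
    mean_height_cm: float
    mean_sla_mm2_mg: float
    mean_srl_cm_g: float
    mean_rsr: float


def _nanmean(values: np.ndarray) -> float:
    v = values[~np.isnan(values)]
    return float(v.mean()) if v.size else float("nan")


def aggregate_pot(
    individuals: pd.DataFrame, pot: PotRecord, biomass: str = "total"
) -> PotAggregate:
    """Aggregate one pot's individuals into per-species biomass and trait means.

    Every individual must carry the pot's id and a species within its
    composition.  Individuals missing a trait are excluded from that trait's
    mean only; biomass requires non-missing shoot (and, for ``total``, root)
    dry mass.
    """
    sub = individuals[individuals["pot_id"] == pot.pot_id]
    if sub.empty:
        raise EmptyPotError(f"no individuals recorded for pot {pot.pot_id}")
    alien = set(sub["species"]) - set(pot.composition.members)
    if alien:
        raise PotIntegrityError(
            f"pot {pot.pot_id}: species {sorted(alien)} not in composition "
            f"{pot.composition.sorted_members()}"
        )
    traits = compute_traits(sub, biomass=biomass)
    by_species = traits.groupby("species", sort=True)["total_biomass_g"].sum()
    species_biomass = {s: float(v) for s, v in by_species.items()}
    return PotAggregate(
        pot_id=pot.pot_id,
        species_biomass_g=species_biomass,
        total_biomass_g=float(sum(species_biomass.values())),
        n_individuals=len(sub),
        mean_height_cm=_nanmean(traits["height_cm"].to_numpy(dtype=float)),
        mean_sla_mm2_mg=_nanmean(traits["sla_mm2_mg"].to_numpy(dtype=float)),
        mean_srl_cm_g=_nanmean(traits["srl_cm_g"].to_numpy(dtype=float)),
        mean_rsr=_nanmean(traits["rsr"].to_numpy(dtype=float)),
    )


def aggregate_pots(
    individuals: pd.DataFrame, pots: list[PotRecord], biomass: str = "total"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate all pots; returns (per-species biomass table, pot trait table).

    The first table has one row per pot × species (``pot_id``, ``species``,
    ``biomass_g``); the second one row per pot with totals and trait means,
    joined to the design columns.  Pots without individuals raise
    :class:`EmptyPotError` (a designed pot must have data or be removed from
    the design before aggregation).
    """
    species_rows = []
    pot_rows = []
    for pot in pots:
        agg = aggregate_pot(individuals, pot, biomass=biomass)
        for sp, b in sorted(agg.species_biomass_g.items()):
            species_rows.append({"pot_id": pot.pot_id, "species": sp, "biomass_g": b})
        pot_rows.append(
            {
                "pot_id": pot.pot_id,
                "richness": pot.composition.richness,
                "drought": int(pot.treatment.drought),
                "biochar": int(pot.treatment.biochar),
                "replicate": pot.replicate,
                "n_individuals": agg.n_individuals,
                "total_biomass_g": agg.total_biomass_g,
                "mean_height_cm": agg.mean_height_cm,
                "mean_sla_mm2_mg": agg.mean_sla_mm2_mg,
                "mean_srl_cm_g": agg.mean_srl_cm_g,
                "mean_rsr": agg.mean_rsr,
            }
        )
    return pd.DataFrame(species_rows), pd.DataFrame(pot_rows)
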