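"""Additive partition of biodiversity effects (Loreau–Hector).

For a mixture of N species with observed per-species yields Y_oi and
monoculture baselines M_i, the net biodiversity effect is

    NBE = Σ Y_oi − Σ p_i M_i            (observed − expected biomass)

with p_i the expected proportion of species i (planted proportion 1/N by
default).  Writing RY_i = Y_oi / M_i and ΔRY_i = RY_i − 1/N, the partition
splits NBE into a complementarity and a selection component:

    CE = N · mean(ΔRY) · mean(M)
    SE = N · cov(ΔRY, M)

where cov is the *population* covariance (denominator N).  With planted
proportions this makes NBE = CE + SE an exact algebraic identity; each
result carries the floating-point residual as a certificate, and a residual
beyond tolerance raises rather than passing silently.  Because ΔRY differs
from RY by the constant 1/N, cov(ΔRY, M) equals cov(RY, M).

Baselines are treatment-matched by default: a drought mixture is compared
against drought monocultures, so treatment main effects cancel out of the
partition and only diversity structure remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PotRecord, Treatment

logger = logging.getLogger(__name__)

__all__ = [
    "PartitionError",
    "MissingBaselineError",
    "AdditivityError",
    "MonocultureReference",
    "PartitionResult",
    "monoculture_yield",
    "monoculture_references",
    "expected_biomass",
    "partition",
    "partition_dataset",
    "partition_results_to_frames",
]

ADDITIVITY_RTOL = 1e-9


class PartitionError(ValueError):
    """The partition is undefined or ill-posed for the given inputs."""


class MissingBaselineError(PartitionError):
    """No monoculture baseline exists for a species under a treatment."""


class AdditivityError(AssertionError):
    """The NBE = CE + SE certificate failed beyond floating tolerance."""


@dataclass(frozen=True)
class MonocultureReference:
    """Mean monoculture yield M_i of one species under one treatment."""

    species: str
    treatment: Treatment
    m_g: float
    n_pots: int

    def __post_init__(self) -> None:
        if self.m_g <= 0:
            raise PartitionError(
                f"monoculture yield for {self.species} must be > 0, got {self.m_g}"
            )
        if self.n_pots < 1:
            raise PartitionError("a baseline needs at least one monoculture pot")


@dataclass
class PartitionResult:
    """The partition of one mixture pot, with its additivity certificate."""

    pot_id: str
    treatment: Treatment
    richness: int
    species: tuple[str, ...]
    expected_biomass_g: float
    observed_biomass_g: float
    nbe_g: float
    ce_g: float
    se_g: float
    ry: dict[str, float]
    delta_ry: dict[str, float]
    additivity_residual_g: float


def monoculture_yield(
    species_biomass: pd.DataFrame,
    design: list[PotRecord],
    species: str,
    treatment: Treatment,
) -> MonocultureReference:
    """Mean biomass of one species across its monoculture pots of one treatment.

    ``species_biomass`` is the per-pot × species biomass table from
    :func:`befpart.traits.aggregate_pots`.
    """
    mono_ids = [
        p.pot_id
        for p in design
        if p.composition.richness == 1
        and p.treatment == treatment
        and species in p.composition.members
    ]
    if not mono_ids:
        raise MissingBaselineError(
            f"no monoculture pot for species {species!r} under "
            f"treatment {treatment.label!r}"
        )
    sub = species_biomass[
        species_biomass["pot_id"].isin(mono_ids)
        & (species_biomass["species"] == species)
    ]
    if sub.empty:
        raise MissingBaselineError(
            f"monoculture pots for {species!r}/{treatment.label!r} carry no biomass rows"
        )
    return MonocultureReference(
        species=species,
        treatment=treatment,
        m_g=float(sub["biomass_g"].mean()),
        n_pots=len(sub),
    )


def monoculture_references(
    species_biomass: pd.DataFrame, design: list[PotRecord]
) -> dict[tuple[str, str], MonocultureReference]:
    """All available (species, treatment-label) → baseline references."""
    refs: dict[tuple[str, str], MonocultureReference] = {}
    seen = {
        (s, p.treatment)
        for p in design
        if p.composition.richness == 1
        for s in p.composition.members
    }
    for species, treatment in sorted(seen, key=lambda st: (st[0], st[1].label)):
        try:
            ref = monoculture_yield(species_biomass, design, species, treatment)
        except MissingBaselineError:
            continue
        refs[(species, treatment.label)] = ref
    return refs


def expected_biomass(m: np.ndarray, p: np.ndarray) -> float:
    """Expected mixture biomass Σ p_i · M_i from monoculture baselines."""
    m = np.asarray(m, dtype=float)
    p = np.asarray(p, dtype=float)
    if m.shape != p.shape:
        raise PartitionError("baseline and proportion vectors differ in length")
    if np.any(m <= 0):
        raise PartitionError("monoculture baselines must be strictly positive")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, rtol=0, atol=1e-9):
        raise PartitionError(f"proportions must be non-negative and sum to 1, got {p}")
    return float(np.dot(p, m))


def partition(
    observed: dict[str, float],
    baselines: dict[str, float],
    *,
    pot_id: str = "",
    treatment: Treatment | None = None,
    proportions: str = "planted",
    additivity_rtol: float = ADDITIVITY_RTOL,
) -> PartitionResult:
    """Partition one mixture's net biodiversity effect into CE + SE.

    Parameters
    ----------
    observed
        Species → observed yield in the mixture (g); zero allowed (death).
    baselines
        Species → monoculture yield M_i (g), strictly positive, covering
        every observed species.
    proportions
        ``"planted"`` (p_i = 1/N, the identity-preserving default) or
        ``"observed"`` (p_i from realized yields; the expected biomass then
        uses realized relative abundances and NBE = CE + SE no longer holds,
        so no certificate is enforced).

    Raises
    ------
    PartitionError
        For monocultures (N = 1, partition undefined) or invalid baselines.
    AdditivityError
        If, with planted proportions, |NBE − (CE + SE)| exceeds
        ``additivity_rtol · max(1, |NBE|)``.
    """
    species = tuple(sorted(observed))
    n = len(species)
    if n < 2:
        raise PartitionError("the partition is undefined for monocultures (N = 1)")
    if set(baselines) < set(species):
        missing = sorted(set(species) - set(baselines))
        raise MissingBaselineError(f"missing monoculture baselines for {missing}")
    if proportions not in ("planted", "observed"):
        raise PartitionError(f"unknown proportions mode {proportions!r}")

    y = np.array([float(observed[s]) for s in species])
    m = np.array([float(baselines[s]) for s in species])
    if np.any(y < 0):
        raise PartitionError("observed yields must be non-negative")
    if np.any(m <= 0):
        raise PartitionError("monoculture baselines must be strictly positive")

    if proportions == "planted":
        p = np.full(n, 1.0 / n)
    else:
        total = y.sum()
        if total <= 0:
            raise PartitionError("observed proportions undefined for an empty mixture")
        p = y / total

    ry = y / m
    dry = ry - 1.0 / n
    observed_total = float(y.sum())
    expected = expected_biomass(m, p)
    nbe = observed_total - expected
    ce = n * dry.mean() * m.mean()
    # population covariance (denominator N): the only choice under which
    # CE + SE telescopes exactly back to NBE
    se = n * float(np.mean(dry * m) - dry.mean() * m.mean())
    residual = nbe - (ce + se)

    if proportions == "planted" and abs(residual) > additivity_rtol * max(1.0, abs(nbe)):
        raise AdditivityError(
            f"pot {pot_id or '<anon>'}: |NBE - (CE + SE)| = {abs(residual):.3e} "
            f"exceeds tolerance"
        )

    return PartitionResult(
        pot_id=pot_id,
        treatment=treatment if treatment is not None else Treatment(False, False),
        richness=n,
        species=species,
        expected_biomass_g=expected,
        observed_biomass_g=observed_total,
        nbe_g=nbe,
        ce_g=ce,
        se_g=se,
        ry={s: float(v) for s, v in zip(species, ry)},
        delta_ry={s: float(v) for s, v in zip(species, dry)},
        additivity_residual_g=float(residual),
    )


def partition_dataset(
    species_biomass: pd.DataFrame,
    design: list[PotRecord],
    *,
    proportions: str = "planted",
    baseline: str = "matched",
    additivity_rtol: float = ADDITIVITY_RTOL,
) -> tuple[list[PartitionResult], list[tuple[str, str]]]:
    """Partition every mixture pot of a dataset.

    Monoculture pots are excluded by construction (they define the baselines).
    ``baseline="matched"`` compares each mixture against monocultures of its
    own treatment; ``baseline="control"`` compares all mixtures against
    control monocultures (a sensitivity mode in which treatment main effects
    load onto the partition).

    Returns ``(results, skips)`` where ``skips`` pairs each skipped pot id
    with a reason; skips are also logged at WARN level.
    """
    if baseline not in ("matched", "control"):
        raise PartitionError(f"unknown baseline mode {baseline!r}")
    refs = monoculture_references(species_biomass, design)
    by_pot = {
        pid: dict(zip(sub["species"], sub["biomass_g"]))
        for pid, sub in species_biomass.groupby("pot_id")
    }

    results: list[PartitionResult] = []
    skips: list[tuple[str, str]] = []
    for pot in design:
        if pot.composition.richness < 2:
            continue
        observed = by_pot.get(pot.pot_id)
        if not observed or sum(observed.values()) <= 0:
            skips.append((pot.pot_id, "empty mixture pot"))
            logger.warning("skipping pot %s: empty mixture pot", pot.pot_id)
            continue
        ref_label = "control" if baseline == "control" else pot.treatment.label
        try:
            base = {
                s: refs[(s, ref_label)].m_g for s in pot.composition.sorted_members()
            }
        except KeyError as err:
            reason = f"missing monoculture baseline for {err.args[0]}"
            skips.append((pot.pot_id, reason))
            logger.warning("skipping pot %s: %s", pot.pot_id, reason)
            continue
        # a species that died entirely still enters with zero observed yield
        full_observed = {
            s: float(observed.get(s, 0.0)) for s in pot.composition.sorted_members()
        }
        results.append(
            partition(
                full_observed,
                base,
                pot_id=pot.pot_id,
                treatment=pot.treatment,
                proportions=proportions,
                additivity_rtol=additivity_rtol,
            )
        )
    return results, skips


def partition_results_to_frames(
    results: list[PartitionResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(pot-level effects table, per-species relative-yield table)."""
    pot_rows = [
        {
            "pot_id": r.pot_id,
            "drought": int(r.treatment.drought),
            "biochar": int(r.treatment.biochar),
            "richness": r.richness,
            "expected_biomass_g": r.expected_biomass_g,
            "observed_biomass_g": r.observed_biomass_g,
            "nbe_g": r.nbe_g,
            "ce_g": r.ce_g,
            "se_g": r.se_g,
            "additivity_residual_g": r.additivity_residual_g,
        }
        for r in results
    ]
    species_rows = [
        {
            "pot_id": r.pot_id,
            "species": s,
            "ry": r.ry[s],
            "delta_ry": r.delta_ry[s],
        }
        for r in results
        for s in r.species
    ]
    effects_cols = [
        "pot_id", "drought", "biochar", "richness", "expected_biomass_g",
        "observed_biomass_g", "nbe_g", "ce_g", "se_g", "additivity_residual_g",
    ]
    ry_cols = ["pot_id", "species", "ry", "delta_ry"]
    return (
        pd.DataFrame(pot_rows, columns=effects_cols),
        pd.DataFrame(species_rows, columns=ry_cols),
    )
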