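"""Balanced factorial design construction for diversity × treatment experiments.

The design crossed here is the classic greenhouse biodiversity layout: a small
species pool, a handful of richness levels, a 2×2 water × soil-amendment
treatment grid, and a fixed number of replicate communities per richness level.
Every mixture composition is drawn once per richness level and then subjected
to *all four* treatments, so diversity × treatment contrasts compare identical
communities.  Mixture selection is random but balanced: across the replicate
communities of one richness level every species appears equally often (or
within one occurrence when exact balance is arithmetically impossible).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DesignError",
    "InfeasibleBalanceError",
    "Treatment",
    "CommunityComposition",
    "PotRecord",
    "DesignConfig",
    "select_balanced_mixtures",
    "enumerate_design",
    "validate_design",
    "design_to_frame",
    "frame_to_design",
]

#: annotation-only husbandry constants; nothing downstream computes with them
WATERING_ML = {"control": 660, "drought": 220}
BIOCHAR_KG = 1.25


class DesignError(ValueError):
    """An invalid design configuration or construction request."""


class InfeasibleBalanceError(DesignError):
    """Balanced mixture selection could not be satisfied."""


@dataclass(frozen=True, order=True)
class Treatment:
    """One cell of the 2×2 drought × biochar grid."""

    drought: bool
    biochar: bool

    @property
    def label(self) -> str:
        if self.biochar and self.drought:
            return "biochar_drought"
        if self.biochar:
            return "biochar"
        if self.drought:
            return "drought"
        return "control"

    @staticmethod
    def all() -> tuple["Treatment", ...]:
        """The four treatment combinations, in a fixed canonical order."""
        return (
            Treatment(False, False),
            Treatment(True, False),
            Treatment(False, True),
            Treatment(True, True),
        )

    @staticmethod
    def from_label(label: str) -> "Treatment":
        for t in Treatment.all():
            if t.label == label:
                return t
        raise DesignError(f"unknown treatment label: {label!r}")


@dataclass(frozen=True)
class CommunityComposition:
    """An unordered set of species planted together in one pot."""

    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise DesignError("composition must contain at least one species")
        if any(not isinstance(m, str) or not m for m in self.members):
            raise DesignError("species labels must be non-empty strings")

    @property
    def richness(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))

    def __iter__(self):
        return iter(self.sorted_members())


@dataclass(frozen=True)
class PotRecord:
    """One experimental unit: a community under a treatment, replicate-indexed."""

    pot_id: str
    composition: CommunityComposition
    treatment: Treatment
    replicate: int


@dataclass
class DesignConfig:
    """Parameters defining the full factorial design.

    ``replicates_per_cell`` counts the distinct replicate communities per
    richness level; each of them occurs once under every treatment.
    ``individuals_per_pot`` is carried for downstream seedling allocation.
    """

    species_pool: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5")
    richness_levels: tuple[int, ...] = (1, 2, 4)
    replicates_per_cell: int = 5
    individuals_per_pot: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.species_pool = tuple(self.species_pool)
        self.richness_levels = tuple(int(r) for r in self.richness_levels)

    def validate(self) -> None:
        pool = self.species_pool
        if len(pool) == 0:
            raise DesignError("species pool is empty")
        if len(set(pool)) != len(pool):
            raise DesignError("species pool contains duplicate labels")
        if any(not isinstance(s, str) or not s for s in pool):
            raise DesignError("species labels must be non-empty strings")
        if not self.richness_levels:
            raise DesignError("no richness levels configured")
        for r in self.richness_levels:
            if r < 1:
                raise DesignError(f"richness level must be positive, got {r}")
            if r > len(pool):
                raise DesignError(
                    f"richness level {r} exceeds pool size {len(pool)}"
                )
        if len(set(self.richness_levels)) != len(self.richness_levels):
            raise DesignError("duplicate richness levels")
        if self.replicates_per_cell < 1:
            raise DesignError("replicates_per_cell must be >= 1")
        if self.individuals_per_pot < 1:
            raise DesignError("individuals_per_pot must be >= 1")


def select_balanced_mixtures(
    pool: list[str] | tuple[str, ...],
    richness: int,
    count: int,
    seed: int,
    max_retries: int = 10_000,
) -> list[CommunityComposition]:
    """Draw ``count`` distinct compositions of the given richness, balanced.

    Balance means the species occurrence counts across the returned mixtures
    differ by at most one (exactly equal whenever ``count * richness`` is a
    multiple of the pool size).  The draw is rejection sampling over seeded
    shuffles of a balanced species multiset, chunked into richness-sized
    groups; a shuffle is accepted when every chunk holds distinct species and
    the chunks are pairwise-distinct compositions.

    Raises
    ------
    DesignError
        If the request is structurally impossible (richness > pool, count
        exceeding the number of distinct subsets).
    InfeasibleBalanceError
        If no accepting shuffle is found within ``max_retries`` attempts.
    """
    pool = tuple(pool)
    n_pool = len(pool)
    if richness < 1 or richness > n_pool:
        raise DesignError(f"richness {richness} infeasible for pool of {n_pool}")
    if count < 1:
        raise DesignError("count must be >= 1")
    n_subsets = math.comb(n_pool, richness)
    if count > n_subsets:
        raise InfeasibleBalanceError(
            f"{count} distinct mixtures of richness {richness} requested but "
            f"only {n_subsets} subsets exist"
        )

    rng = np.random.default_rng(seed)
    total = count * richness
    base, extra = divmod(total, n_pool)
    sorted_pool = sorted(pool)

    for _ in range(max_retries):
        multiset = list(sorted_pool) * base
        if extra:
            bonus = rng.choice(n_pool, size=extra, replace=False)
            multiset.extend(sorted_pool[i] for i in bonus)
        order = rng.permutation(total)
        shuffled = [multiset[i] for i in order]
        chunks = [
            frozenset(shuffled[i * richness : (i + 1) * richness])
            for i in range(count)
        ]
        if any(len(c) != richness for c in chunks):
            continue  # a chunk repeated a species
        if len(set(chunks)) != count:
            continue  # two replicate mixtures coincide
        return [CommunityComposition(c) for c in chunks]

    raise InfeasibleBalanceError(
        f"no balanced selection of {count} mixtures (richness {richness}, "
        f"pool {n_pool}) found in {max_retries} attempts"
    )


def _level_seed(config: DesignConfig, level_index: int) -> int:
    """Deterministic per-richness-level child seed (kept below 2**31)."""
    ss = np.random.SeedSequence(config.seed, spawn_key=(level_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def enumerate_design(config: DesignConfig) -> list[PotRecord]:
    """Construct the full crossed design as a flat list of pots.

    Within each richness level the replicate compositions are drawn once and
    reused across all four treatments.  The output size is
    ``len(richness_levels) × 4 × replicates_per_cell``.
    """
    config.validate()
    pots: list[PotRecord] = []
    for li, richness in enumerate(config.richness_levels):
        comps = select_balanced_mixtures(
            config.species_pool,
            richness,
            config.replicates_per_cell,
            seed=_level_seed(config, li),
        )
        for treatment in Treatment.all():
            for rep, comp in enumerate(comps, start=1):
                pot_id = f"N{richness}_{treatment.label}_r{rep}"
                pots.append(PotRecord(pot_id, comp, treatment, rep))
    logger.info("enumerated design with %d pots", len(pots))
    return pots


def validate_design(pots: list[PotRecord], config: DesignConfig) -> list[str]:
    """Diagnostic check of a constructed design; returns a list of violations.

    An empty list means the design satisfies every structural invariant:
    unique pot ids, complete richness × treatment cells at the configured
    replicate count, identical compositions across treatments within a level,
    and ≤1 occurrence spread among species per richness level.
    """
    violations: list[str] = []
    ids = [p.pot_id for p in pots]
    for dup in sorted({i for i in ids if ids.count(i) > 1}):
        violations.append(f"duplicate pot_id: {dup}")

    cells: dict[tuple[int, str], list[PotRecord]] = {}
    for p in pots:
        cells.setdefault((p.composition.richness, p.treatment.label), []).append(p)

    for richness in config.richness_levels:
        comps_by_treatment: dict[str, set[frozenset[str]]] = {}
        for t in Treatment.all():
            cell = cells.get((richness, t.label), [])
            if len(cell) != config.replicates_per_cell:
                violations.append(
                    f"cell richness={richness} treatment={t.label} has "
                    f"{len(cell)} replicates, expected {config.replicates_per_cell}"
                )
            comps_by_treatment[t.label] = {p.composition.members for p in cell}
        if len({frozenset(v) for v in comps_by_treatment.values()}) > 1:
            violations.append(
                f"richness {richness}: compositions differ across treatments"
            )
        # balance over one treatment's replicate mixtures (shared across all)
        any_cell = comps_by_treatment[Treatment.all()[0].label]
        counts = {s: 0 for s in config.species_pool}
        for comp in any_cell:
            for s in comp:
                if s not in counts:
                    violations.append(f"species {s} not in configured pool")
                    counts[s] = 0
                counts[s] += 1
        occurring = [c for c in counts.values()]
        if occurring and max(occurring) - min(occurring) > 1:
            violations.append(
                f"richness {richness}: species occurrences unbalanced {counts}"
            )

    for p in pots:
        if p.composition.richness not in config.richness_levels:
            violations.append(
                f"pot {p.pot_id}: richness {p.composition.richness} not configured"
            )
        if not (1 <= p.replicate <= config.replicates_per_cell):
            violations.append(f"pot {p.pot_id}: replicate index {p.replicate} out of range")
    return violations


# ---------------------------------------------------------------------------
# CSV interchange

def design_to_frame(pots: list[PotRecord]) -> pd.DataFrame:
    """Design as a tidy table: one row per pot, species semicolon-joined."""
    rows = [
        {
            "pot_id": p.pot_id,
            "richness": p.composition.richness,
            "species_list": ";".join(p.composition.sorted_members()),
            "drought": int(p.treatment.drought),
            "biochar": int(p.treatment.biochar),
            "replicate": p.replicate,
        }
        for p in pots
    ]
    return pd.DataFrame(rows)


def frame_to_design(frame: pd.DataFrame) -> list[PotRecord]:
    required = {"pot_id", "richness", "species_list", "drought", "biochar", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise DesignError(f"design table missing columns: {sorted(missing)}")
    pots = []
    for row in frame.itertuples(index=False):
        members = frozenset(str(row.species_list).split(";"))
        comp = CommunityComposition(members)
        if comp.richness != int(row.richness):
            raise DesignError(
                f"pot {row.pot_id}: richness column {row.richness} does not "
                f"match species_list of {comp.richness} species"
            )
        pots.append(
            PotRecord(
                pot_id=str(row.pot_id),
                composition=comp,
                treatment=Treatment(bool(int(row.drought)), bool(int(row.biochar))),
                replicate=int(row.replicate),
            )
        )
    return pots
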