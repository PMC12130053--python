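"""The additive biodiversity-effect partition and its identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import befpart as bp
from befpart.design import Treatment
from conftest import random_partition_instance


def brute_force_ce_se(observed, baselines):
    """Term-by-term oracle: CE = Σ ΔRY_i·M̄ / 1, SE = Σ ΔRY_i·(M_i − M̄).

    Evaluates the partition summand-by-summand without the closed
    N·mean/N·cov formulas, as an independent reference.
    """
    species = sorted(observed)
    n = len(species)
    m = np.array([baselines[s] for s in species])
    y = np.array([observed[s] for s in species])
    dry = y / m - 1.0 / n
    m_bar = m.mean()
    ce = sum(d * m_bar for d in dry)
    se = sum(d * (mi - m_bar) for d, mi in zip(dry, m))
    return ce, se


class TestWorkedExamples:
    def test_uniform_overyielding_is_pure_complementarity(self):
        """M=(10,20), Y=(6,12): equal ΔRY forces SE = 0 and CE = NBE = 3."""
        r = bp.partition({"A": 6.0, "B": 12.0}, {"A": 10.0, "B": 20.0})
        assert r.nbe_g == pytest.approx(3.0, abs=1e-12)
        assert r.ce_g == pytest.approx(3.0, abs=1e-12)
        assert r.se_g == pytest.approx(0.0, abs=1e-12)
        assert r.ry == pytest.approx({"A": 0.6, "B": 0.6})

    def test_low_yielder_overperformance_gives_negative_selection(self):
        """M=(10,20), Y=(8,8): NBE=1 splits into CE=3 and SE=−2."""
        r = bp.partition({"A": 8.0, "B": 8.0}, {"A": 10.0, "B": 20.0})
        assert r.nbe_g == pytest.approx(1.0, abs=1e-12)
        assert r.ce_g == pytest.approx(3.0, abs=1e-12)
        assert r.se_g == pytest.approx(-2.0, abs=1e-12)
        assert r.delta_ry == pytest.approx({"A": 0.3, "B": -0.1})

    def test_null_community_has_all_zero_effects(self):
        """Y_i = M_i/N exactly meets expectation: NBE = CE = SE = 0."""
        r = bp.partition({"A": 5.0, "B": 10.0}, {"A": 10.0, "B": 20.0})
        assert r.nbe_g == pytest.approx(0.0, abs=1e-12)
        assert r.ce_g == pytest.approx(0.0, abs=1e-12)
        assert r.se_g == pytest.approx(0.0, abs=1e-12)


class TestPartitionContracts:
    def test_monoculture_partition_is_undefined(self):
        with pytest.raises(bp.PartitionError):
            bp.partition({"A": 5.0}, {"A": 10.0})

    def test_missing_baseline_raises(self):
        with pytest.raises(bp.MissingBaselineError):
            bp.partition({"A": 5.0, "B": 4.0}, {"A": 10.0})

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(bp.PartitionError):
            bp.partition({"A": 5.0, "B": 4.0}, {"A": 10.0, "B": 0.0})

    def test_dead_species_allowed_with_zero_yield(self):
        r = bp.partition({"A": 0.0, "B": 12.0}, {"A": 10.0, "B": 20.0})
        assert r.ry["A"] == 0.0
        assert r.nbe_g == pytest.approx(r.ce_g + r.se_g, abs=1e-12)

    def test_observed_proportions_change_expected_biomass(self):
        observed = {"A": 8.0, "B": 8.0}
        baselines = {"A": 10.0, "B": 20.0}
        planted = bp.partition(observed, baselines, proportions="planted")
        realized = bp.partition(observed, baselines, proportions="observed")
        assert planted.expected_biomass_g == pytest.approx(15.0)
        assert realized.expected_biomass_g == pytest.approx(15.0, abs=1e-9)
        # equal realized yields happen to give p = 1/2 here; an uneven case:
        realized2 = bp.partition({"A": 12.0, "B": 4.0}, baselines,
                                 proportions="observed")
        assert realized2.expected_biomass_g == pytest.approx(0.75 * 10 + 0.25 * 20)


class TestPartitionInvariants:
    def test_additivity_certificate_over_randomized_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(2000):
            y, m = random_partition_instance(rng)
            r = bp.partition(y, m)
            assert abs(r.additivity_residual_g) <= 1e-9 * max(1.0, abs(r.nbe_g))

    def test_closed_form_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            y, m = random_partition_instance(rng)
            r = bp.partition(y, m)
            ce, se = brute_force_ce_se(y, m)
            assert r.ce_g == pytest.approx(ce, rel=1e-12, abs=1e-12)
            assert r.se_g == pytest.approx(se, rel=1e-12, abs=1e-12)

    def test_selection_vanishes_for_equal_baselines(self):
        r = bp.partition({"A": 3.0, "B": 9.0, "C": 1.0},
                         {"A": 10.0, "B": 10.0, "C": 10.0})
        assert r.se_g == pytest.approx(0.0, abs=1e-12)

    def test_complementarity_vanishes_when_mean_deviation_is_zero(self):
        # ΔRY = (+0.2, −0.2): mean zero, so CE = 0 and NBE is pure selection
        r = bp.partition({"A": 7.0, "B": 6.0}, {"A": 10.0, "B": 20.0})
        assert r.ce_g == pytest.approx(0.0, abs=1e-12)
        assert r.nbe_g == pytest.approx(r.se_g, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(
        scale=st.floats(0.001, 1000.0),
        seed=st.integers(0, 2**20),
    )
    def test_scale_equivariance(self, scale, seed):
        """×c on all yields and baselines scales NBE/CE/SE by c, RY unchanged."""
        rng = np.random.default_rng(seed)
        y, m = random_partition_instance(rng)
        r1 = bp.partition(y, m)
        r2 = bp.partition({k: v * scale for k, v in y.items()},
                          {k: v * scale for k, v in m.items()})
        assert r2.nbe_g == pytest.approx(r1.nbe_g * scale, rel=1e-9, abs=1e-12)
        assert r2.ce_g == pytest.approx(r1.ce_g * scale, rel=1e-9, abs=1e-12)
        assert r2.se_g == pytest.approx(r1.se_g * scale, rel=1e-9, abs=1e-12)
        for s in y:
            assert r2.ry[s] == pytest.approx(r1.ry[s], rel=1e-9)


class TestBaselinesAndBatch:
    def test_monoculture_yield_is_treatment_matched_mean(self, paper_pots, generated):
        _, individuals, _ = generated
        species_biomass, _ = bp.aggregate_pots(individuals, paper_pots)
        control = Treatment(False, False)
        mono_pots = [
            p.pot_id for p in paper_pots
            if p.composition.richness == 1 and p.treatment == control
        ]
        some_species = next(
            s for p in paper_pots if p.composition.richness == 1
            for s in p.composition.members
        )
        ref = bp.monoculture_yield(species_biomass, paper_pots, some_species, control)
        manual = species_biomass[
            species_biomass["pot_id"].isin(mono_pots)
            & (species_biomass["species"] == some_species)
        ]["biomass_g"].mean()
        assert ref.m_g == pytest.approx(manual, rel=1e-12)
        assert ref.treatment == control

    def test_missing_monoculture_is_reported(self, paper_pots, generated):
        _, individuals, _ = generated
        species_biomass, _ = bp.aggregate_pots(individuals, paper_pots)
        with pytest.raises(bp.MissingBaselineError):
            bp.monoculture_yield(
                species_biomass, paper_pots, "NOT_A_SPECIES", Treatment(False, False)
            )

    def test_canonical_dataset_partitions_forty_mixture_pots(
        self, paper_pots, generated
    ):
        _, individuals, _ = generated
        species_biomass, _ = bp.aggregate_pots(individuals, paper_pots)
        results, skips = bp.partition_dataset(species_biomass, paper_pots)
        assert len(results) == 40  # 2 mixture richness levels × 4 treatments × 5
        assert skips == []
        assert {r.richness for r in results} == {2, 4}

    def test_missing_baseline_skips_affected_mixtures(self, paper_pots, generated):
        _, individuals, _ = generated
        species_biomass, _ = bp.aggregate_pots(individuals, paper_pots)
        # drop one species' control monoculture rows entirely
        victim = sorted({
            s for p in paper_pots if p.composition.richness == 1
            for s in p.composition.members
        })[0]
        mono_control = [
            p.pot_id for p in paper_pots
            if p.composition.richness == 1
            and p.treatment == Treatment(False, False)
            and victim in p.composition.members
        ]
        pruned = species_biomass[
            ~species_biomass["pot_id"].isin(mono_control)
        ]
        results, skips = bp.partition_dataset(pruned, paper_pots)
        affected = [
            p.pot_id for p in paper_pots
            if p.composition.richness >= 2
            and p.treatment == Treatment(False, False)
            and victim in p.composition.members
        ]
        assert {pid for pid, _ in skips} == set(affected)
        assert len(results) == 40 - len(affected)
        assert all("baseline" in reason for _, reason in skips)

    def test_empty_input_gives_empty_output(self):
        empty = pd.DataFrame(columns=["pot_id", "species", "biomass_g"])
        results, skips = bp.partition_dataset(empty, [])
        assert results == [] and skips == []

    def test_effects_frame_schema(self, paper_pots, generated):
        _, individuals, _ = generated
        species_biomass, _ = bp.aggregate_pots(individuals, paper_pots)
        results, _ = bp.partition_dataset(species_biomass, paper_pots)
        effects, per_species = bp.partition_results_to_frames(results)
        assert list(effects.columns) == [
            "pot_id", "drought", "biochar", "richness", "expected_biomass_g",
            "observed_biomass_g", "nbe_g", "ce_g", "se_g", "additivity_residual_g",
        ]
        assert len(per_species) == sum(r.richness for r in results)
        assert (effects["additivity_residual_g"].abs()
                <= 1e-9 * np.maximum(1.0, effects["nbe_g"].abs())).all()
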