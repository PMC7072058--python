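"""Gate fitting, three-population classification, morphology split."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cytogate import (
    GateFitError,
    MixtureSimSpec,
    ParameterError,
    classify,
    classify_morphology,
    counts_to_concentration,
    fit_gates,
    fit_morphology_boundary,
    simulate_mixture,
    simulate_population,
    viable_spec,
)
from cytogate.gating import GateSet
from cytogate.pulse import EventFeatureTable
from tests.conftest import features


class TestFitGates:
    def test_well_separated_references_give_disjoint_cell_gates(self, gates):
        assert not gates.viable_gate.intersects(gates.dead_gate)

    def test_same_population_as_both_references_fails(self, reference_tables):
        _, ref_dead, ref_blank = reference_tables
        with pytest.raises(GateFitError, match="overlap"):
            fit_gates(ref_dead, ref_dead, ref_blank)

    def test_small_reference_rejected(self, reference_tables):
        ref_viable, ref_dead, ref_blank = reference_tables
        tiny = ref_viable.subset(np.arange(len(ref_viable)) < 50)
        with pytest.raises(ParameterError, match="pure_viable"):
            fit_gates(tiny, ref_dead, ref_blank)

    def test_fit_is_deterministic(self, reference_tables):
        g1 = fit_gates(*reference_tables)
        g2 = fit_gates(*reference_tables)
        assert g1.to_dict() == g2.to_dict()

    def test_serialisation_round_trip(self, gates_with_morphology, tmp_path):
        path = tmp_path / "gates.json"
        gates_with_morphology.save(path)
        back = GateSet.load(path)
        assert back.to_dict() == gates_with_morphology.to_dict()

    def test_cross_seed_label_agreement(self, gates):
        """Gates from seed-1 references classify fresh events >=97% correctly."""
        spec = MixtureSimSpec(p_viable=60, p_dead=40, seed=202, n_cell_events=20000)
        events, truth = simulate_mixture(spec)
        result = classify(features(events), gates)
        agreement = (result.labels == truth["label"].to_numpy()).mean()
        assert agreement >= 0.97


class TestClassify:
    def test_pure_viable_sample_viability_100(self, gates):
        table = features(simulate_population(viable_spec(), 2000, seed=31))
        result = classify(table, gates)
        assert result.viability_percent == pytest.approx(100.0, abs=0.2)

    def test_pure_dead_sample_viability_0(self, gates, reference_tables):
        from cytogate import dead_spec

        table = features(simulate_population(dead_spec(), 2000, seed=32))
        result = classify(table, gates)
        assert result.viability_percent == pytest.approx(0.0, abs=0.2)

    def test_mixture_recovery_with_background(self, gates):
        """60/40 with SSL background recovered within 2 points across seeds."""
        for seed in range(10):
            spec = MixtureSimSpec(p_viable=60, p_dead=40, r_yield=1.0, ssl_level=1.0,
                                  seed=300 + seed, n_cell_events=50000)
            events, _ = simulate_mixture(spec)
            result = classify(features(events), gates)
            assert result.viability_percent == pytest.approx(60.0, abs=2.0)

    def test_classification_is_a_partition(self, gates):
        spec = MixtureSimSpec(p_viable=40, p_dead=60, seed=41, n_cell_events=5000)
        events, _ = simulate_mixture(spec)
        table = features(events)
        result = classify(table, gates)
        assert result.total_events == len(table)
        assert set(result.counts) == {"viable", "dead", "background", "unclassified"}

    def test_adding_viable_gate_events_never_decreases_viable_count(self, gates):
        spec = MixtureSimSpec(p_viable=50, p_dead=50, seed=42, n_cell_events=3000)
        events, _ = simulate_mixture(spec)
        table = features(events)
        base = classify(table, gates)
        viable_rows = table.data[base.labels == "viable"].copy()
        viable_rows["event_id"] += 10_000_000
        bigger = EventFeatureTable(pd.concat([table.data, viable_rows], ignore_index=True))
        grown = classify(bigger, gates)
        assert grown.counts["viable"] == base.counts["viable"] * 2

    def test_saturated_green_events_stay_viable_and_are_flagged(self, gates):
        """Clip the green channel hard: events remain viable, saturation counted."""
        table = features(
            simulate_population(
                replace(viable_spec(), green_amp_median=80000.0), 1000, seed=43,
                adc_max=65535.0,
            )
        )
        sat = table.data["fl_green_saturated"].to_numpy(bool)
        assert sat.mean() > 0.5
        result = classify(table, gates)
        # every saturated event inside the cell windows stays viable
        assert (result.labels[sat] == "viable").mean() > 0.97
        assert result.flags["saturation_fraction"] > 0.5

    def test_empty_table_classifies_to_empty_result(self, gates):
        result = classify(features([]), gates)
        assert result.total_events == 0 and result.viability_percent is None

    def test_concentration_reporting(self, gates):
        table = features(simulate_population(viable_spec(), 500, seed=44))
        result = classify(table, gates, analyzed_volume_ul=100.0, dilution_factor=1000.0)
        assert result.concentrations_per_ml["total"] == pytest.approx(5e6)


class TestMorphology:
    def test_singlet_only_sample_has_no_budding(self, gates_with_morphology):
        table = features(simulate_population(viable_spec(), 2000, seed=51))
        m = classify_morphology(table, gates_with_morphology)
        assert m.n_budding / len(table) < 0.02

    def test_doublet_only_sample_all_budding(self, gates_with_morphology):
        table = features(
            simulate_population(replace(viable_spec(), budding_fraction=1.0), 2000, seed=52)
        )
        m = classify_morphology(table, gates_with_morphology)
        assert m.n_budding / len(table) > 0.95
        assert m.budding_ratio_infinite or m.budding_ratio > 19

    def test_budding_fraction_recovery(self, gates_with_morphology):
        """30% budding recovered as budding/(single+budding) = 0.30 +/- 0.03."""
        fracs = []
        for seed in range(10):
            spec = MixtureSimSpec(p_viable=100, p_dead=0, ssl_level=0.0,
                                  budding_fraction=0.3, seed=600 + seed,
                                  n_cell_events=5000)
            events, _ = simulate_mixture(spec)
            table = features(events)
            result = classify(table, gates_with_morphology)
            viable = table.subset(result.labels == "viable")
            m = classify_morphology(viable, gates_with_morphology)
            fracs.append(m.n_budding / (m.n_single + m.n_budding))
        assert np.mean(fracs) == pytest.approx(0.30, abs=0.03)

    def test_missing_boundary_rejected(self, gates):
        table = features(simulate_population(viable_spec(), 100, seed=53))
        with pytest.raises(ParameterError):
            classify_morphology(table, gates)

    def test_boundary_references_too_small_rejected(self, gates):
        table = features(simulate_population(viable_spec(), 5, seed=54))
        with pytest.raises(ParameterError):
            fit_morphology_boundary(table, table)


class TestConcentration:
    def test_basic_arithmetic(self):
        assert counts_to_concentration(500, 100.0, 1.0) == pytest.approx(5000.0)

    def test_dilution_linearity(self):
        assert counts_to_concentration(500, 100.0, 1000.0) == pytest.approx(5e6)
        assert counts_to_concentration(250, 100.0, 1000.0) == pytest.approx(2.5e6)

    def test_zero_events(self):
        assert counts_to_concentration(0, 100.0) == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            counts_to_concentration(1, 0.0)
        with pytest.raises(ParameterError):
            counts_to_concentration(1, 10.0, 0.5)
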