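"""Shared fixtures: simulated reference populations and fitted gate sets."""

from dataclasses import replace

import pytest

from cytogate import (
    build_feature_table,
    dead_spec,
    fit_gates,
    fit_morphology_boundary,
    simulate_population,
    ssl_spec,
    viable_spec,
)
from cytogate.simulate import DEFAULT_LENGTH_THRESHOLD

N_REFERENCE = 4000


def features(events):
    """Feature extraction with the standard pipeline length threshold."""
    return build_feature_table(events, length_threshold=DEFAULT_LENGTH_THRESHOLD)


@pytest.fixture(scope="session")
def reference_tables():
    """Pure viable / dead / medium-blank reference feature tables."""
    ref_viable = features(simulate_population(viable_spec(), N_REFERENCE, seed=10))
    ref_dead = features(simulate_population(dead_spec(), N_REFERENCE, seed=11))
    ref_blank = features(simulate_population(ssl_spec(), N_REFERENCE, seed=12))
    return ref_viable, ref_dead, ref_blank


@pytest.fixture(scope="session")
def gates(reference_tables):
    """Default gate set fitted on the session reference populations."""
    return fit_gates(*reference_tables)


@pytest.fixture(scope="session")
def gates_with_morphology(reference_tables):
    """Gate set with a morphology boundary fitted on singlet/doublet references.

    The viable reference here contains budding cells, as a growing pre-culture
    does, so the cell size/shape windows span doublet pulses too.
    """
    _, ref_dead, ref_blank = reference_tables
    ref_viable = features(
        simulate_population(replace(viable_spec(), budding_fraction=0.3), N_REFERENCE, seed=20)
    )
    g = fit_gates(ref_viable, ref_dead, ref_blank)
    singles = features(simulate_population(viable_spec(), 3000, seed=21))
    doublets = features(
        simulate_population(replace(viable_spec(), budding_fraction=1.0), 3000, seed=22)
    )
    g.morphology_boundary = fit_morphology_boundary(singles, doublets)
    return g
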