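import pytest

import fluxko as fk


def battery_network(seed_index: int) -> fk.MetabolicNetwork:
    """Random test network #seed_index of the cross-validation battery.

    Small enough (<= 8 reactions, <= 6 metabolites) for the brute-force
    lattice oracle; mixes reversibility fractions and densities.
    """
    n_met = 3 + seed_index % 4
    n_int = 4 + seed_index % 3
    frac = [0.0, 0.3, 0.5][seed_index % 3]
    dens = 0.4 + 0.02 * (seed_index % 5)
    return fk.random_network(
        n_met, n_int, frac, dens, seed=100 + seed_index, n_exchanges=2
    )


BATTERY_SEEDS = list(range(30))


@pytest.fixture(scope="session")
def figure1():
    return fk.figure1_fixture()


@pytest.fixture(scope="session")
def figure1_analysis(figure1):
    """Shared FCA + double-knockout results on the worked example."""
    model = fk.ConeModel(figure1)
    table, pool = fk.fca(model)
    partition = fk.partial_classes(table)
    records = fk.double_knockout_analysis(model, table=table, pool=pool)
    return model, table, pool, partition, records


@pytest.fixture(scope="session")
def figure1_lattice(figure1):
    return fk.enumerate_lattice(figure1)
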