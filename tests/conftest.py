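import pytest

from xlinkprm import (
    RosterEntry,
    SimulationConfig,
    load_table1,
    load_table2,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def small_config(table1):
    """A 5-pair roster (one isomeric-precursor collision pair included) with
    2 decoys: fast enough for per-module tests, rich enough to exercise the
    cascade."""
    by_id = {r.id: r for r in table1}
    entries = []
    for rid in (1, 4, 27, 35, 45):  # ids 4 and 35 share a precursor m/z at 4+
        row = by_id[rid]
        entries.append(
            RosterEntry(pair=row.pair, charge=row.z_list[0], rt_center=row.rt_list[0])
        )
    return SimulationConfig(roster=tuple(entries), n_decoys=2, seed=123)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_cohort(small_config)
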