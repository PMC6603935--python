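"""Shared fixtures: panels, frequency tables (synthetic), tiny TSV writers."""

import numpy as np
import pandas as pd
import pytest

from ethnorisk import (
    FrequencyTable,
    SimulationConfig,
    builtin_panel,
    make_null_table,
    simulate_frequency_table,
)
from ethnorisk.frequency import TSV_COLUMNS


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture(scope="session")
def dedup_panel():
    return builtin_panel("table1_dedup")


@pytest.fixture(scope="session")
def null_table(panel):
    return make_null_table(panel)


@pytest.fixture(scope="session")
def sim_table(panel):
    """A differentiated table mirroring the builtin panel (fixed seed)."""
    return simulate_frequency_table(SimulationConfig(seed=20240611, panel=panel, fst=0.15))


def random_frequency_table(rng, rsids, populations=("AFR", "EAS", "EUR", "SAS", "ALL"), n=500):
    """Random valid genotype-frequency table via Dirichlet triples (oracle helper)."""
    rows = []
    for rsid in rsids:
        for pop in populations:
            f_rr, f_ra, f_aa = rng.dirichlet((2.0, 2.0, 2.0))
            rows.append((rsid, pop, n, f_rr, f_ra, f_aa))
    return FrequencyTable(pd.DataFrame(rows, columns=list(TSV_COLUMNS)), source="random")


def write_tsv(path, rows, header="rsid\tpopulation\tn\tf_hom_ref\tf_het\tf_hom_alt"):
    lines = [header] + ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
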