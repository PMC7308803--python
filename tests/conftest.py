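import numpy as np
import pandas as pd
import pytest

from agestrat_prs.datatypes import GenotypePanel
from agestrat_prs.simulate import (
    SimulationConfig,
    attach_apoe,
    simulate_discovery_sumstats,
    simulate_genotypes,
    simulate_parents,
    simulate_phenotype,
)


@pytest.fixture(scope="session")
def tiny_config():
    """A small but non-degenerate proxy-design cohort configuration."""
    return SimulationConfig(
        seed=11, n_variants=60, n_blocks=12, n_target=2_000, n_discovery=4_000,
        n_causal=20, proxy=True,
    )


@pytest.fixture(scope="session")
def apoe_panel(tiny_config):
    return attach_apoe(simulate_genotypes(tiny_config), tiny_config)


@pytest.fixture(scope="session")
def cohort(tiny_config, apoe_panel):
    """(panel, child table with proxy fields, discovery sumstats)."""
    _, _, table = simulate_parents(apoe_panel, tiny_config)
    sumstats = simulate_discovery_sumstats(tiny_config)
    return apoe_panel, table, sumstats


@pytest.fixture(scope="session")
def case_control_table(tiny_config, apoe_panel):
    return simulate_phenotype(apoe_panel, tiny_config)


def make_panel(dosages, chrom="1", spacing=1000, missing=None, effect="A", other="G",
               pos=None, ids=None):
    """Hand-built panel for unit fixtures: one chromosome, fixed alleles."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"v{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": pos if pos is not None else 1 + np.arange(m) * spacing,
            "effect_allele": [effect] * m if isinstance(effect, str) else effect,
            "other_allele": [other] * m if isinstance(other, str) else other,
        }
    )
    return GenotypePanel(
        sample_ids=np.array([f"s{i + 1}" for i in range(n)]),
        variants=variants,
        dosages=dosages,
        missing=missing,
    )
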