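import pandas as pd
import pytest

from dasekit.group_selection import ContrastGroups
from dasekit.synthetic_data import Population, SimConfig, simulate_population


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(
        n_animals=40,
        n_sires=20,
        traits=("T1", "T2"),
        n_snps=60,
        het_prob=0.6,
        dase_fraction=0.2,
        pi_shift=0.25,
        seed=7,
    )


@pytest.fixture
def small_population(small_config) -> Population:
    return simulate_population(small_config)


@pytest.fixture
def toy_groups() -> ContrastGroups:
    return ContrastGroups(
        trait="T1",
        high=("H1", "H2", "H3", "H4"),
        low=("L1", "L2", "L3", "L4"),
    )


def make_counts(records) -> pd.DataFrame:
    """Build a long-format count table from (sample, snp, ref, alt) tuples."""
    rows = []
    for sample, snp, ref, alt in records:
        rows.append(
            {
                "sample_id": sample,
                "contig": "1",
                "position": 1000 + int(snp.lstrip("s")) if snp.startswith("s") else 1000,
                "variantID": snp,
                "refAllele": "A",
                "altAllele": "G",
                "refCount": ref,
                "altCount": alt,
            }
        )
    return pd.DataFrame(rows)
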