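import numpy as np
import pandas as pd
import pytest

from pwas import (
    BinderSpec,
    SimulationConfig,
    SnpRecord,
    load_default_panel,
    simulate_pair,
)
from pwas.simulate import FORWARD, REVERSE, PulldownExperiment


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def snp(panel):
    """rs12722495, the first panel record (alleles A/G)."""
    return panel[0]


@pytest.fixture
def tiny_record():
    return SnpRecord(
        rsid="rs_test", left_flank="ACGT", alleles=("A", "G"), right_flank="TTCC",
        group="group 1",
    )


@pytest.fixture
def small_config():
    """Reduced-scale generator settings for fast unit tests."""
    return SimulationConfig(seed=1234, n_background=200, n_contaminants=10)


def make_experiment(rows, rsid="rs_test", orientation=FORWARD, alleles=("A", "G")):
    """Build a PulldownExperiment from (protein, peptide, unique, ratio) tuples."""
    heavy, light = alleles if orientation == FORWARD else alleles[::-1]
    exp = PulldownExperiment(rsid=rsid, orientation=orientation,
                             heavy_allele=heavy, light_allele=light)
    exp.evidence = pd.DataFrame(
        {
            "experiment_id": f"{rsid}_{orientation}",
            "protein_id": [r[0] for r in rows],
            "peptide_sequence": [r[1] for r in rows],
            "is_unique": [r[2] for r in rows],
            "ratio_hl": [r[3] for r in rows],
            "intensity": 1e6,
        }
    )
    return exp


@pytest.fixture
def spiked_pair(snp):
    """Default-scale pair with one tenfold allele-1 binder and one contaminant."""
    binders = [
        BinderSpec("TF10", target_allele=snp.alleles[0], fold_change=10.0, n_peptides=10),
    ]
    cfg = SimulationConfig(seed=77)
    return simulate_pair(snp, binders, cfg)
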