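import logging

import numpy as np
import pandas as pd
import pytest

from silac_turnover import (
    SimulationConfig,
    estimate_purity_table,
    generate_proteome,
    simulate_silac_experiment,
)

logging.getLogger("silac_turnover").setLevel(logging.ERROR)


@pytest.fixture
def small_config():
    """A small but complete experiment design for fast end-to-end tests."""
    return SimulationConfig(
        n_proteins=40, peptides_per_protein_mean=4.0, n_injections=2,
        n_complexes=0, seed=7,
    )


@pytest.fixture
def small_run(small_config):
    """(peptide table, label counts, ground truth, purities) at small scale."""
    proteome = generate_proteome(small_config)
    table, counts, truth = simulate_silac_experiment(proteome, small_config)
    purities = estimate_purity_table(counts)
    return table, counts, truth, purities


def make_oldfrac_rows(entries):
    """Build a minimal %old-annotated peptide table from
    (protein, sequence, timepoint, replicate, injection, fraction_old) rows."""
    frame = pd.DataFrame(
        entries,
        columns=["protein_group", "sequence", "timepoint", "replicate",
                 "injection", "fraction_old"],
    )
    frame["condition"] = "mixed"
    frame["missed_cleavages"] = 0
    frame["excluded"] = False
    frame["reason"] = ""
    return frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
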