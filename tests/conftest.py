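import numpy as np
import pytest

from genomotyper import SimulationConfig, simulate_experiment
from genomotyper.calling import PresenceMatrix, call_presence, fit_all_strains
from genomotyper.preprocess import average_replicates, filter_selfself_background


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions: 16 strains, 1 outgroup, triplicates, 10k probes."""
    cfg = SimulationConfig(seed=23)
    truth, arrays = simulate_experiment(cfg)
    return cfg, truth, arrays


@pytest.fixture(scope="session")
def default_calls(default_sim):
    """QC'd, averaged and EPP-called presence matrix for the default run."""
    _, _, arrays = default_sim
    qc = filter_selfself_background(arrays.selfself)
    tensor = arrays.tensor.subset_probes(qc.kept)
    rm = average_replicates(tensor)
    fits = fit_all_strains(rm)
    return qc, rm, fits, call_presence(fits, rm)


def make_presence(rng, n_genes, strains, p=0.7, reference=None, outgroups=()):
    """Random binary presence matrix for combinatorial-stage tests."""
    P = (rng.random((n_genes, len(strains))) < p).astype(np.int8)
    return PresenceMatrix(
        probe_ids=[f"g{i:04d}" for i in range(n_genes)], strains=list(strains),
        P=P, epp=P.astype(float), reference=reference, outgroups=list(outgroups))
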