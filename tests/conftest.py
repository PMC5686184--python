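import numpy as np
import pytest

from ernatlas import discovery, simulate


@pytest.fixture(scope="session")
def sim_cfg():
    return simulate.SimConfig(seed=42)


@pytest.fixture(scope="session")
def genome_bundle(sim_cfg):
    """Synthetic genome with planted enhancers and labelled decoys."""
    return simulate.generate_genome_bundle(sim_cfg)


@pytest.fixture(scope="session")
def filtered_bundle(genome_bundle, sim_cfg):
    """Consensus peaks run through the seven-criterion cascade."""
    ann, peaks, signals, truth = genome_bundle
    k27 = discovery.consensus_peaks(peaks["H3K27ac"], 0.7)
    me1 = discovery.consensus_peaks(peaks["H3K4me1"], 0.7)
    candidates, trace = discovery.filter_candidates(
        k27, me1, signals["H3K4me1"], signals["H3K4me3"], ann)
    return candidates, trace, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
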