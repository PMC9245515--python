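import numpy as np
import pytest

from colptm.chain_model import CollagenChain
from colptm.synthetic_data import SimulationConfig, generate_chain, place_planted_sites


@pytest.fixture
def toy_chain():
    # 22-residue chain: flank + G-X-Y triplets with a GXK motif and a GPP cluster
    #            1234567890123456789012
    return CollagenChain(id="toy", sequence="MALSAGPPGPKGDAGPPGAAGR")


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture
def sim_chain(sim_config):
    return generate_chain(sim_config)


@pytest.fixture
def sim_planted(sim_chain, sim_config):
    return place_planted_sites(sim_chain, sim_config)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
    return path
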