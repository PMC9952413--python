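import numpy as np
import pytest

from prosfold import synthetic
from prosfold.structio import Atom, Chain, ProSRecord, Residue, Structure


def make_structure(ca_coords, chain_id="A", seq=None, b_factors=None,
                   source_id="synthetic") -> Structure:
    """Calpha-only structure from an Nx3 coordinate array."""
    ca = np.asarray(ca_coords, float)
    seq = seq or "A" * len(ca)
    residues = []
    for i, xyz in enumerate(ca):
        b = float(b_factors[i]) if b_factors is not None else 0.0
        residues.append(Residue(code=seq[i], number=i + 1,
                                atoms=[Atom("CA", "C", np.array(xyz), b_factor=b)]))
    return Structure(chains=[Chain(chain_id, residues)], source_id=source_id)


def make_record(length, exp_chain="A", partners=(), reliability="verified",
                uniprot_ac="P00001", start=1) -> ProSRecord:
    return ProSRecord(
        uniprot_ac=uniprot_ac, ideal_id="IID00000",
        region=(start, start + length - 1), reliability=reliability,
        exp_source="exp", exp_chain=exp_chain,
        partner_chain_ids=list(partners), model_source="model")


@pytest.fixture(scope="session")
def helix_pair():
    """Noise-free 33-residue long-helix pair with an in-contact partner."""
    spec = synthetic.SynthSpec("long_helix", 33, noise_sigma=0.0,
                               plddt_mean=82.0, seed=11)
    return synthetic.gen_structure_pair(spec)


@pytest.fixture(scope="session")
def noisy_coil_pair():
    spec = synthetic.SynthSpec("extended_coil", 20, noise_sigma=4.0,
                               plddt_mean=55.0, seed=12)
    return synthetic.gen_structure_pair(spec)
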