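import numpy as np
import pytest

from cgphase import load_residue_params


@pytest.fixture(scope="session")
def params():
    return load_residue_params()


@pytest.fixture(scope="session")
def fus_fasta(tmp_path_factory):
    """Synthetic stand-in for a full-length FUS FASTA (526 residues).

    Not the real UniProt K7DPS7 sequence -- a deterministic pseudo-random
    sequence of the right length for interface tests only.
    """
    rng = np.random.default_rng(42)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seq = "".join(rng.choice(letters, 526))
    path = tmp_path_factory.mktemp("fasta") / "fus_synthetic.fasta"
    path.write_text(">FUS_synthetic full-length stand-in\n" + seq + "\n")
    return path
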