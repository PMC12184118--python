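import numpy as np
import pytest

from mampipe import ProteinRecord, parse_pattern
from mampipe.reference import (
    LEADER_MOTIF_TEXT,
    MAM_LENGTH,
    MAM_NTERM_42,
    PCAT_MOTIF_TEXT,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def mam42():
    """The 42-residue N-terminal peptide of MAM identified by LC-MS/MS."""
    return ProteinRecord(id="MAM_nterm42", sequence=MAM_NTERM_42)


@pytest.fixture
def leader_motif():
    return parse_pattern(LEADER_MOTIF_TEXT)


@pytest.fixture
def pcat_motif():
    return parse_pattern(PCAT_MOTIF_TEXT)


@pytest.fixture
def mam_like_135():
    """Synthetic 135-residue stand-in for full-length MAM.

    The real C7H4X2 record cannot be bundled; this chain starts with the
    published 42-mer and continues with seeded random residues, so only
    positional/length facts (leader at 1-21, length 135) may be asserted
    against it, never composition-dependent ones.
    """
    rng = np.random.default_rng(135)
    tail = "".join(rng.choice(list(AA), size=MAM_LENGTH - len(MAM_NTERM_42)))
    return ProteinRecord(id="MAM_synthetic135", sequence=MAM_NTERM_42 + tail)


def random_protein(rng, length, alphabet=AA):
    return "".join(rng.choice(list(alphabet), size=length))
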