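import numpy as np
import pandas as pd
import pytest

from chondrax import AMINO_ACIDS, PSSM, PanelSpec, simulate_panel, simulate_pssm


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform_pssm():
    """Degenerate matrix: every residue scores 1 at every position."""
    return PSSM(np.ones((8, 20)))


@pytest.fixture
def random_pssm():
    return simulate_pssm(seed=7)


@pytest.fixture
def consensus_pssm():
    """A selective motif: one consensus residue per position scores 1, others 0.

    Random peptides then score in multiples of 1/8, so chance hits above a
    cutoff between 3/8 and 4/8 need four consensus matches.
    """
    scores = np.zeros((8, 20))
    consensus = "RSPDGEAS"
    for pos, aa in enumerate(consensus):
        scores[pos, AMINO_ACIDS.index(aa)] = 1.0
    return PSSM(scores)


@pytest.fixture
def small_panel():
    """16-strain single-factor panel with the default 14 matrix genes."""
    spec = PanelSpec(n_genes=60, seed=11)
    panel, truth = simulate_panel(spec)
    return spec, panel, truth


def random_peptide(rng, alphabet=AMINO_ACIDS, length=8):
    return "".join(rng.choice(list(alphabet), size=length))
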