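import numpy as np
import pytest

from oyescan import synthgen as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pangenome():
    """A 2+2-genome pangenome with decoys, a fusion carrier and markers."""
    design = sg.PangenomeDesign(
        phenotype={"p1": sg.POSITIVE, "p2": sg.POSITIVE,
                   "n1": sg.NEGATIVE, "n2": sg.NEGATIVE},
        decoy_family_ids=("d0", "d1"),
        fusion_carriers=frozenset({"p2"}),
        marker_proximal=frozenset({"p1"}),
        marker_distal=frozenset({"p2"}),
        protein_len=80,
        partner_len=60,
        marker_len=60,
        divergence=0.1,
    )
    genomes, truth = sg.build_pangenome(design, seed=7)
    return design, genomes, truth
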