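import numpy as np
import pytest

from geneloss.simulate import sim_reference_gene
from geneloss.trees import SpeciesTree


@pytest.fixture(scope="session")
def gba3_model():
    """Synthetic five-exon reference with the 1407-bp / 469-aa geometry."""
    return sim_reference_gene(seed=42)


@pytest.fixture(scope="session")
def six_taxon_tree():
    nw = ("(((a:0.15,b:0.15):0.08,(c:0.15,d:0.15):0.08):0.05,"
          "(e:0.2,f:0.2):0.05);")
    return SpeciesTree.from_newick_string(
        nw, clade_labels={"X": ["a", "b"]}, branch_labels={"BX": ["a", "b"]})


@pytest.fixture(scope="session")
def eight_taxon_tree():
    nw = ("(((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05):0.05,"
          "((e:0.1,f:0.1):0.05,(g:0.1,h:0.1):0.05):0.05);")
    return SpeciesTree.from_newick_string(nw)


@pytest.fixture(scope="session")
def uniform_pi():
    return np.full(61, 1.0 / 61.0)
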