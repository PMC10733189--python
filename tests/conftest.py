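import warnings

import dendropy
import pytest

from photorep.simulate import SimConfig, simulate_bundle

warnings.filterwarnings("ignore", category=DeprecationWarning)


def rooted(newick: str, label_internals: bool = True) -> dendropy.Tree:
    """Parse a rooted tree; label internal nodes n1, n2, ... in preorder."""
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    t.is_rooted = True
    if label_internals:
        i = 0
        for nd in t.preorder_node_iter():
            if nd.is_leaf():
                nd.label = nd.taxon.label
            else:
                i += 1
                nd.label = f"n{i}"
    return t


@pytest.fixture(scope="session")
def small_bundle():
    """Four species, seven families, no decoys; shared across read-only tests."""
    return simulate_bundle(SimConfig(seed=2, n_species=4))


@pytest.fixture(scope="session")
def small_panel(small_bundle):
    from photorep.classify import ReferencePanel

    return ReferencePanel.from_ungapped(
        small_bundle.panel_records, small_bundle.panel_labels,
        small_bundle.panel_outgroups)
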