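import numpy as np
import pytest
from hypothesis import settings

import lineagesel as ls

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mito():
    return ls.load_genetic_code("vertebrate_mitochondrial")


@pytest.fixture(scope="session")
def standard():
    return ls.load_genetic_code("standard")


@pytest.fixture
def quartet_tree():
    """Rooted 4-leaf tree ((A,B),(C,D)) with all-background branches."""
    groups = ls.GroupAssignment(
        taxon_to_group={t: "surface" for t in "ABCD"},
        group_to_role={"surface": "background"},
    )
    newick = "((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.08);"
    return ls.label_branches(newick, groups, mode="terminal")


def make_alignment(rows):
    """Build a CodonAlignment from {taxon: [codon or None, ...]}."""
    taxa = list(rows)
    sites = len(next(iter(rows.values())))
    return ls.CodonAlignment(taxa=taxa, sites=sites, states={t: list(v) for t, v in rows.items()})


def labeled_tree(newick, foreground=(), outgroup=(), mode="clade"):
    """Label a newick string given foreground/outgroup taxon names."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted",
                             preserve_underscores=True)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    taxon_to_group, roles = {}, {}
    for t in taxa:
        if t in foreground:
            taxon_to_group[t] = "fg"
            roles["fg"] = "foreground"
        elif t in outgroup:
            taxon_to_group[t] = "out"
            roles["out"] = "outgroup"
        else:
            taxon_to_group[t] = "bg"
            roles["bg"] = "background"
    groups = ls.GroupAssignment(taxon_to_group=taxon_to_group, group_to_role=roles)
    return ls.label_branches(newick, groups, mode=mode)


@pytest.fixture(scope="session")
def study_scenario():
    return ls.study_like_scenario(seed=20260)


@pytest.fixture(scope="session")
def study_simulation(study_scenario):
    return ls.simulate(study_scenario)
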