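"""Parsimony ancestral reconstruction and per-branch substitution events.

Ancestral codon states are inferred per site by Fitch parsimony over the
sense-codon state space (missing leaves contribute the full state set),
with a deterministic top-down resolution: the root takes its most
frequent candidate among the observed leaf states (ties lexicographic),
and every other node prefers the parent's state when it lies in its
candidate set, otherwise the lexicographically smallest candidate.  Each branch/site pair where the
parent and child states differ yields one :class:`SubstitutionEvent`
whose multi-nucleotide changes are decomposed into synonymous and
nonsynonymous steps by averaging over stop-free mutational pathways
(Nei–Gojobori-style counting).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Optional

from lineagesel.genetics_io import CodonAlignment, GeneticCode, LabeledTree


@dataclass
class AncestralStates:
    """Per-node, per-site codon states after Fitch tie resolution.

    ``states[node_id][site-1]`` is a codon or ``None`` (all-missing
    site, or a missing leaf).  ``candidates`` holds the pre-resolution
    Fitch sets; ``changes[site-1]`` is the per-site minimum change
    count; ``flagged_sites`` lists 1-based sites with no data at all.
    """

    states: dict
    candidates: dict
    changes: list
    flagged_sites: list


def fitch_states(aln: CodonAlignment, tree: LabeledTree) -> AncestralStates:
    """Fitch parsimony over codon states, per site.

    Missing leaf states impose no constraint (they contribute the full
    sense-codon set during the bottom-up pass and inherit the parent's
    state in the top-down pass, producing no event on their branch).
    """
    leaf_taxa = tree.leaf_taxa
    if sorted(aln.taxa) != leaf_taxa:
        raise ValueError("alignment taxa do not match tree leaves")
    if len(leaf_taxa) < 3:
        raise ValueError("need at least 3 taxa for ancestral reconstruction")

    all_states = frozenset(
        {c for row in aln.states.values() for c in row if c is not None}
    )
    postorder = list(tree.tree.postorder_node_iter())
    preorder = list(tree.tree.preorder_node_iter())

    states = {n.branch_id: [None] * aln.sites for n in postorder}
    candidates = {n.branch_id: [None] * aln.sites for n in postorder}
    changes = [0] * aln.sites
    flagged = []

    for s in range(aln.sites):
        observed = {
            t: aln.states[t][s] for t in aln.taxa if aln.states[t][s] is not None
        }
        if not observed:
            flagged.append(s + 1)
            continue
        site_states = frozenset(observed.values()) or all_states

        # bottom-up: intersection if nonempty, else union (+1 change)
        upsets = {}
        n_changes = 0
        for node in postorder:
            if node.is_leaf():
                c = observed.get(node.taxon.label)
                upsets[node.branch_id] = frozenset([c]) if c is not None else site_states
            else:
                kids = [upsets[k.branch_id] for k in node.child_nodes()]
                acc = kids[0]
                for other in kids[1:]:
                    inter = acc & other
                    if inter:
                        acc = inter
                    else:
                        acc = acc | other
                        n_changes += 1
                upsets[node.branch_id] = acc
        changes[s] = n_changes

        # top-down: parent-preferring, then lexicographic
        for node in preorder:
            bid = node.branch_id
            cand = upsets[bid]
            candidates[bid][s] = cand
            if node.parent_node is None:
                # root tie-break: the most frequent observed state among the
                # candidates (then lexicographic).  A frequency-blind choice
                # can root rare derived states and misattribute root-adjacent
                # changes to the wrong side of the basal split.
                freq = {}
                for c in observed.values():
                    freq[c] = freq.get(c, 0) + 1
                states[bid][s] = min(cand, key=lambda c: (-freq.get(c, 0), c))
            else:
                parent_state = states[node.parent_node.branch_id][s]
                if node.is_leaf():
                    obs = observed.get(node.taxon.label)
                    states[bid][s] = obs  # None for a missing leaf
                elif parent_state in cand:
                    states[bid][s] = parent_state
                else:
                    states[bid][s] = min(cand)

    return AncestralStates(
        states=states, candidates=candidates, changes=changes, flagged_sites=flagged
    )


def classify_codon_change(from_codon: str, to_codon: str, code: GeneticCode):
    """Expected synonymous/nonsynonymous steps between two sense codons.

    Enumerates all orderings of the single-nucleotide steps from
    ``from_codon`` to ``to_codon``, discards pathways passing through a
    stop codon, scores each step by the genetic code and averages over
    the surviving pathways.  If every pathway is blocked by stops, each
    differing position is scored in the ``from_codon`` context
    directly; :func:`pathway_blocked` lets a caller detect that
    fallback.

    Returns ``(n_syn, n_nonsyn)``; their sum equals the nucleotide
    Hamming distance between the codons.
    """
    if from_codon == to_codon:
        raise ValueError("codons are identical")
    if not code.is_sense(from_codon) or not code.is_sense(to_codon):
        raise ValueError(f"stop codon in change {from_codon}->{to_codon}")
    diff = [i for i in range(3) if from_codon[i] != to_codon[i]]
    totals = []
    for order in permutations(diff):
        cur = from_codon
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + to_codon[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.translate(cur) == code.translate(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            totals.append((syn, nonsyn))
    if not totals:
        # all pathways stop-blocked: score each position in the source context
        syn = nonsyn = 0
        for pos in diff:
            nxt = from_codon[:pos] + to_codon[pos] + from_codon[pos + 1 :]
            if code.is_stop(nxt) or code.translate(from_codon) != code.translate(nxt):
                nonsyn += 1
            else:
                syn += 1
        return float(syn), float(nonsyn)
    n = len(totals)
    return sum(t[0] for t in totals) / n, sum(t[1] for t in totals) / n


def pathway_blocked(from_codon: str, to_codon: str, code: GeneticCode) -> bool:
    """True when every single-step pathway between the codons crosses a stop."""
    diff = [i for i in range(3) if from_codon[i] != to_codon[i]]
    for order in permutations(diff):
        cur = from_codon
        ok = True
        for pos in order:
            cur = cur[:pos] + to_codon[pos] + cur[pos + 1 :]
            if code.is_stop(cur):
                ok = False
                break
        if ok:
            return False
    return True


@dataclass(frozen=True)
class SubstitutionEvent:
    """One inferred codon change on one branch at one site."""

    branch_id: str
    parent_id: str
    branch_class: str
    site: int          # 1-based codon index
    from_codon: str
    to_codon: str
    n_syn: float
    n_nonsyn: float
    from_aa: str
    to_aa: str

    @property
    def is_nonsynonymous(self) -> bool:
        return self.n_nonsyn > 0

    @property
    def is_synonymous(self) -> bool:
        return self.n_syn > 0


def map_events(states: AncestralStates, tree: LabeledTree, code: GeneticCode) -> list:
    """Enumerate substitution events on every branch of the labeled tree."""
    events = []
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        child = states.states[node.branch_id]
        parent = states.states[node.parent_node.branch_id]
        for s in range(len(child)):
            a, b = parent[s], child[s]
            if a is None or b is None or a == b:
                continue
            n_syn, n_nonsyn = classify_codon_change(a, b, code)
            events.append(
                SubstitutionEvent(
                    branch_id=node.branch_id,
                    parent_id=node.parent_node.branch_id,
                    branch_class=getattr(node, "branch_class", "background"),
                    site=s + 1,
                    from_codon=a,
                    to_codon=b,
                    n_syn=n_syn,
                    n_nonsyn=n_nonsyn,
                    from_aa=code.translate(a),
                    to_aa=code.translate(b),
                )
            )
    return events


def write_events_tsv(events: list, path) -> None:
    import pandas as pd

    rows = [
        {
            "branch": e.branch_id,
            "parent_node": e.parent_id,
            "child_node": e.branch_id,
            "branch_class": e.branch_class,
            "site": e.site,
            "from_codon": e.from_codon,
            "to_codon": e.to_codon,
            "n_syn": e.n_syn,
            "n_nonsyn": e.n_nonsyn,
            "from_aa": e.from_aa,
            "to_aa": e.to_aa,
        }
        for e in sorted(events, key=lambda e: (e.site, e.branch_id))
    ]
    pd.DataFrame(
        rows,
        columns=[
            "branch", "parent_node", "child_node", "branch_class", "site",
            "from_codon", "to_codon", "n_syn", "n_nonsyn", "from_aa", "to_aa",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list:
    """Read an events TSV written by :func:`write_events_tsv`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"branch": str, "parent_node": str})
    return [
        SubstitutionEvent(
            branch_id=row["branch"],
            parent_id=row["parent_node"],
            branch_class=row["branch_class"],
            site=int(row["site"]),
            from_codon=row["from_codon"],
            to_codon=row["to_codon"],
            n_syn=float(row["n_syn"]),
            n_nonsyn=float(row["n_nonsyn"]),
            from_aa=row["from_aa"],
            to_aa=row["to_aa"],
        )
        for _, row in df.iterrows()
    ]
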