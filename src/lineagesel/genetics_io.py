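"""Readers/writers for alignments, trees, group tables and domain maps.

Conventions used throughout the package:

* codon sites and amino-acid positions are 1-based and inclusive
  (nucleotides of codon ``i`` are ``3i-2 .. 3i``);
* any codon containing a non-ACGT character is missing data;
* the default genetic code is the vertebrate mitochondrial one
  (NCBI translation table 2: 60 sense codons, AGA/AGG/TAA/TAG stops,
  ATA→Met, TGA→Trp), since the motivating application is a
  mitochondrially encoded gene;
* trees must be supplied rooted; no rerooting is performed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
BRANCH_CLASSES = ("foreground", "background", "excluded")
ROLES = ("foreground", "background", "outgroup")

_BUILTIN_CODES = {
    "standard": "Standard",
    "vertebrate_mitochondrial": "Vertebrate Mitochondrial",
}


@dataclass(frozen=True)
class GeneticCode:
    """A total map from the 64 codons to amino acids ('*' marks stops)."""

    name: str
    codon_to_aa: dict

    def __post_init__(self):
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code {self.name!r} has {len(self.codon_to_aa)} codons, expected 64"
            )
        for codon, aa in self.codon_to_aa.items():
            if len(codon) != 3 or any(n not in NUCLEOTIDES for n in codon):
                raise ValueError(f"invalid codon {codon!r}")
            if len(aa) != 1:
                raise ValueError(f"invalid amino acid {aa!r} for codon {codon}")

    @property
    def sense_codons(self) -> tuple:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != "*"))

    @property
    def stop_codons(self) -> tuple:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa == "*"))

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == "*"

    def is_sense(self, codon: str) -> bool:
        aa = self.codon_to_aa.get(codon)
        return aa is not None and aa != "*"


def load_genetic_code(name_or_table: str) -> GeneticCode:
    """Load a genetic code by built-in name or from a two-column TSV.

    Built-ins: ``"vertebrate_mitochondrial"`` (the default throughout
    the package) and ``"standard"``.  A TSV table must have columns
    ``codon`` and ``aa`` covering all 64 codons exactly once; stops are
    written ``*``.
    """
    key = str(name_or_table)
    if key in _BUILTIN_CODES:
        table = CodonTable.unambiguous_dna_by_name[_BUILTIN_CODES[key]]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return GeneticCode(name=key, codon_to_aa=mapping)
    path = Path(key)
    if not path.exists():
        raise ValueError(
            f"unknown genetic code {key!r}: not a built-in "
            f"({', '.join(sorted(_BUILTIN_CODES))}) and not a file"
        )
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"codon", "aa"} <= set(df.columns):
        raise ValueError("genetic code table needs columns 'codon' and 'aa'")
    codons = [c.upper() for c in df["codon"]]
    if len(set(codons)) != len(codons):
        raise ValueError("duplicate codons in genetic code table")
    mapping = dict(zip(codons, df["aa"]))
    missing = {a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES} - set(mapping)
    if missing:
        raise ValueError(f"genetic code table missing codons: {sorted(missing)[:5]}...")
    return GeneticCode(name=path.stem, codon_to_aa=mapping)


@dataclass
class CodonAlignment:
    """Taxa × codon-site matrix of codon states.

    ``states[taxon]`` is a list of length ``sites`` whose entries are
    either a three-letter upper-case DNA codon or ``None`` (missing).
    """

    taxa: list
    sites: int
    states: dict

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names in alignment")
        for taxon in self.taxa:
            row = self.states[taxon]
            if len(row) != self.sites:
                raise ValueError(f"row {taxon!r} has {len(row)} sites, expected {self.sites}")

    def codon(self, taxon: str, site: int) -> Optional[str]:
        """State at a 1-based codon site."""
        return self.states[taxon][site - 1]

    def translate(self, code: GeneticCode) -> dict:
        """Per-taxon protein sequence; missing codons become 'X'."""
        out = {}
        for taxon in self.taxa:
            out[taxon] = "".join(
                "X" if c is None else code.translate(c) for c in self.states[taxon]
            )
        return out

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon in self.taxa:
                seq = "".join(c if c is not None else "NNN" for c in self.states[taxon])
                fh.write(f">{taxon}\n{seq}\n")


def read_codon_alignment(path, code: GeneticCode, strict: bool = True) -> CodonAlignment:
    """Read an in-frame FASTA codon alignment.

    All sequences must have equal length divisible by 3.  Codons with
    any non-ACGT symbol become missing.  A stop codon at an internal
    site is an error in strict mode and masked to missing otherwise; a
    stop at the final site (common for mitochondrial ORFs) is always
    masked.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    (nt_len,) = lengths
    if nt_len % 3 != 0:
        raise ValueError(f"alignment length {nt_len} not divisible by 3")
    sites = nt_len // 3
    taxa, states = [], {}
    for rec in records:
        name = rec.id
        if name in states:
            raise ValueError(f"duplicate taxon {name!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        row = []
        for i in range(sites):
            codon = seq[3 * i : 3 * i + 3]
            if any(n not in NUCLEOTIDES for n in codon):
                row.append(None)
            elif code.is_stop(codon):
                if i == sites - 1:
                    row.append(None)
                elif strict:
                    raise ValueError(
                        f"internal stop codon {codon} at site {i + 1} in {name!r} "
                        f"under code {code.name!r}"
                    )
                else:
                    row.append(None)
            else:
                row.append(codon)
        taxa.append(name)
        states[name] = row
    return CodonAlignment(taxa=taxa, sites=sites, states=states)


@dataclass(frozen=True)
class GroupAssignment:
    """Taxon→group and group→role maps (role: foreground/background/outgroup)."""

    taxon_to_group: dict
    group_to_role: dict

    def __post_init__(self):
        bad = {g: r for g, r in self.group_to_role.items() if r not in ROLES}
        if bad:
            raise ValueError(f"invalid roles {bad}; must be one of {ROLES}")
        unknown = {g for g in self.taxon_to_group.values() if g not in self.group_to_role}
        if unknown:
            raise ValueError(f"groups without a role: {sorted(unknown)}")

    def role(self, taxon: str) -> str:
        return self.group_to_role[self.taxon_to_group[taxon]]

    def taxa_with_role(self, role: str) -> list:
        return sorted(t for t in self.taxon_to_group if self.role(t) == role)


def read_group_table(path) -> GroupAssignment:
    """Read a TSV with columns ``taxon``, ``group``, ``role``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"taxon", "group", "role"}
    if not need <= set(df.columns):
        raise ValueError(f"group table needs columns {sorted(need)}")
    taxon_to_group = dict(zip(df["taxon"], df["group"]))
    group_to_role = {}
    for g, r in zip(df["group"], df["role"]):
        if g in group_to_role and group_to_role[g] != r:
            raise ValueError(f"group {g!r} mapped to conflicting roles")
        group_to_role[g] = r
    return GroupAssignment(taxon_to_group=taxon_to_group, group_to_role=group_to_role)


@dataclass(frozen=True)
class Branch:
    """One edge of a labeled tree, identified by its child node."""

    id: str
    parent_id: str
    length: float
    branch_class: str
    is_leaf: bool


class LabeledTree:
    """A rooted dendropy tree with a class on every branch.

    Every non-root node carries ``node.branch_id`` (the taxon label for
    leaves, ``N<k>`` in postorder for internal nodes) and
    ``node.branch_class`` in ``{foreground, background, excluded}`` on
    the edge above it.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._index_nodes()

    def _index_nodes(self):
        k = 0
        self._by_id = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node.branch_id = node.taxon.label
            elif node.parent_node is None:
                node.branch_id = "root"
            else:
                k += 1
                node.branch_id = f"N{k}"
            self._by_id[node.branch_id] = node

    @classmethod
    def parse(cls, newick: str) -> "LabeledTree":
        tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted",
                                 preserve_underscores=True)
        return cls(tree)

    def node(self, branch_id: str) -> dendropy.Node:
        return self._by_id[branch_id]

    @property
    def leaf_taxa(self) -> list:
        return sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    def branches(self) -> list:
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            out.append(
                Branch(
                    id=node.branch_id,
                    parent_id=node.parent_node.branch_id,
                    length=float(node.edge.length or 0.0),
                    branch_class=getattr(node, "branch_class", "background"),
                    is_leaf=node.is_leaf(),
                )
            )
        return out

    def branches_of_class(self, branch_class: str) -> list:
        return [b for b in self.branches() if b.branch_class == branch_class]

    def n_branches(self, branch_class: str) -> int:
        return len(self.branches_of_class(branch_class))

    def foreground_lineages(self) -> list:
        """Connected components of foreground branches.

        Two foreground branches belong to the same lineage when the
        path between them runs entirely through foreground branches
        (i.e. they share a foreground ancestor branch).  Returns a list
        of frozensets of branch ids, sorted by smallest member.
        """
        lineage_of = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if getattr(node, "branch_class", None) != "foreground":
                continue
            parent = node.parent_node
            if getattr(parent, "branch_class", None) == "foreground":
                lineage_of[node.branch_id] = lineage_of[parent.branch_id]
            else:
                lineage_of[node.branch_id] = node.branch_id
        components = {}
        for bid, root in lineage_of.items():
            components.setdefault(root, set()).add(bid)
        return sorted((frozenset(v) for v in components.values()), key=min)

    def write_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def label_branches(tree, groups: GroupAssignment, mode: str = "clade") -> LabeledTree:
    """Assign a class to every branch of a rooted tree.

    ``terminal`` mode labels only the leaf branches of foreground taxa
    as foreground.  ``clade`` mode additionally labels every branch
    inside (and the stem of) any maximal clade whose leaves are all
    foreground.  Leaf branches of outgroup-role taxa — and, in clade
    mode, all-outgroup clades — are labeled ``excluded``; everything
    else is ``background``.
    """
    if mode not in ("terminal", "clade"):
        raise ValueError(f"mode must be 'terminal' or 'clade', got {mode!r}")
    if isinstance(tree, LabeledTree):
        lt = tree
    elif isinstance(tree, dendropy.Tree):
        lt = LabeledTree(tree)
    else:
        lt = LabeledTree.parse(str(tree))

    leaves = lt.leaf_taxa
    unassigned = [t for t in leaves if t not in groups.taxon_to_group]
    if unassigned:
        raise ValueError(f"taxa not in group table: {unassigned}")

    role_of_leaf = {t: groups.role(t) for t in leaves}
    # bottom-up: does every leaf below this node have the given role?
    for node in lt.tree.postorder_node_iter():
        if node.is_leaf():
            node._roles = {role_of_leaf[node.taxon.label]}
        else:
            node._roles = set().union(*(c._roles for c in node.child_nodes()))

    root = lt.tree.seed_node
    if root._roles == {"foreground"}:
        raise ValueError("all leaves are foreground: no background to contrast against")
    if mode == "clade" and "foreground" not in root._roles:
        pass  # no foreground at all is legal here; contrasts refuse later

    for node in lt.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        pure = node._roles if len(node._roles) == 1 else None
        if node.is_leaf():
            role = role_of_leaf[node.taxon.label]
            node.branch_class = (
                "foreground" if role == "foreground"
                else "excluded" if role == "outgroup"
                else "background"
            )
        elif mode == "clade" and pure == {"foreground"}:
            node.branch_class = "foreground"
        elif pure == {"outgroup"}:
            node.branch_class = "excluded"
        else:
            node.branch_class = "background"

    for node in lt.tree.preorder_node_iter():
        del node._roles
    return lt


@dataclass(frozen=True)
class DomainRegion:
    name: str
    region_class: str  # membrane | transmembrane
    start_aa: int      # 1-based inclusive
    end_aa: int

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1

    def contains(self, site: int) -> bool:
        return self.start_aa <= site <= self.end_aa


@dataclass
class DomainMap:
    """Non-overlapping protein regions (e.g. membrane/transmembrane domains)."""

    regions: list

    def __post_init__(self):
        spans = sorted((r.start_aa, r.end_aa, r.name) for r in self.regions)
        for r in self.regions:
            if not (1 <= r.start_aa <= r.end_aa):
                raise ValueError(f"region {r.name}: bad coordinates {r.start_aa}..{r.end_aa}")
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping regions {n1} and {n2}")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate region names")

    def __len__(self):
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


def read_domain_map(path) -> DomainMap:
    """Read a TSV with columns ``name``, ``class``, ``start``, ``end``."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "class": str})
    need = {"name", "class", "start", "end"}
    if not need <= set(df.columns):
        raise ValueError(f"domain map needs columns {sorted(need)}")
    regions = [
        DomainRegion(
            name=row["name"],
            region_class=row["class"],
            start_aa=int(row["start"]),
            end_aa=int(row["end"]),
        )
        for _, row in df.iterrows()
    ]
    return DomainMap(regions=regions)


def write_domain_map(domains: DomainMap, path) -> None:
    rows = [
        {"name": r.name, "class": r.region_class, "start": r.start_aa, "end": r.end_aa}
        for r in domains
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_group_table(groups: GroupAssignment, path) -> None:
    rows = [
        {"taxon": t, "group": g, "role": groups.group_to_role[g]}
        for t, g in sorted(groups.taxon_to_group.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
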