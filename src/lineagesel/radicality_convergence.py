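"""Physicochemical radicality of replacements and convergence detection.

Amino-acid replacements reachable by a single nucleotide change are
binned, per physicochemical property, into eight equal-width magnitude
categories over [0, max |Δproperty|]; categories 6–8 are "radical".
Nonsynonymous events are then screened with a sliding window (default
20 codons): within each window the count of events in a category is
compared with the expectation under a neutral null (uniform over all
single-step nonsynonymous sense-codon changes) via a binomial z-score,
and events in radical categories inside windows with significantly
positive z (one-tailed p < 0.001 by default) are flagged.

Convergent substitutions are sites where the same derived amino acid
arises on phylogenetically independent foreground lineages (no shared
foreground ancestor branch), is absent from all background terminals,
and recurs in at least ``min_lineages`` lineages (default 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd
from scipy.stats import norm

from lineagesel.genetics_io import GeneticCode, LabeledTree, NUCLEOTIDES

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_CATEGORIES = 8


@dataclass(frozen=True)
class PropertyTable:
    """Physicochemical property values for the 20 amino acids.

    ``values[property][aa]`` is a real number in property-specific
    units.  The shipped default table carries 31 widely used indices
    (hydropathy, polarity, volume, helix/sheet/turn propensities, ...).
    """

    values: dict

    def __post_init__(self):
        for prop, row in self.values.items():
            missing = set(AMINO_ACIDS) - set(row)
            if missing:
                raise ValueError(f"property {prop!r} missing amino acids {sorted(missing)}")

    @property
    def properties(self) -> list:
        return list(self.values)

    def delta(self, prop: str, aa1: str, aa2: str) -> float:
        return abs(self.values[prop][aa1] - self.values[prop][aa2])


def load_property_table(path=None) -> PropertyTable:
    """Load a property TSV (columns: property, A, C, ..., Y).

    Without a path, loads the packaged 31-property default.
    """
    if path is None:
        with resources.files("lineagesel").joinpath("data/aa_properties.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if "property" not in df.columns:
        raise ValueError("property table needs a 'property' column")
    values = {
        row["property"]: {aa: float(row[aa]) for aa in AMINO_ACIDS}
        for _, row in df.iterrows()
    }
    return PropertyTable(values=values)


def single_step_aa_pairs(code: GeneticCode) -> set:
    """Unordered amino-acid pairs reachable by one nucleotide change."""
    pairs = set()
    for codon in code.sense_codons:
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                other = codon[:pos] + nt + codon[pos + 1 :]
                if not code.is_sense(other):
                    continue
                a1, a2 = code.translate(codon), code.translate(other)
                if a1 != a2:
                    pairs.add(frozenset((a1, a2)))
    return pairs


@dataclass(frozen=True)
class CategoryMap:
    """Per property: unordered amino-acid pair → magnitude category 1..8."""

    categories: dict  # prop -> {frozenset(pair) -> int}
    max_delta: dict   # prop -> max |Δ| over single-step pairs

    def category(self, prop: str, aa1: str, aa2: str) -> Optional[int]:
        return self.categories[prop].get(frozenset((aa1, aa2)))


def _bin_category(delta: float, top: float) -> int:
    """Equal-width bin of |Δ| over [0, top]; boundaries go to the higher bin.

    The boundary comparison snaps within 1e-9 relative so the binning is
    invariant to rescaling the property by a constant.
    """
    r = delta * N_CATEGORIES / top
    nearest = round(r)
    if abs(r - nearest) < 1e-9:
        r = nearest
    return max(1, min(N_CATEGORIES, math.floor(r) + 1))


def categorize_changes(props: PropertyTable, code: GeneticCode) -> CategoryMap:
    """Bin |Δproperty| of single-step replacements into 8 equal-width categories.

    Bin edges divide [0, max|Δ|] uniformly; a value exactly on a
    boundary goes to the higher category, and the maximum lands in
    category 8.
    """
    pairs = single_step_aa_pairs(code)
    categories, max_delta = {}, {}
    for prop in props.properties:
        deltas = {pair: props.delta(prop, *tuple(pair)) for pair in pairs}
        top = max(deltas.values())
        if top == 0:
            raise ValueError(f"property {prop!r} is constant over reachable pairs")
        categories[prop] = {
            pair: _bin_category(d, top) for pair, d in deltas.items()
        }
        max_delta[prop] = top
    return CategoryMap(categories=categories, max_delta=max_delta)


def neutral_category_distribution(cat_map: CategoryMap, code: GeneticCode) -> dict:
    """Expected category proportions per property under the neutral null.

    Uniform weight over all ordered single-nucleotide nonsynonymous
    changes between sense codons.  Returns ``{prop: [p_1 .. p_8]}``
    with each vector summing to one.
    """
    changes = []
    for codon in code.sense_codons:
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                other = codon[:pos] + nt + codon[pos + 1 :]
                if code.is_sense(other) and code.translate(codon) != code.translate(other):
                    changes.append(frozenset((code.translate(codon), code.translate(other))))
    out = {}
    for prop, cats in cat_map.categories.items():
        counts = [0] * N_CATEGORIES
        for pair in changes:
            counts[cats[pair] - 1] += 1
        total = sum(counts)
        out[prop] = [c / total for c in counts]
    return out


@dataclass(frozen=True)
class WindowZScore:
    property: str
    category: int
    start: int       # 1-based first codon of the window
    window: int
    observed: int
    expected: float
    z: float
    p: float         # one-tailed (upper)


def window_z_scores(events, cat_map: CategoryMap, code: GeneticCode,
                    protein_length: int, window: int = 20) -> list:
    """Sliding-window binomial z-scores of category counts, per property.

    Windows of ``window`` codons step by one.  N = nonsynonymous
    events in the window; for each category c present, z =
    (n_c − N·p_c) / sqrt(N·p_c·(1−p_c)) with p_c from the neutral
    distribution.  Windows without nonsynonymous events emit nothing.
    """
    if window > protein_length:
        raise ValueError(f"window {window} exceeds protein length {protein_length}")
    null = neutral_category_distribution(cat_map, code)
    ns_events = [e for e in events if e.from_aa != e.to_aa]
    # per-site event lists for fast windowing
    by_site = {}
    for e in ns_events:
        by_site.setdefault(e.site, []).append(e)
    out = []
    for prop in cat_map.categories:
        p_by_cat = null[prop]
        for start in range(1, protein_length - window + 2):
            in_window = [
                e for s in range(start, start + window) for e in by_site.get(s, ())
            ]
            n_total = len(in_window)
            if n_total == 0:
                continue
            counts = [0] * N_CATEGORIES
            for e in in_window:
                cat = cat_map.category(prop, e.from_aa, e.to_aa)
                if cat is not None:
                    counts[cat - 1] += 1
            for cat in range(1, N_CATEGORIES + 1):
                n_c = counts[cat - 1]
                if n_c == 0:
                    continue
                p_c = p_by_cat[cat - 1]
                expected = n_total * p_c
                if p_c <= 0.0 or p_c >= 1.0:
                    continue
                z = (n_c - expected) / math.sqrt(n_total * p_c * (1 - p_c))
                out.append(
                    WindowZScore(
                        property=prop, category=cat, start=start, window=window,
                        observed=n_c, expected=expected, z=z,
                        p=float(norm.sf(z)),
                    )
                )
    return out


def radical_events(events, zscores, category_min: int = 6, alpha: float = 0.001,
                   cat_map: CategoryMap = None) -> list:
    """Nonsynonymous events in radical categories within significant windows.

    An event is radical if for at least one property its replacement
    falls in category ≥ ``category_min`` and it lies inside at least
    one window where that (property, category) has positive z with
    one-tailed p < ``alpha``.
    """
    if cat_map is None:
        raise ValueError("cat_map is required to look up event categories")
    significant = {}
    for ws in zscores:
        if ws.category >= category_min and ws.z > 0 and ws.p < alpha:
            significant.setdefault((ws.property, ws.category), []).append(
                (ws.start, ws.start + ws.window - 1)
            )
    flagged = []
    for e in events:
        if e.from_aa == e.to_aa:
            continue
        hit = False
        for prop in cat_map.categories:
            cat = cat_map.category(prop, e.from_aa, e.to_aa)
            if cat is None or cat < category_min:
                continue
            for lo, hi in significant.get((prop, cat), ()):
                if lo <= e.site <= hi:
                    hit = True
                    break
            if hit:
                break
        if hit:
            flagged.append(e)
    return flagged


@dataclass(frozen=True)
class ConvergentSite:
    """A site where independent foreground lineages share a derived amino acid."""

    site: int
    derived_aa: str
    lineages: tuple   # tuple of frozensets of branch ids
    radical: bool

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)


def find_convergent(events, tree: LabeledTree, aln, code: GeneticCode,
                    min_lineages: int = 3, require_radical: bool = False,
                    radical_set=None) -> list:
    """Detect convergent replacements across independent foreground lineages.

    For each (site, derived amino acid), foreground branches whose
    event produces that amino acid are grouped into lineages (branches
    sharing a foreground ancestor merge); sites with at least
    ``min_lineages`` independent lineages are reported, provided the
    derived amino acid is absent from every background terminal at that
    site.  With ``require_radical`` the replacement must additionally
    be flagged radical (``radical_set`` from :func:`radical_events`)
    on at least one of the lineages.
    """
    lineage_components = tree.foreground_lineages()
    lineage_of_branch = {
        bid: comp for comp in lineage_components for bid in comp
    }
    bg_taxa = [b.id for b in tree.branches() if b.is_leaf and b.branch_class == "background"]
    radical_keys = (
        {(e.branch_id, e.site) for e in radical_set} if radical_set is not None else set()
    )

    hits = {}
    for e in sorted(events, key=lambda e: (e.site, e.branch_id)):
        if e.branch_class != "foreground" or e.from_aa == e.to_aa:
            continue
        comp = lineage_of_branch.get(e.branch_id)
        if comp is None:
            continue
        hits.setdefault((e.site, e.to_aa), {}).setdefault(comp, []).append(e)

    out = []
    for (site, aa), by_lineage in sorted(hits.items()):
        # the derived amino acid must be the terminal state of the lineage,
        # not an intermediate later replaced downstream
        carrying = []
        for comp, evts in by_lineage.items():
            leaf_ids = [
                b.id for b in tree.branches()
                if b.is_leaf and _has_ancestor_in(tree, b.id, comp)
            ]
            codons = [aln.states[t][site - 1] for t in leaf_ids if t in aln.states]
            aas = {code.translate(c) for c in codons if c is not None}
            if aa in aas:
                carrying.append((comp, evts))
        if len(carrying) < min_lineages:
            continue
        bg_states = {
            code.translate(aln.states[t][site - 1])
            for t in bg_taxa
            if aln.states[t][site - 1] is not None
        }
        if aa in bg_states:
            continue
        if require_radical:
            if not any(
                (e.branch_id, e.site) in radical_keys
                for _, evts in carrying for e in evts
            ):
                continue
        out.append(
            ConvergentSite(
                site=site,
                derived_aa=aa,
                lineages=tuple(sorted((c for c, _ in carrying), key=min)),
                radical=any(
                    (e.branch_id, e.site) in radical_keys
                    for _, evts in carrying for e in evts
                ),
            )
        )
    return out


def _has_ancestor_in(tree: LabeledTree, leaf_id: str, comp) -> bool:
    node = tree.node(leaf_id)
    while node is not None:
        if getattr(node, "branch_id", None) in comp:
            return True
        node = node.parent_node
    return False


def write_zscores_tsv(zscores, path) -> None:
    rows = [
        {
            "property": z.property, "category": z.category, "start": z.start,
            "window": z.window, "observed": z.observed, "expected": z.expected,
            "z": z.z, "p": z.p,
        }
        for z in zscores
    ]
    pd.DataFrame(
        rows, columns=["property", "category", "start", "window", "observed",
                       "expected", "z", "p"],
    ).to_csv(path, sep="\t", index=False)


def write_convergence_tsv(sites, path) -> None:
    rows = [
        {
            "site": s.site,
            "derived_aa": s.derived_aa,
            "n_lineages": s.n_lineages,
            "lineages": ";".join(sorted(min(c) for c in s.lineages)),
            "radical": s.radical,
        }
        for s in sites
    ]
    pd.DataFrame(
        rows, columns=["site", "derived_aa", "n_lineages", "lineages", "radical"],
    ).to_csv(path, sep="\t", index=False)
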