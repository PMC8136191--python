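"""Exact-test contrasts of substitution densities and amino-acid usage.

Foreground-vs-background contrasts are 2×2 Fisher exact tests on event
counts against "opportunity" (codon sites × branches of the class),
computed per site or per protein domain, plus per-(site, amino-acid)
usage contrasts across sequence collections.  Families of tests are
corrected by Holm's step-down procedure; the family size may exceed the
number of supplied p-values so that a printed subset known to be the
smallest members of a larger family can be adjusted correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from lineagesel.genetics_io import DomainMap, LabeledTree


@dataclass(frozen=True)
class ContrastResult:
    """A 2×2 foreground/background contrast with raw and Holm-adjusted p.

    Table layout: ``[[a, b], [c, d]]`` with *a* = foreground events,
    *b* = foreground opportunity minus *a*, and *c*, *d* analogous for
    the background.  ``freq_fg``/``freq_bg`` are events per codon-site
    per branch of the class.
    """

    unit: str
    substitution_class: str  # nonsynonymous | synonymous | any
    a: int
    b: int
    c: int
    d: int
    freq_fg: float
    freq_bg: float
    p_raw: float
    p_holm: float = math.nan

    @property
    def table(self):
        return [[self.a, self.b], [self.c, self.d]]


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table of nonnegative integers.

    Sums the hypergeometric probabilities of every table with the same
    margins whose probability does not exceed that of the observed
    table.  All arithmetic is exact (integer numerators over the common
    denominator C(n, column-1 total)), so ties are compared exactly.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError(f"table entries must be nonnegative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    m = a + c  # first-column total
    n = r1 + r2
    if r1 == 0 or r2 == 0 or m == 0 or m == n:
        return 1.0
    # P(k) = C(r1,k) C(r2,m-k) / C(n,m); compare numerators exactly
    lo, hi = max(0, m - r2), min(r1, m)
    obs = math.comb(r1, a) * math.comb(r2, c)
    num = sum(
        w
        for k in range(lo, hi + 1)
        if (w := math.comb(r1, k) * math.comb(r2, m - k)) <= obs
    )
    return min(1.0, num / math.comb(n, m))


def holm_adjust(p_values, family_size: Optional[int] = None) -> list:
    """Holm step-down adjusted p-values, returned in input order.

    ``family_size`` defaults to ``len(p_values)``; it may be larger
    when the supplied p-values are known to be the smallest members of
    a bigger test family (the remaining members then only enter through
    the multipliers, which is exact for the supplied subset).
    """
    p = list(p_values)
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise ValueError(f"family_size {m} < number of p-values {len(p)}")
    for x in p:
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"p-value {x} outside [0, 1]")
    order = sorted(range(len(p)), key=lambda i: p[i])
    adjusted = [0.0] * len(p)
    running = 0.0
    for rank, idx in enumerate(order):  # rank 0 => multiplier m
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted


def _class_counts(events, subclass: str):
    """Per-event contribution to a substitution class (pathway-averaged steps)."""
    if subclass == "nonsynonymous":
        return [(e, e.n_nonsyn) for e in events]
    if subclass == "synonymous":
        return [(e, e.n_syn) for e in events]
    if subclass == "any":
        return [(e, e.n_syn + e.n_nonsyn) for e in events]
    raise ValueError(f"unknown substitution class {subclass!r}")


def _round_count(x: float) -> int:
    # banker's rounding; pathway-averaged steps are integral except for
    # rare multi-nucleotide events
    return int(round(x))


def _contrast(unit, subclass, fg_count, bg_count, fg_opportunity, bg_opportunity):
    a = _round_count(fg_count)
    c = _round_count(bg_count)
    b = max(0, fg_opportunity - a)
    d = max(0, bg_opportunity - c)
    return ContrastResult(
        unit=str(unit),
        substitution_class=subclass,
        a=a, b=b, c=c, d=d,
        freq_fg=fg_count / fg_opportunity if fg_opportunity else math.nan,
        freq_bg=bg_count / bg_opportunity if bg_opportunity else math.nan,
        p_raw=fisher_exact([[a, b], [c, d]]),
    )


def _with_holm(results, family_size):
    adj = holm_adjust([r.p_raw for r in results], family_size=family_size)
    return [replace(r, p_holm=ph) for r, ph in zip(results, adj)]


def _check_classes(tree: LabeledTree):
    n_fg = tree.n_branches("foreground")
    n_bg = tree.n_branches("background")
    if n_fg == 0 or n_bg == 0:
        raise ValueError(
            f"contrast needs both classes populated (foreground={n_fg}, background={n_bg})"
        )
    return n_fg, n_bg


def domain_contrast(events, tree: LabeledTree, domains: DomainMap,
                    subclasses=("nonsynonymous", "synonymous")) -> list:
    """Per-domain foreground/background contrast of substitution density.

    For each domain D and each substitution class, the foreground count
    is the class's event steps in D on foreground branches and the
    opportunity is |D| × (number of foreground branches); analogously
    for the background.  Holm correction runs jointly over all domains
    × all requested classes (34 tests for a 17-region map).
    """
    n_fg, n_bg = _check_classes(tree)
    if isinstance(subclasses, str):
        subclasses = (subclasses,)
    for region in domains:
        if region.length == 0:
            raise ValueError(f"empty domain {region.name}")
    results = []
    for subclass in subclasses:
        weighted = _class_counts(events, subclass)
        for region in domains:
            fg = sum(w for e, w in weighted
                     if e.branch_class == "foreground" and region.contains(e.site))
            bg = sum(w for e, w in weighted
                     if e.branch_class == "background" and region.contains(e.site))
            results.append(
                _contrast(region.name, subclass, fg, bg,
                          region.length * n_fg, region.length * n_bg)
            )
    return _with_holm(results, family_size=len(results))


def site_contrast(events, tree: LabeledTree, subclass: str, n_sites: int) -> list:
    """Per-site foreground/background contrast (domain of size one per site).

    Holm correction runs across all ``n_sites`` positions.
    """
    n_fg, n_bg = _check_classes(tree)
    weighted = _class_counts(events, subclass)
    fg_by_site = [0.0] * n_sites
    bg_by_site = [0.0] * n_sites
    for e, w in weighted:
        if e.site > n_sites:
            raise ValueError(f"event site {e.site} beyond protein length {n_sites}")
        if e.branch_class == "foreground":
            fg_by_site[e.site - 1] += w
        elif e.branch_class == "background":
            bg_by_site[e.site - 1] += w
    results = [
        _contrast(site + 1, subclass, fg_by_site[site], bg_by_site[site], n_fg, n_bg)
        for site in range(n_sites)
    ]
    return _with_holm(results, family_size=n_sites)


def aa_site_patterns(fg_seqs, bg_seqs) -> list:
    """Per-site, per-amino-acid usage contrasts between sequence sets.

    ``fg_seqs``/``bg_seqs`` are collections of equal-length protein
    sequences; sequences (not species) are the sampling unit, so
    several sequences per species are allowed and group sizes may be
    very unequal.  For each site and each amino acid observed there, a
    2×2 table of (sequences carrying the amino acid vs not) × (group)
    is tested; Holm runs across all (site, amino-acid) tests.  'X' and
    '-' are treated as missing and skipped.
    """
    fg = [s.upper() for s in fg_seqs]
    bg = [s.upper() for s in bg_seqs]
    if not fg or not bg:
        raise ValueError("both sequence groups must be non-empty")
    lengths = {len(s) for s in fg} | {len(s) for s in bg}
    if len(lengths) != 1:
        raise ValueError(f"protein sequences have unequal lengths {sorted(lengths)}")
    (n_sites,) = lengths
    results = []
    for site in range(n_sites):
        fg_col = [s[site] for s in fg if s[site] not in "X-"]
        bg_col = [s[site] for s in bg if s[site] not in "X-"]
        n_fg, n_bg = len(fg_col), len(bg_col)
        if n_fg == 0 or n_bg == 0:
            continue
        for aa in sorted(set(fg_col) | set(bg_col)):
            a = fg_col.count(aa)
            c = bg_col.count(aa)
            results.append(
                ContrastResult(
                    unit=f"{site + 1}:{aa}",
                    substitution_class="any",
                    a=a, b=n_fg - a, c=c, d=n_bg - c,
                    freq_fg=a / n_fg,
                    freq_bg=c / n_bg,
                    p_raw=fisher_exact([[a, n_fg - a], [c, n_bg - c]]),
                )
            )
    return _with_holm(results, family_size=len(results))


def significant_sites(pattern_results, alpha: float = 0.05) -> list:
    """1-based sites where any amino-acid usage test survives Holm."""
    sites = set()
    for r in pattern_results:
        if r.p_holm < alpha:
            sites.add(int(r.unit.split(":")[0]))
    return sorted(sites)


def write_contrasts_tsv(results, path, alpha: float = 0.05) -> None:
    import pandas as pd

    rows = [
        {
            "unit": r.unit,
            "class": r.substitution_class,
            "a": r.a, "b": r.b, "c": r.c, "d": r.d,
            "freq_fg": r.freq_fg,
            "freq_bg": r.freq_bg,
            "p_raw": r.p_raw,
            "p_holm": r.p_holm,
            "significant": r.p_holm < alpha,
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["unit", "class", "a", "b", "c", "d", "freq_fg", "freq_bg",
                 "p_raw", "p_holm", "significant"],
    ).to_csv(path, sep="\t", index=False)
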