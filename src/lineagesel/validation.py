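"""End-to-end validation routines with independent oracles.

Self-contained checks that exercise the whole pipeline under the
study-like conditions and against published reference values:

* reproduction of the Holm-adjusted p-values reported for the
  cytochrome-b domain contrasts in subterranean voles, treating the
  eight published raw Fisher p-values as the smallest members of the
  34-test family (17 domains × 2 substitution classes);
* exhaustive comparison of the Fisher exact test against a rational-
  arithmetic enumeration oracle;
* comparison of the pruning log-likelihood against matrix-exponential
  state enumeration on small trees;
* parameter-recovery and LRT power/size simulations at the published
  foreground/background ω effect sizes;
* spiked-convergence detection.

Every routine recomputes its numbers from scratch at call time.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

import lineagesel as ls
from lineagesel.codon_model_ml import CodonModelParams, fit_model, lrt
from lineagesel.synthetic_data import Spike

# Published domain-contrast p-values (cytochrome b, subterranean vs
# surface-dwelling voles): (domain, substitution class, raw Fisher p,
# reported Holm-adjusted p).  The eight tests shown are the smallest of
# the 34-member family.
PUBLISHED_DOMAIN_PVALUES = (
    ("Memb1", "NS", 0.00000033, 0.000011),
    ("Memb2", "NS", 0.00001176, 0.000365),
    ("Memb5", "NS", 0.00033176, 0.008957),
    ("Memb9", "NS", 0.00005434, 0.001522),
    ("TM5",   "NS", 0.00000001, 0.000000),
    ("TM7",   "NS", 0.00004166, 0.001208),
    ("Memb6", "S",  0.00000012, 0.000004),
    ("TM5",   "S",  0.00002733, 0.000820),
)
DOMAIN_FAMILY_SIZE = 34

# Published foreground/background omega estimates for the strongest
# single-species contrast, used as simulation truth for recovery runs.
PUBLISHED_OMEGA_FG = 0.1325
PUBLISHED_OMEGA_BG = 0.0269


def holm_reproduction() -> list:
    """Adjust the published raw p-values within the 34-test family.

    Returns ``[(domain, subclass, raw, reported, computed), ...]``.
    """
    raws = [row[2] for row in PUBLISHED_DOMAIN_PVALUES]
    adjusted = ls.holm_adjust(raws, family_size=DOMAIN_FAMILY_SIZE)
    return [
        (d, s, raw, reported, computed)
        for (d, s, raw, reported), computed in zip(PUBLISHED_DOMAIN_PVALUES, adjusted)
    ]


def _fisher_oracle(a, b, c, d) -> Fraction:
    r1, r2, m = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or m == 0 or m == n:
        return Fraction(1)
    denom = math.comb(n, m)
    obs = Fraction(math.comb(r1, a) * math.comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, m - r2), min(r1, m) + 1):
        p = Fraction(math.comb(r1, k) * math.comb(r2, m - k), denom)
        if p <= obs:
            total += p
    return min(Fraction(1), total)


def fisher_exhaustive_check(max_margin: int = 15):
    """Max |p - oracle| over all 2×2 tables with row margins ≤ max_margin."""
    worst = 0.0
    n_tables = 0
    for r1 in range(max_margin + 1):
        for r2 in range(max_margin + 1):
            for a in range(r1 + 1):
                for c in range(r2 + 1):
                    b, d = r1 - a, r2 - c
                    got = ls.fisher_exact([[a, b], [c, d]])
                    want = float(_fisher_oracle(a, b, c, d))
                    worst = max(worst, abs(got - want))
                    n_tables += 1
    return worst, n_tables


def _enumeration_lnl(tree, aln, params, code) -> float:
    """Brute-force oracle: expm transition matrices + explicit summation
    over every internal-state assignment."""
    from scipy.linalg import expm

    q = ls.build_rate_matrix(params, code)
    idx = {c: i for i, c in enumerate(code.sense_codons)}
    n = len(code.sense_codons)
    nodes = list(tree.tree.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    p_mat = {
        nd.branch_id: expm(q * float(nd.edge.length or 0.0) * params.scale)
        for nd in nodes if nd.parent_node is not None
    }
    pi = params.codon_freqs
    total = 0.0
    for site in range(aln.sites):
        site_l = 0.0
        for combo in itertools.product(range(n), repeat=len(internal)):
            assign = {nd.branch_id: s for nd, s in zip(internal, combo)}
            for nd in nodes:
                if nd.is_leaf():
                    assign[nd.branch_id] = idx[aln.states[nd.taxon.label][site]]
            prob = pi[assign[tree.tree.seed_node.branch_id]]
            for nd in nodes:
                if nd.parent_node is not None:
                    prob *= p_mat[nd.branch_id][
                        assign[nd.parent_node.branch_id], assign[nd.branch_id]
                    ]
            site_l += prob
        total += math.log(site_l)
    return total


def _uniform_params(code, kappa=2.5, omega=0.4):
    n = len(code.sense_codons)
    return CodonModelParams(
        kappa=kappa,
        omega_by_class={"foreground": omega, "background": omega, "excluded": omega},
        codon_freqs=np.full(n, 1.0 / n),
    )


def pruning_oracle_check() -> float:
    """Max |pruning lnL − oracle| over small fixed cases (≤4 leaves, ≤3 sites)."""
    from scipy.linalg import expm

    code = ls.load_genetic_code("vertebrate_mitochondrial")
    groups = ls.GroupAssignment(
        taxon_to_group={t: "g" for t in "ABCD"}, group_to_role={"g": "background"},
    )
    worst = 0.0

    # 2-taxon closed form: sum_i pi_i P_ij(t_a + t_b)
    two = ls.label_branches(
        "(A:0.13,B:0.27);",
        ls.GroupAssignment(taxon_to_group={"A": "g", "B": "g"},
                           group_to_role={"g": "background"}),
        mode="terminal",
    )
    params = _uniform_params(code, kappa=3.0)
    q = ls.build_rate_matrix(params, code)
    idx = {c: i for i, c in enumerate(code.sense_codons)}
    p = expm(q * 0.40)
    for ca, cb in (("ATT", "ATT"), ("ATT", "GTT"), ("CTA", "TTA")):
        aln = ls.CodonAlignment(taxa=["A", "B"], sites=1,
                                states={"A": [ca], "B": [cb]})
        lnl = ls.log_likelihood(aln, two, params, code)
        closed = math.log(params.codon_freqs[idx[ca]] * p[idx[ca], idx[cb]])
        worst = max(worst, abs(lnl - closed))

    # 3 leaves x 3 sites and 4 leaves x 2 sites against state enumeration
    cases = [
        ("((A:0.1,B:0.05):0.08,C:0.2);",
         {"A": ["ATT", "CTA", "GGT"], "B": ["ATT", "CTG", "GGT"],
          "C": ["GTT", "CTA", "GGC"]}),
        ("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.08);",
         {"A": ["ATT", "CTA"], "B": ["GTT", "CTA"],
          "C": ["ATT", "CTG"], "D": ["ATC", "TTA"]}),
    ]
    for newick, rows in cases:
        tree = ls.label_branches(newick, groups, mode="terminal")
        aln = ls.CodonAlignment(
            taxa=list(rows), sites=len(next(iter(rows.values()))),
            states={t: list(v) for t, v in rows.items()},
        )
        params = _uniform_params(code, kappa=2.5)
        lnl = ls.log_likelihood(aln, tree, params, code)
        worst = max(worst, abs(lnl - _enumeration_lnl(tree, aln, params, code)))
    return worst


def _fit_m0_vs_free(aln, tree, code):
    m0 = fit_model(aln, tree, "M0", code)
    warm = {"kappa": m0.params.kappa, "scale": m0.params.scale,
            "omega_fg": m0.omega_fg, "omega_bg": m0.omega_bg}
    free = fit_model(aln, tree, "b_free", code, init=warm)
    return m0, free, lrt(free, m0, df=1)


def omega_recovery(seed: int, n_replicates: int = 20, n_sites: int = 381,
                   alpha: float = 0.05) -> dict:
    """Recovery/power run at the published foreground/background ω.

    Simulates the study-like scenario at ω_fg = 0.1325, ω_bg = 0.0269
    and fits b_free (warm-started from M0); reports median estimates,
    median relative errors, and the fraction of replicates where the
    b_free-vs-M0 LRT rejects at ``alpha``.
    """
    code = ls.load_genetic_code("vertebrate_mitochondrial")
    fg_hats, bg_hats, rejections = [], [], 0
    for rep in range(n_replicates):
        sc = ls.study_like_scenario(
            seed=seed + rep, n_sites=n_sites,
            omega_fg=PUBLISHED_OMEGA_FG, omega_bg=PUBLISHED_OMEGA_BG,
        )
        aln, _ = ls.simulate(sc)
        _, free, test = _fit_m0_vs_free(aln, sc.tree, code)
        fg_hats.append(free.omega_fg)
        bg_hats.append(free.omega_bg)
        rejections += test.p < alpha
    fg_hats, bg_hats = np.array(fg_hats), np.array(bg_hats)
    return {
        "omega_fg_true": PUBLISHED_OMEGA_FG,
        "omega_bg_true": PUBLISHED_OMEGA_BG,
        "omega_fg_median": float(np.median(fg_hats)),
        "omega_bg_median": float(np.median(bg_hats)),
        "omega_fg_median_rel_err": float(
            np.median(np.abs(fg_hats - PUBLISHED_OMEGA_FG) / PUBLISHED_OMEGA_FG)
        ),
        "omega_bg_median_rel_err": float(
            np.median(np.abs(bg_hats - PUBLISHED_OMEGA_BG) / PUBLISHED_OMEGA_BG)
        ),
        "power": rejections / n_replicates,
        "n_replicates": n_replicates,
        "n_sites": n_sites,
    }


def null_calibration(seed: int, n_replicates: int = 200, n_sites: int = 150,
                     alpha: float = 0.05) -> dict:
    """Size of the b_free-vs-M0 LRT under single-ω (M0-truth) simulation."""
    code = ls.load_genetic_code("vertebrate_mitochondrial")
    rejections = 0
    for rep in range(n_replicates):
        sc = ls.study_like_scenario(
            seed=seed + rep, n_sites=n_sites,
            omega_fg=PUBLISHED_OMEGA_BG, omega_bg=PUBLISHED_OMEGA_BG,
        )
        aln, _ = ls.simulate(sc)
        _, _, test = _fit_m0_vs_free(aln, sc.tree, code)
        rejections += test.p < alpha
    half_width = 2.5758293 * math.sqrt(alpha * (1 - alpha) / n_replicates)
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "n_sites": n_sites,
        "band_low": alpha - half_width,
        "band_high": alpha + half_width,
    }


def convergence_detection(seed: int) -> dict:
    """Spiked-convergence detection under the study-like scenario.

    Three independent lineages must be reported; two lineages, or one
    four-leaf clade, must not be at the default minimum of three.
    """
    code = ls.load_genetic_code("vertebrate_mitochondrial")
    base_aln, _ = ls.simulate(ls.study_like_scenario(seed=seed))

    def spikeable_site(aa: str, start: int) -> int:
        # the spike precondition: the derived amino acid must be absent
        # from the site in the base simulation (otherwise the absence
        # criterion is confounded by design)
        for site in range(start, base_aln.sites + 1):
            observed = {
                code.translate(row[site - 1])
                for row in base_aln.states.values() if row[site - 1] is not None
            }
            if aa not in observed:
                return site
        raise RuntimeError(f"no site without {aa} in the base simulation")

    def run(spike):
        sc = ls.study_like_scenario(seed=seed, spikes=(spike,))
        aln, _ = ls.simulate(sc)
        events = ls.map_events(ls.fitch_states(aln, sc.tree), sc.tree, code)
        sites = ls.find_convergent(events, sc.tree, aln, code, min_lineages=3)
        return [s for s in sites if s.site == spike.site and
                s.derived_aa == spike.derived_aa]

    pro_site = spikeable_site("P", 57)
    asn_site = spikeable_site("N", 214)
    three = run(Spike(site=pro_site, derived_aa="P",
                      lineage_branches=("prometheomys", "lasiopodomys", "terricola")))
    two = run(Spike(site=pro_site, derived_aa="P",
                    lineage_branches=("prometheomys", "lasiopodomys")))
    clade = run(Spike(site=asn_site, derived_aa="N", lineage_branches=("ellobius1",)))
    return {
        "three_lineage_hits": len(three),
        "three_lineage_count": three[0].n_lineages if three else 0,
        "two_lineage_hits": len(two),
        "clade_hits": len(clade),
    }
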