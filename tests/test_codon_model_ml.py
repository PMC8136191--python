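"""Rate matrix construction, pruning likelihood and LRTs."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

import lineagesel as ls
from lineagesel.codon_model_ml import CodonModelParams, f3x4_frequencies

from conftest import labeled_tree, make_alignment


def uniform_params(code, omega_fg=0.5, omega_bg=0.1, kappa=2.0):
    n = len(code.sense_codons)
    return CodonModelParams(
        kappa=kappa,
        omega_by_class={"foreground": omega_fg, "background": omega_bg,
                        "excluded": omega_bg},
        codon_freqs=np.full(n, 1.0 / n),
    )


def enumeration_lnl(tree, aln, params, code, branch_class="background"):
    """Independent oracle: per-branch expm + explicit summation over all
    internal-state assignments (no pruning recursion, no eigendecomposition)."""
    q = ls.build_rate_matrix(params, code, branch_class=branch_class)
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
        import itertools
        for combo in itertools.product(range(n), repeat=len(internal)):
            assign = {nd.branch_id: s for nd, s in zip(internal, combo)}
            for nd in nodes:
                if nd.is_leaf():
                    assign[nd.branch_id] = idx[aln.states[nd.taxon.label][site]]
            prob = pi[assign[tree.tree.seed_node.branch_id]]
            for nd in nodes:
                if nd.parent_node is None:
                    continue
                prob *= p_mat[nd.branch_id][
                    assign[nd.parent_node.branch_id], assign[nd.branch_id]
                ]
            site_l += prob
        total += math.log(site_l)
    return total


class TestBuildRateMatrix:
    def test_rows_sum_to_zero(self, mito):
        q = ls.build_rate_matrix(uniform_params(mito), mito)
        assert q.shape == (60, 60)
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_omega_zero_kills_nonsynonymous_rates(self, mito):
        params = uniform_params(mito, omega_bg=0.0)
        q = ls.build_rate_matrix(params, mito, branch_class="background")
        codons = mito.sense_codons
        for i, ci in enumerate(codons):
            for j, cj in enumerate(codons):
                if i != j and mito.translate(ci) != mito.translate(cj):
                    assert q[i, j] == 0.0

    def test_detailed_balance(self, mito):
        rng = np.random.default_rng(7)
        freqs = rng.dirichlet(np.ones(60))
        params = CodonModelParams(
            kappa=3.1, omega_by_class={"foreground": 0.7, "background": 0.2,
                                       "excluded": 0.2},
            codon_freqs=freqs,
        )
        for cls in ("foreground", "background"):
            q = ls.build_rate_matrix(params, mito, branch_class=cls)
            flux = freqs[:, None] * q
            assert np.abs(flux - flux.T).max() < 1e-14

    def test_background_omega_sets_normalisation(self, mito):
        params = uniform_params(mito)
        q = ls.build_rate_matrix(params, mito, branch_class="background")
        rate = -float(params.codon_freqs @ np.diag(q))
        assert rate == pytest.approx(1.0, abs=1e-12)


class TestLogLikelihood:
    def test_zero_branch_lengths_give_log_pi(self, mito):
        tree = labeled_tree("(a:0.0,b:0.0);", mode="terminal")
        aln = make_alignment({"a": ["ATT"], "b": ["ATT"]})
        params = uniform_params(mito)
        lnl = ls.log_likelihood(aln, tree, params, mito)
        assert lnl == pytest.approx(math.log(1 / 60), abs=1e-10)

    def test_two_taxon_matches_matrix_exponential(self, mito):
        tree = labeled_tree("(a:0.13,b:0.27);", mode="terminal")
        params = uniform_params(mito, kappa=3.0)
        q = ls.build_rate_matrix(params, mito)
        idx = {c: i for i, c in enumerate(mito.sense_codons)}
        for ca, cb in (("ATT", "ATT"), ("ATT", "GTT"), ("CTA", "TTA")):
            aln = make_alignment({"a": [ca], "b": [cb]})
            lnl = ls.log_likelihood(aln, tree, params, mito)
            p = expm(q * 0.40)  # reversible: only the path length matters
            expected = math.log(params.codon_freqs[idx[ca]] * p[idx[ca], idx[cb]])
            assert lnl == pytest.approx(expected, abs=1e-8)

    def test_matches_state_enumeration_on_quartet(self, quartet_tree, mito):
        aln = make_alignment(
            {"A": ["ATT", "CTA"], "B": ["GTT", "CTA"],
             "C": ["ATT", "CTG"], "D": ["ATC", "TTA"]}
        )
        params = uniform_params(mito, kappa=2.5)
        lnl = ls.log_likelihood(aln, quartet_tree, params, mito)
        oracle = enumeration_lnl(quartet_tree, aln, params, mito)
        assert lnl == pytest.approx(oracle, abs=1e-8)

    def test_three_taxon_three_sites_enumeration(self, mito):
        tree = labeled_tree("((a:0.1,b:0.05):0.08,c:0.2);", mode="terminal")
        aln = make_alignment(
            {"a": ["ATT", "CTA", "GGT"], "b": ["ATT", "CTG", "GGT"],
             "c": ["GTT", "CTA", "GGC"]}
        )
        params = uniform_params(mito, kappa=4.0)
        lnl = ls.log_likelihood(aln, tree, params, mito)
        assert lnl == pytest.approx(enumeration_lnl(tree, aln, params, mito), abs=1e-8)

    def test_invariant_to_leaf_relabeling(self, mito):
        aln_rows = {"A": ["ATT"], "B": ["GTT"], "C": ["ATC"], "D": ["CTA"]}
        t1 = labeled_tree("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.08);", mode="terminal")
        relabel = {"A": "C", "B": "D", "C": "A", "D": "B"}
        t2 = labeled_tree("((C:0.1,D:0.2):0.05,(A:0.15,B:0.1):0.08);", mode="terminal")
        params = uniform_params(mito)
        lnl1 = ls.log_likelihood(make_alignment(aln_rows), t1, params, mito)
        swapped = {relabel[k]: v for k, v in aln_rows.items()}
        lnl2 = ls.log_likelihood(make_alignment(swapped), t2, params, mito)
        assert lnl1 == pytest.approx(lnl2, abs=1e-10)

    def test_invariant_to_rerooting_under_reversibility(self, mito):
        aln = make_alignment(
            {"a": ["ATT", "CTA"], "b": ["GTT", "CTA"], "c": ["ATC", "CTG"]}
        )
        params = uniform_params(mito)
        t1 = labeled_tree("((a:0.1,b:0.2):0.05,c:0.15);", mode="terminal")
        t2 = labeled_tree("(a:0.05,(b:0.2,c:0.2):0.05);", mode="terminal")
        # same unrooted tree: a-u 0.1, b-u 0.2, u-c 0.2; root moved onto a's branch
        lnl1 = ls.log_likelihood(aln, t1, params, mito)
        lnl2 = ls.log_likelihood(aln, t2, params, mito)
        assert lnl1 == pytest.approx(lnl2, abs=1e-10)

    def test_missing_data_sums_over_states(self, mito):
        tree = labeled_tree("((a:0.1,b:0.2):0.05,c:0.15);", mode="terminal")
        with_missing = make_alignment({"a": ["ATT"], "b": [None], "c": ["GTT"]})
        lnl = ls.log_likelihood(with_missing, tree, uniform_params(mito), mito)
        # marginalising b is equivalent to a 2-taxon tree a..c through the join
        total = 0.0
        q = ls.build_rate_matrix(uniform_params(mito), mito)
        idx = {c: i for i, c in enumerate(mito.sense_codons)}
        p = expm(q * 0.30)
        total = (1 / 60) * p[idx["ATT"], idx["GTT"]]
        assert lnl == pytest.approx(math.log(total), abs=1e-8)

    def test_kappa_profile_peaks_near_truth(self, mito, study_scenario):
        aln, _ = ls.simulate(study_scenario)
        pi = f3x4_frequencies(aln, mito)
        def lnl_at(kappa):
            params = CodonModelParams(
                kappa=kappa, omega_by_class=dict(study_scenario.omega_by_class),
                codon_freqs=pi,
            )
            return ls.log_likelihood(aln, study_scenario.tree, params, mito)
        near = lnl_at(4.0)
        assert near > lnl_at(0.5)
        assert near > lnl_at(40.0)


class TestFitModel:
    def test_m0_nested_in_b_free(self, mito, study_simulation, study_scenario):
        aln, _ = study_simulation
        from lineagesel.codon_model_ml import fit_branch_models
        res = fit_branch_models(aln, study_scenario.tree, mito)
        fits = res["fits"]
        assert fits["b_free"].lnl >= fits["M0"].lnl - 1e-6
        assert fits["b_free"].lnl >= fits["b_neut"].lnl - 1e-6
        assert fits["b_free"].omega_fg > fits["b_free"].omega_bg
        assert fits["b_neut"].omega_fg == 1.0

    def test_uninformative_alignment_hits_boundary(self, mito):
        tree = labeled_tree("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);",
                            foreground={"a"}, mode="terminal")
        aln = make_alignment({t: ["ATT", "CTA", "GGT"] for t in "abcd"})
        fit = ls.fit_model(aln, tree, "M0", mito)
        assert fit.status == "boundary"

    def test_unknown_model_rejected(self, mito, quartet_tree):
        aln = make_alignment({t: ["ATT"] for t in "ABCD"})
        with pytest.raises(ValueError, match="unknown model"):
            ls.fit_model(aln, quartet_tree, "M7", mito)


class TestLrt:
    def test_chi2_quantiles(self):
        from lineagesel.codon_model_ml import LRTResult

        fit = lambda lnl: type("F", (), {"lnl": lnl})()
        r = ls.lrt(fit(-100.0), fit(-100.0 - 3.841459 / 2), df=1)
        assert r.p == pytest.approx(0.05, abs=1e-6)
        r2 = ls.lrt(fit(-100.0), fit(-100.0 - 10.83 / 2), df=1)
        assert r2.p == pytest.approx(0.001, abs=5e-5)

    def test_identical_fits_give_p_one(self):
        fit = lambda lnl: type("F", (), {"lnl": lnl})()
        r = ls.lrt(fit(-50.0), fit(-50.0), df=1)
        assert r.statistic == 0.0 and r.p == 1.0

    def test_statistic_clamped_at_zero(self):
        fit = lambda lnl: type("F", (), {"lnl": lnl})()
        r = ls.lrt(fit(-51.0), fit(-50.0), df=1)
        assert r.statistic == 0.0

    def test_nonpositive_df_rejected(self):
        fit = lambda lnl: type("F", (), {"lnl": lnl})()
        with pytest.raises(ValueError):
            ls.lrt(fit(-1.0), fit(-2.0), df=0)
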