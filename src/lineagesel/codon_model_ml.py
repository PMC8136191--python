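"""Branch-model codon substitution ML and likelihood-ratio tests.

A GY94-style reversible codon model over the sense codons: substitution
rate ``q_ij = π_j · κ^[transition] · ω^[nonsynonymous]`` for codons
differing at a single position (zero otherwise), with a branch-class-
specific ω (foreground vs background) and F3x4 equilibrium frequencies
estimated from the alignment.  The generator is normalised so that one
unit of branch length is one expected substitution per codon under the
background-class ω.  Likelihoods are computed by Felsenstein pruning
with per-site rescaling; transition matrices come from the eigensystem
of the symmetrised generator.

Three model shapes mirror the standard branch-model comparisons:

* ``M0`` — one ω shared by all branches;
* ``b_free`` — separate foreground and background ω, both free;
* ``b_neut`` — foreground ω fixed at 1, background ω free.

``lrt`` compares nested fits with a χ² upper tail on 2ΔlnL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from lineagesel.genetics_io import CodonAlignment, GeneticCode, LabeledTree

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_MODEL_NAMES = ("M0", "b_free", "b_neut")
_structure_cache = {}


def _code_structure(code: GeneticCode):
    """Single-difference / transition / nonsynonymous masks over sense codons."""
    if code.name in _structure_cache:
        return _structure_cache[code.name]
    codons = code.sense_codons
    n = len(codons)
    single = np.zeros((n, n), dtype=bool)
    is_ts = np.zeros((n, n), dtype=bool)
    is_ns = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            single[i, j] = True
            p = diff[0]
            is_ts[i, j] = frozenset((ci[p], cj[p])) in _TRANSITIONS
            is_ns[i, j] = code.translate(ci) != code.translate(cj)
    _structure_cache[code.name] = (codons, single, is_ts, is_ns)
    return _structure_cache[code.name]


@dataclass
class CodonModelParams:
    """GY94 branch-model parameter set.

    ``codon_freqs`` is over ``code.sense_codons`` order and sums to 1;
    ``omega_by_class`` maps branch classes to ω; ``scale`` multiplies
    all input branch lengths.
    """

    kappa: float
    omega_by_class: dict
    codon_freqs: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        freqs = np.asarray(self.codon_freqs, dtype=float)
        if np.any(freqs <= 0):
            raise ValueError("codon frequencies must be strictly positive (smooth first)")
        if not math.isclose(float(freqs.sum()), 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError("codon frequencies must sum to 1")
        self.codon_freqs = freqs / freqs.sum()
        for cls, w in self.omega_by_class.items():
            if not (math.isfinite(w) and w >= 0):
                raise ValueError(f"omega for class {cls!r} must be finite and >= 0")


def f3x4_frequencies(aln: CodonAlignment, code: GeneticCode,
                     pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 codon frequencies over sense codons, pseudocount-smoothed."""
    from lineagesel.genetics_io import NUCLEOTIDES

    counts = np.full((3, 4), pseudocount)
    idx = {n: k for k, n in enumerate(NUCLEOTIDES)}
    for row in aln.states.values():
        for codon in row:
            if codon is None:
                continue
            for pos in range(3):
                counts[pos, idx[codon[pos]]] += 1
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pis = np.array(
        [pos_freq[0, idx[c[0]]] * pos_freq[1, idx[c[1]]] * pos_freq[2, idx[c[2]]]
         for c in code.sense_codons]
    )
    return pis / pis.sum()


def _unscaled_q(kappa: float, omega: float, pi: np.ndarray, structure) -> np.ndarray:
    _, single, is_ts, is_ns = structure
    rate = np.where(single, np.where(is_ts, kappa, 1.0), 0.0)
    rate = rate * np.where(is_ns, omega, 1.0) * pi[None, :]
    np.fill_diagonal(rate, 0.0)
    np.fill_diagonal(rate, -rate.sum(axis=1))
    return rate


def build_rate_matrix(params: CodonModelParams, code: GeneticCode,
                      branch_class: str = "background") -> np.ndarray:
    """Scaled generator Q for one branch class.

    All classes share the normalisation constant computed from the
    background-class ω, so branch lengths keep a single interpretation
    (expected substitutions per codon on a background branch) while
    foreground branches run proportionally faster or slower.
    """
    structure = _code_structure(code)
    pi = np.asarray(params.codon_freqs, dtype=float)
    q_bkg = _unscaled_q(params.kappa, params.omega_by_class["background"], pi, structure)
    norm = -float(pi @ np.diag(q_bkg))
    if norm <= 0:
        raise ValueError("degenerate codon frequencies: zero total rate")
    omega = params.omega_by_class[branch_class]
    q = _unscaled_q(params.kappa, omega, pi, structure)
    return q / norm


class PruningEngine:
    """Cached Felsenstein pruning over a labeled tree and codon alignment.

    Built once per (alignment, tree, code, π) and evaluated many times
    during optimisation.  Leaf messages are column gathers (one-hot
    tips); missing codons contribute a flat message (sum over states).
    """

    def __init__(self, aln: CodonAlignment, tree: LabeledTree, code: GeneticCode,
                 pi: np.ndarray):
        if sorted(aln.taxa) != tree.leaf_taxa:
            raise ValueError("alignment taxa do not match tree leaves")
        self.code = code
        self.structure = _code_structure(code)
        self.pi = np.asarray(pi, dtype=float)
        self.n_states = len(code.sense_codons)
        self.n_sites = aln.sites
        codon_index = {c: i for i, c in enumerate(code.sense_codons)}

        self.postorder = []   # (node_id, [(child_id, child_is_leaf, class, length)])
        self.leaf_states = {}  # leaf_id -> int array, -1 = missing
        self.classes = set()
        for node in tree.tree.postorder_node_iter():
            if node.is_leaf():
                row = aln.states[node.taxon.label]
                self.leaf_states[node.branch_id] = np.array(
                    [codon_index[c] if c is not None else -1 for c in row], dtype=int
                )
            else:
                children = []
                for child in node.child_nodes():
                    children.append(
                        (child.branch_id, child.is_leaf(),
                         getattr(child, "branch_class", "background"),
                         float(child.edge.length or 0.0))
                    )
                    self.classes.add(getattr(child, "branch_class", "background"))
                self.postorder.append((node.branch_id, children))
        self.root_id = self.postorder[-1][0]

    def _eigensystem(self, kappa: float, omega: float):
        q = _unscaled_q(kappa, omega, self.pi, self.structure)
        d = np.sqrt(self.pi)
        sym = q * d[:, None] / d[None, :]
        w, u = np.linalg.eigh(sym)
        return w, u, d

    def log_likelihood(self, kappa: float, scale: float, omega_by_class: dict) -> float:
        norm_q = _unscaled_q(kappa, omega_by_class["background"], self.pi, self.structure)
        norm = -float(self.pi @ np.diag(norm_q))
        eig = {}
        for cls in self.classes:
            omega = omega_by_class.get(cls, omega_by_class["background"])
            key = round(omega, 15)
            if key not in eig:
                eig[key] = self._eigensystem(kappa, omega)
        omega_key = {
            cls: round(omega_by_class.get(cls, omega_by_class["background"]), 15)
            for cls in self.classes
        }

        partials = {}
        log_scaler = np.zeros(self.n_sites)
        for node_id, children in self.postorder:
            acc = np.ones((self.n_states, self.n_sites))
            for child_id, child_is_leaf, cls, length in children:
                w, u, d = eig[omega_key[cls]]
                t = length * scale / norm
                expwt = np.exp(w * t)
                p = (u * expwt[None, :]) @ u.T
                p = (p / d[:, None]) * d[None, :]
                np.clip(p, 0.0, None, out=p)
                if child_is_leaf:
                    states = self.leaf_states[child_id]
                    msg = np.ones((self.n_states, self.n_sites))
                    present = states >= 0
                    msg[:, present] = p[:, states[present]]
                else:
                    msg = p @ partials.pop(child_id)
                acc *= msg
            top = acc.max(axis=0)
            top[top == 0.0] = 1.0
            acc /= top[None, :]
            log_scaler += np.log(top)
            partials[node_id] = acc
        site_l = self.pi @ partials[self.root_id]
        if np.any(site_l <= 0):
            return -np.inf
        return float(np.sum(np.log(site_l) + log_scaler))


def log_likelihood(aln: CodonAlignment, tree: LabeledTree,
                   params: CodonModelParams, code: GeneticCode) -> float:
    """Pruning log-likelihood of the alignment under the branch model."""
    engine = PruningEngine(aln, tree, code, params.codon_freqs)
    lnl = engine.log_likelihood(params.kappa, params.scale, params.omega_by_class)
    if not math.isfinite(lnl):
        raise ValueError("non-finite log-likelihood")
    return lnl


@dataclass
class ModelFit:
    """Maximum-likelihood fit of one model shape."""

    model: str
    params: CodonModelParams
    lnl: float
    status: str            # "ok" | "not_converged" | "boundary"
    n_free_params: int

    @property
    def omega_fg(self) -> float:
        return self.params.omega_by_class["foreground"]

    @property
    def omega_bg(self) -> float:
        return self.params.omega_by_class["background"]


_OMEGA_STARTS = (0.2, 1.5)
_LOG_BOUNDS = (-9.0, 4.0)


def fit_model(aln: CodonAlignment, tree: LabeledTree, model: str,
              code: GeneticCode, init: Optional[dict] = None,
              tol: float = 1e-6) -> ModelFit:
    """Fit M0 / b_free / b_neut by bounded quasi-Newton on log parameters.

    κ, a global branch-length scale and the free ω values are
    optimised; π is fixed at F3x4 estimates.  Two deterministic starts
    (ω = 0.2 and 1.5) are run and the best kept; ``init`` adds one
    extra start (e.g. a warm start from a nested fit).  ``tol`` is the
    absolute convergence tolerance on lnL.
    """
    if model not in _MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; expected one of {_MODEL_NAMES}")
    pi = f3x4_frequencies(aln, code)
    engine = PruningEngine(aln, tree, code, pi)

    def omega_map(omegas):
        if model == "M0":
            w = omegas[0]
            return {"foreground": w, "background": w, "excluded": w}
        if model == "b_free":
            return {"foreground": omegas[0], "background": omegas[1],
                    "excluded": omegas[1]}
        return {"foreground": 1.0, "background": omegas[0], "excluded": omegas[0]}

    n_omega = 2 if model == "b_free" else 1

    def objective(x):
        kappa, scale = math.exp(x[0]), math.exp(x[1])
        omegas = [math.exp(v) for v in x[2:]]
        lnl = engine.log_likelihood(kappa, scale, omega_map(omegas))
        return -lnl if math.isfinite(lnl) else 1e12

    starts = []
    for w0 in _OMEGA_STARTS:
        starts.append([math.log(2.0), 0.0] + [math.log(w0)] * n_omega)
    if init is not None:
        x0 = [math.log(init.get("kappa", 2.0)), math.log(init.get("scale", 1.0))]
        if model == "b_free":
            x0 += [math.log(max(init.get("omega_fg", 0.2), 1e-8)),
                   math.log(max(init.get("omega_bg", 0.2), 1e-8))]
        else:
            x0 += [math.log(max(init.get("omega_bg", init.get("omega", 0.2)), 1e-8))]
        starts.append(x0)

    best = None
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B",
            bounds=[_LOG_BOUNDS] * len(x0),
            options={"ftol": tol * 1e-3, "gtol": 1e-7, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res

    kappa, scale = math.exp(best.x[0]), math.exp(best.x[1])
    omegas = [math.exp(v) for v in best.x[2:]]
    params = CodonModelParams(
        kappa=kappa, omega_by_class=omega_map(omegas), codon_freqs=pi, scale=scale,
    )
    status = "ok" if best.success else "not_converged"
    lo, hi = _LOG_BOUNDS
    if any(abs(v - lo) < 1e-6 or abs(v - hi) < 1e-6 for v in best.x):
        status = "boundary"
    n_free = 2 + n_omega
    return ModelFit(model=model, params=params, lnl=-float(best.fun),
                    status=status, n_free_params=n_free)


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float


def lrt(fit_alt: ModelFit, fit_null: ModelFit, df: int) -> LRTResult:
    """χ² likelihood-ratio test of nested fits (statistic clamped at 0)."""
    if df <= 0:
        raise ValueError("df must be positive")
    stat = max(0.0, 2.0 * (fit_alt.lnl - fit_null.lnl))
    return LRTResult(statistic=stat, df=df, p=float(chi2.sf(stat, df)))


def fit_branch_models(aln: CodonAlignment, tree: LabeledTree, code: GeneticCode,
                      tol: float = 1e-6) -> dict:
    """Fit M0, b_free and b_neut with warm starts and run both LRTs.

    b_free is warm-started from the M0 optimum (in addition to the two
    fixed starts), which also guarantees lnL(b_free) ≥ lnL(M0).
    Returns ``{"fits": {name: ModelFit}, "lrt_free_vs_m0": LRTResult,
    "lrt_free_vs_neut": LRTResult}``.
    """
    m0 = fit_model(aln, tree, "M0", code, tol=tol)
    warm = {"kappa": m0.params.kappa, "scale": m0.params.scale,
            "omega_fg": m0.omega_fg, "omega_bg": m0.omega_bg}
    free = fit_model(aln, tree, "b_free", code, init=warm, tol=tol)
    neut = fit_model(aln, tree, "b_neut", code, init=warm, tol=tol)
    return {
        "fits": {"M0": m0, "b_free": free, "b_neut": neut},
        "lrt_free_vs_m0": lrt(free, m0, df=1),
        "lrt_free_vs_neut": lrt(free, neut, df=1),
    }


def write_fits_tsv(results: dict, path) -> None:
    import pandas as pd

    rows = []
    for name, fit in results["fits"].items():
        rows.append({
            "model": name,
            "lnL": fit.lnl,
            "kappa": fit.params.kappa,
            "omega_fg": fit.omega_fg,
            "omega_bg": fit.omega_bg,
            "scale": fit.params.scale,
            "status": fit.status,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_lrt_tsv(results: dict, path) -> None:
    import pandas as pd

    rows = [
        {"comparison": "b_free_vs_M0",
         "statistic": results["lrt_free_vs_m0"].statistic,
         "df": results["lrt_free_vs_m0"].df,
         "p": results["lrt_free_vs_m0"].p},
        {"comparison": "b_free_vs_b_neut",
         "statistic": results["lrt_free_vs_neut"].statistic,
         "df": results["lrt_free_vs_neut"].df,
         "p": results["lrt_free_vs_neut"].p},
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
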