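# lineagesel

Detecting lineage-specific selection signatures in protein-coding genes.

`lineagesel` is built for a common comparative-genomics design: a set of
species that independently evolved the same lifestyle (the motivating
case is subterranean voles and their mitochondrial cytochrome *b*) is
contrasted against their surface-dwelling relatives on a shared
phylogeny.  Given an in-frame codon alignment, a rooted tree with
branch lengths, and a table assigning each taxon to a *foreground*
(focal) or *background* group, the package:

1. **maps substitutions onto branches** — Fitch parsimony over codon
   states with deterministic tie-breaking, and pathway-averaged
   synonymous/nonsynonymous decomposition of each codon change;
2. **contrasts substitution densities** between foreground and
   background branches, per site and per protein domain (e.g.
   membrane/transmembrane regions), with two-sided Fisher exact tests
   and Holm step-down correction, plus per-site amino-acid usage
   contrasts across large sequence collections;
3. **scores physicochemical radicality** of replacements: |Δproperty|
   of each single-step replacement is binned into 8 equal-width
   categories per property (31 shipped amino-acid indices, fully
   configurable); sliding-window (20 codons) binomial z-scores against
   a neutral category distribution flag radical bursts (categories
   6–8, one-tailed p < 0.001);
4. **detects convergent substitutions** — sites where the same derived
   amino acid arises on ≥ 3 phylogenetically independent foreground
   lineages and is absent from the background;
5. **fits branch-model dN/dS** — a GY94-style codon model with F3x4
   frequencies and class-specific ω, in three shapes: `M0` (one ω),
   `b_free` (ω_fg and ω_bg free) and `b_neut` (ω_fg = 1), compared by
   χ²(1) likelihood-ratio tests.

A first-class simulator (`lineagesel.synthetic_data`) evolves codons
along labeled trees by exact Gillespie simulation under the same model
family, emits the true substitution history, and can spike convergent
replacements — so every stage of the pipeline is testable without any
sequence downloads.

## The model in brief

For sense codons *i* → *j* differing at one position the substitution
rate is

    q_ij = π_j · κ^[transition] · ω_c^[nonsynonymous]

where π is F3x4, κ the transition/transversion ratio, and ω_c the
dN/dS ratio of the branch's class c ∈ {foreground, background}.  Q is
normalised so a branch length of 1 is one expected substitution per
codon under the background ω.  Likelihoods use Felsenstein pruning
with per-site rescaling; ω < 1 indicates purifying selection, ω = 1
neutrality.  The `b_free` vs `M0` LRT asks whether the foreground
evolves at a different ω than the rest of the tree; `b_free` vs
`b_neut` asks whether ω_fg differs from 1.

## Worked example

Simulate the study-like design (30 taxa, five independent foreground
lineages, 381 codons, mitochondrial code), spike a convergent
Ser→Pro-style replacement into three lineages, and run the pipeline:

```python
import lineagesel as ls
from lineagesel.codon_model_ml import fit_branch_models
from lineagesel.synthetic_data import Spike

code = ls.load_genetic_code("vertebrate_mitochondrial")
spike = Spike(site=57, derived_aa="P",
              lineage_branches=("prometheomys", "lasiopodomys", "terricola"))
scenario = ls.study_like_scenario(seed=7, spikes=(spike,))
aln, history = ls.simulate(scenario)

states = ls.fitch_states(aln, scenario.tree)
events = ls.map_events(states, scenario.tree, code)
print(f"mapped events: {len(events)}")

for h in ls.find_convergent(events, scenario.tree, aln, code, min_lineages=3):
    print(f"convergent site {h.site}: derived {h.derived_aa} "
          f"in {h.n_lineages} independent lineages")

res = fit_branch_models(aln, scenario.tree, code)
free = res["fits"]["b_free"]
print(f"b_free: omega_fg={free.omega_fg:.4f} omega_bg={free.omega_bg:.4f}")
print(f"LRT b_free vs M0: p={res['lrt_free_vs_m0'].p:.2e}")
```

Output:

```
mapped events: 1560
convergent site 57: derived P in 3 independent lineages
b_free: omega_fg=0.0829 omega_bg=0.0348
LRT b_free vs M0: p=1.13e-07
```

The convergent spike is recovered exactly; the fitted class ω values
recover the generating values (ω_fg = 0.08, ω_bg = 0.03), and the LRT
detects the foreground/background rate difference.

A CLI wraps the same stages:

```bash
lineagesel all --config config.yaml --out results/ --seed 7
# stages: simulate | map | contrast | radicality | convergence | dnds | all
```

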