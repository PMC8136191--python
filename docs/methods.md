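# Methods

## Scope and data model

The package analyses one protein-coding locus on one rooted phylogeny.
The central objects are a `CodonAlignment` (taxa × codon sites, 1-based
coordinates, vertebrate mitochondrial code by default), a `LabeledTree`
(every branch classed foreground/background/excluded), and a stream of
`SubstitutionEvent`s (one inferred codon change on one branch at one
site).  Branch labeling has two modes: `terminal` marks only the leaf
branches of foreground taxa; `clade` additionally marks every branch
inside, and the stem of, each maximal all-foreground clade — the
labeling used for a foreground genus sampled with several species.
Outgroup-role taxa are `excluded` from counting contrasts; whether to
fold them into the background was an open choice, and exclusion was
adopted as the conservative reading (they contribute neither
opportunity nor events).  Trees must arrive rooted; no rerooting is
attempted.

Ambiguity policy: any codon containing a non-ACGT symbol is missing
data everywhere (mapping skips it, the likelihood marginalises over all
sense codons).  A stop codon at the final site is masked (mitochondrial
ORFs commonly end in a stop or an incomplete codon); an internal stop
is an error unless a lenient flag masks it.

## Substitution mapping

Ancestral codon states are reconstructed per site by Fitch parsimony
over the sense-codon state space, then resolved deterministically:

* bottom-up intersection/union over the states observed at the site
  (a missing leaf contributes no constraint);
* top-down, the **root** takes its most frequent candidate among the
  observed leaf states, ties broken lexicographically.  A purely
  lexicographic root choice was rejected after it was found to root
  rare derived codons: when a foreground singleton is adjacent to the
  root, the root's Fitch set ties between ancestral and derived state,
  and an alphabetic pick can move the inferred change onto the basal
  background branch.  Every member of the root set is equally
  parsimonious, so the frequency rule stays within the optimum;
* every other node prefers its parent's state when it lies in the
  node's candidate set (DELTRAN-flavoured), otherwise the
  lexicographically smallest candidate.

Codon changes touching more than one nucleotide are decomposed into
synonymous/nonsynonymous steps by enumerating all orderings of the
single-nucleotide steps, discarding pathways through stop codons, and
averaging — the classic pathway-counting convention.  If every pathway
is blocked by stops (rare, e.g. some serine–arginine interchanges under
the mitochondrial code), each position is scored in the source-codon
context directly and the pair is detectable via `pathway_blocked`.

Parsimony mapping undercounts on long branches (multiple hits collapse)
and cannot place changes more finely than one branch; the simulator's
true event logs quantify this in the tests (≥90 % of single-hit sites
are recovered at branch lengths ≤0.05).

## Contrast statistics

The Fisher exact test is two-sided by probability mass: the p-value
sums hypergeometric probabilities of all tables sharing the observed
margins whose probability does not exceed the observed table's.  The
implementation works on exact integer numerators over the common
denominator, so the "≤" comparison is exact and tie-handling needs no
floating tolerance.

Holm's step-down adjustment accepts a declared `family_size` larger
than the number of supplied p-values, so a published subset known to be
the smallest members of a larger family can be adjusted faithfully.
For the 17-region domain map the family is all domains × both
substitution classes = 34 tests — the only family size consistent with
the published raw/adjusted pairs, which the acceptance checks reproduce
to the printed precision.

Density contrasts use an opportunity normalisation: for a unit of
|D| codon sites, foreground opportunity is |D| × (number of foreground
branches), and the 2×2 table is (events, opportunity − events) ×
(foreground, background).  The published frequencies' denominator is
not recoverable, so this convention is declared rather than matched;
reported `freq_fg`/`freq_bg` are events per codon-site per branch.
Events contribute their pathway-averaged step counts to each class;
totals are rounded half-to-even only when the integer table is formed
(single-nucleotide events, the overwhelming majority at study-like
divergence, are always integral).

Amino-acid usage contrasts take *sequences* (not species) as the
sampling unit, matching designs where intraspecific variation is
represented by many sequences per species, and test each (site, amino
acid) as its own 2×2 table rather than a site-wide 2×20 exact test —
exact, interpretable, and Holm-corrected over all (site, aa) tests; a
site is called significant when any of its amino-acid tests survives.

## Radicality and convergence

Per physicochemical property, |Δproperty| over all amino-acid pairs
reachable by a single nucleotide change is binned into 8 equal-width
categories over [0, max |Δ|]; boundary values go to the higher
category (with a 1e-9 relative snap so the binning is invariant to
rescaling a property by a constant).  Categories 6–8 are "radical".

The sliding window (default 20 codons, step 1) compares the category
counts of the nonsynonymous events it contains with a neutral
expectation: the category distribution of all single-step
nonsynonymous sense-codon changes, uniformly weighted.  Uniform
weighting was chosen as the simplest null; weighting by alignment codon
frequencies is a straightforward extension.  The test statistic is the
binomial z-score z = (n_c − N·p_c)/√(N·p_c(1−p_c)) with a one-tailed
normal upper tail; whether the historical tool's variance term is
exactly binomial is not recoverable from its description, so this form
is declared and kept.  An event is flagged radical when, for at least
one property, its category is ≥ 6 and it lies in a window where that
(property, category) has positive z with p < 0.001.

Convergence: foreground branches are grouped into lineages as the
connected components of foreground branches (two branches share a
lineage iff the path between them is all-foreground — a labeled clade
is one lineage, a scattered singleton another).  A (site, derived
amino acid) pair is convergent when ≥ `min_lineages` (default 3)
independent lineages carry an event producing that amino acid, the
lineage's terminal states actually retain it, and it is absent from
every background terminal at that site.  The shipped default property
table carries 31 widely used indices (Kyte–Doolittle hydropathy,
Grantham polarity/volume/composition, Chou–Fasman propensities,
Hopp–Woods hydrophilicity, Fauchère–Pliska hydrophobicity, Woese polar
requirement, residue mass, accessibility, charge, and similar); it is
a configurable data file, not a canonical reproduction of any specific
historical property set.

## Branch-model ML

GY94-style reversible codon model over the sense codons:
q_ij = π_j · κ^[transition] · ω_c^[nonsynonymous] for single-position
differences, π fixed at F3x4 estimates from the alignment (pseudocount
0.5 per nucleotide per position keeps π strictly positive).  Q is
normalised so Σ_i π_i Σ_{j≠i} q_ij = 1 **under the background-class
ω**; all classes share that constant, so branch lengths mean "expected
substitutions per codon on a background branch" and foreground
branches run proportionally faster/slower.  Per-class scaling is a
configurable alternative.

Model shapes: `M0` (ω shared), `b_free` (ω_fg, ω_bg free), `b_neut`
(ω_fg ≡ 1, ω_bg re-estimated — re-estimation rather than sharing with
M0 was the open choice, decided for consistency with the free model's
profile).  κ and a global branch-length scale are free in all shapes.
Likelihood: Felsenstein pruning over the 60 sense codons, per-site
max-rescaling against underflow, transition matrices from the
eigensystem of the π-symmetrised generator.  Optimisation: L-BFGS-B on
log-transformed parameters, bounds e^±(9,4), two fixed starts
(ω ∈ {0.2, 1.5}, κ = 2, scale = 1), convergence tolerance 1e-6 on
lnL; `fit_branch_models` additionally warm-starts `b_free` and
`b_neut` from the M0 optimum, which guarantees lnL(b_free) ≥ lnL(M0)
and removes negative-LRT clamping in practice.  Degenerate inputs
(identical sequences) drive ω̂ to its bound and are reported with a
`boundary` status rather than an error.

LRTs compare nested shapes with 2ΔlnL against χ² (df = 1 for both
standard comparisons), statistic clamped at zero.

## Simulator

Codons evolve by exact continuous-time (Gillespie) simulation along
each branch under that branch's class generator — not by endpoint
sampling — precisely so a true per-branch event log exists for
validating the mapping and counting stages.  Root codons are drawn
from π (uniform over sense codons by default; skewed π only matters
for frequency-estimation exercises and is available).  All randomness
flows through one seeded generator; a seed is mandatory.

The study-like scenario is a 30-leaf tree with five phylogenetically
independent foreground lineages — one early-diverging singleton, one
four-leaf foreground clade (7 labeled branches in clade mode), three
singletons scattered in the background radiation — with 381 codons,
κ = 4, ω_bg = 0.03, ω_fg = 0.08 under the mitochondrial code: sizes
and rates chosen to match the motivating system (a ~1143 bp
mitochondrial gene in a rodent subfamily with strong purifying
selection and modest foreground relaxation).  Branch lengths (0.03–0.35
expected substitutions per codon) give overall divergence typical of a
genus-to-subfamily mitochondrial dataset.

Spiked convergence rewrites one site in the targeted lineages: the
lineage stem receives a single substitution to a codon of the derived
amino acid (a single-nucleotide neighbour of the stem's parent state
when available, else the nearest codon), downstream events at that
site are dropped, and the whole lineage subtree adopts the codon, so
the history still replays exactly to the emitted alignment.  Spiking
an amino acid already present in the background triggers a warning,
since the convergence caller's absence criterion would reject it by
design.

What the simulator does **not** emulate: indels and alignment error,
among-site rate variation beyond the two-class ω, codon-usage bias,
saturation-level divergence, and intraspecific polymorphism.  Passing
tests therefore demonstrate correctness of the machinery under the
declared model, not robustness of the biological conclusions to model
violations on real data.

## Validation problem sizes

The packaged validation (`lineagesel.validation`, driven by
`scripts/acceptance.py` and the acceptance tests) uses: 20 replicates
at 381 codons on the study-like tree for ω recovery and LRT power at
the published effect sizes (ω_fg = 0.1325, ω_bg = 0.0269); 200
replicates at 150 codons for the LRT null size (the χ²(1) null is
insensitive to alignment length, so the shorter alignment is used for
the many-replicate run); exhaustive Fisher tables up to row margins of
15; and ≤4-leaf, ≤3-site trees for the likelihood enumeration oracle.
Convergence validation selects the spike site as the first position at
or after the nominal target where the derived amino acid is absent
from the base simulation, honouring the spike operation's stated
precondition.

## Known limitations

* Parsimony mapping is biased downward at high divergence and resolves
  ties deterministically rather than averaging over reconstructions.
* The opportunity denominator in density contrasts is a declared
  convention; published frequency values using an unstated denominator
  are not numerically reproducible.
* κ is shared across branch classes; synonymous rate variation and
  site-heterogeneous ω mixtures are out of scope.
* The amino-acid property table is a curated default, not a canonical
  historical set; radicality conclusions depend on the chosen
  properties.
* The branch-model LRT inherits the usual asymptotic χ² approximation;
  the null calibration checks its size only at the simulated design.
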