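# Methods

This note documents the models, numerical choices and study designs behind
`carotevol`, and what the synthetic-data experiments do and do not show.

## Pairwise selection screen

### Counting method

Sites and differences follow the Nei–Gojobori (1986) counting scheme with
one explicit convention for stop codons, chosen to match what mainstream
distance packages do:

* **Sites.** Each codon position contributes the fraction of its
  single-nucleotide changes that are synonymous, computed among the
  changes that do not create a stop codon (renormalizing over the
  remainder). Synonymous and nonsynonymous site counts therefore always
  sum to 3 per codon. Per pair they are averaged over the two sequences.
* **Differences.** For codons differing at k positions, synonymous and
  nonsynonymous step counts are averaged over the orderings of the k
  changes whose intermediates are all sense codons. Codon pairs connected
  *only* through stop-codon pathways are skipped entirely (sites and
  differences), as are codons containing a gap, `N`, or a stop.
* **Correction.** d = −(3/4)·ln(1 − 4p/3), applied separately to
  p<sub>S</sub> and p<sub>N</sub>; p ≥ 3/4 yields the `NC`
  (not-computable) status, as does d<sub>S</sub> = 0 for the ratio.

The implementation is validated to 1e−9 against an exhaustive-pathway
brute-force counter written independently (tests/oracles.py).

### Filters, binning, bimodality, flagging

Pairs must satisfy d<sub>S</sub> < 1.5 (mutational saturation) and
d<sub>N</sub> > 0.01 (enough informative substitutions); both bounds are
strict and configurable (`dn_min`, `ds_max`). Surviving ratios are rounded
half-away-from-zero to one decimal.

Bimodality on a histogram of a few dozen values cannot rely on literal
local maxima: one- or two-count outlier bins in the tails read as "modes"
and a plateau of equal counts hides a genuine one. The detector therefore
asks for two *clusters*: a valley at least two bins (0.2 in ratio) wide,
every valley bin strictly below both cluster peaks and below
`valley_ratio` (default 0.5) times the smaller peak, each cluster holding
at least max(2, ⌈`min_mode_fraction`·n⌉) comparisons (default 10%), and
the upper cluster's modal bin at ≥ 1.0. On neutral simulations (ω = 1
everywhere) this gate fires in ≤ 10% of replicates (measured: 0–4%);
the literal local-maximum rule fires on roughly a third of them.

When the gate fires, a sequence is flagged as responsible if at least half
of its usable comparisons have a ratio ≥ `tau` (default 0.9, one
non-iterative pass — deterministic and auditable). Elevated comparisons
are flagged-vs-unflagged pairs; flagged-vs-flagged pairs are excluded
(their ratios are aberrantly low because both lineages accumulated
nonsynonymous changes on the *same* branch-path segments); the rest form
the non-elevated group. The two groups are compared by Mann–Whitney U with
the normal approximation and no tie or continuity correction; U is counted
for the non-elevated group, so complete separation gives U = 0 and a
negative Z.

## Codon simulator

Substitution is Gillespie-simulated per codon along each branch under an
MG94-style parameterization: rate(c→c′) ∝ π(target) · κ^[transition] ·
ω′^[nonsynonymous], stop-codon targets removed, with the overall rate
normalized so one unit of branch length is one expected substitution per
nucleotide site at neutrality. Root codons are drawn from the
frequency-product distribution over sense codons. Defaults: κ = 2,
uniform nucleotide frequencies, standard genetic code (overridable).

**ω is expressed on the NG86 scale.** Raw MG94 rates with κ > 1 make the
NG86 estimate a biased reading of the nominal ω (substitution fluxes are
κ-weighted while NG86 site counts are not; ≈0.89× at κ = 2). Because this
package's measuring instrument *is* NG86, the simulator multiplies the
internal nonsynonymous rate by a closed-form constant c(κ, π, code) =
(F<sub>S</sub>·N̄)/(F<sub>N</sub>·S̄) — neutral synonymous/nonsynonymous
fluxes over mean NG86 site counts — so that the estimated
d<sub>N</sub>/d<sub>S</sub> converges to the nominal ω on long sequences
(c = 1 at κ = 1; disable with `calibrate_omega=False`). Mean neutral
estimates then sit at 1.00 ± 0.03 across replicate 500-codon simulations.

**What the simulator does not model:** indels, among-site rate variation,
codon-usage bias beyond nucleotide frequencies, and within-branch ω
variation. Passing the recovery experiments therefore shows the screen's
logic is sound under its own assumptions, not that real alignments with
alignment error or rate heterogeneity behave as cleanly.

### Planted-lineage recovery design

A pairwise ratio is a path-length-weighted mixture of branch ω's, so no
pairwise screen can detect an elevated lineage whose terminal branch is a
small fraction of every leaf-to-leaf path. The positive control therefore
gives the planted leaf ω = 1.5 on a terminal branch of length 0.55 over a
background Yule tree with mean branch length 0.03 at ω = 0.2 (8 taxa, 500
codons, κ = 2): the nominal mixture ω for planted pairs is ≈1.3 while
planted-pair d<sub>S</sub> stays near 0.85, clear of the saturation
filter — at larger divergences the convexity of the Jukes–Cantor
correction inflates d<sub>S</sub> estimates and drags the planted cluster
below the detection gates. Under this design the planted leaf is flagged
in ≥ 90% of replicates and background leaves in none; the neutral
calibration uses the generator's default geometry (mean branch length
0.1) with ω = 1 everywhere.

## Pathway model

Reactions are single-substrate edges (stoichiometry ignored; compounds
modified at one vs both ends collapsed to one node; glycosylations and
esterifications omitted — all extensible via a user registry file in JSON
or four-column TSV). The registry validates that reactions reference
declared compounds and that the compound graph is acyclic (Kahn). Enzyme
variants (3- vs 4-step desaturase, mono- vs bicyclase) are separate
entries; a bare family symbol resolves to the registry's declared default
(4-step / bicyclic). Reachability is an explicit fixed-point iteration,
checked against a rescanning closure oracle and for monotonicity over
random enzyme subsets. A curated `intermediates` list drives the
incomplete-pathway flag: an organism whose end product is a known
intermediate (e.g. cis-lycopene without CrtH) is marked incomplete, the
in-silico signature of genomic decay or an annotation gap. The shipped
registry is curated data, not code; it covers the canonical branches but
is not exhaustive.

## Clade annotation and gain/loss parsimony

Annotation walks each unlabeled leaf's ancestors to the smallest clade
containing ≥ `min_seed_leaves` (default 2 — a single seed cannot define an
"obvious clade") seed-labeled leaves and assigns only on unanimity; mixed
clades yield `UNASSIGNED`. This is deliberately conservative: it trades
false negatives for a low false-positive rate, and it can never output a
label absent from the seed set. Bootstrap-support gating of the supporting
clade is not applied by default (supports are display metadata in the
input trees); taxonomy-based "adjacent clade" assignment is out of scope
because it needs an external taxonomy.

Dereplication clusters aligned proteins at ≥ 0.99 identity (shared gap
columns ignored, gap-vs-residue counts as mismatch) by connected
components of the thresholded identity graph; representatives are the
longest ungapped sequence, ties broken lexicographically.

Gain/loss uses Fitch small parsimony (Hartigan's counting at polytomies),
with a present-on-ties top-down pass producing one optimal labeling whose
event list length equals the minimum change count; counts are invariant to
rerooting, and events on rooted trees are polarized into gains and losses.
HGT candidates are reported simply as characters whose event count exceeds
a user threshold — the package argues incongruence, not reconciliation.

**Identifiability caveat.** Planted losses on distinct non-nested branches
are *not* always recoverable: parsimony may legitimately prefer a cheaper
flip-and-regain explanation when losses are dense (three losses around a
node with one surviving subclade cost more than one loss plus one regain).
The loss-recovery experiment gates on exact identifiability with an
independent Sankoff-style cost table and demonstrates exact recovery on
the identifiable cases (~80% of all planted families at p_loss = 0.1 on
16-taxon trees), reporting the rest as skipped.

## Recombination screen

*q* = two-state parsimony-informative sites / polymorphic sites, on
third-codon-position columns after complete deletion of gapped or
ambiguous columns. The clonal null simulates alignments of the observed
dimensions on the reference tree under K80 (κ = 1, i.e. Jukes–Cantor, by
default): the expected invariant-column probability is computed exactly by
pruning (three numbers per node suffice under K80's state symmetry) and
the branch-length multiplier matching the observed polymorphic count is
solved by bisection to machine precision. Both one-sided tail
probabilities are reported with the add-one rule
(1 + #{q<sub>null</sub> ≤ q<sub>obs</sub>})/(n + 1), which keeps the test
valid at its nominal level despite discreteness; which tail is *flagged*
is configuration (`tail`, default `lower`, matching the reading that low
q accompanies non-detection). The null scheme is this package's own; no
equivalence with any historical implementation is claimed.

Two measured properties frame its use:

* **Calibration.** On clonal κ = 1 data tested against the generating
  tree, one-sided rejection at α = 0.05 occurs in ≤ nominal + Monte-Carlo
  error of 50 replicates (measured 4–10%). Testing κ = 2 data against a
  Jukes–Cantor null inflates the *upper* tail to ~14% — transition bias
  creates parallel substitutions that read as excess informative sites —
  hence the κ option, to be matched to the data when known.
* **Power.** Recombinants between two independently drawn 8-taxon trees
  with a midpoint breakpoint, analyzed against a neighbor-joining tree
  estimated from the data (the intended use case; NJ compresses the
  conflicted internal branches, so the recombinant's informative-site
  excess lands in the upper tail), are detected in ~30–45% of replicates
  versus ~0–7% of clonal controls at α = 0.05. The statistic is a screen,
  not a localizer: breakpoints are out of scope.

## Profile evolution with loss and transfer

Enzyme profiles propagate an ancestral family set down a tree with
independent per-branch, per-family loss (probability `p_loss`), after
which `n_hgt` transfer events are placed uniformly over valid
(donor branch, recipient branch, family) triples — donor carrying, the
recipient lacking, the family — restoring the family throughout the
recipient's subtree (and erasing the overridden loss records, so the event
log reproduces every leaf profile exactly; this conservation is tested).
Leaves whose profile reaches beta-carotene, the retinal precursor, carry a
rhodopsin flag with probability `p_rhodopsin` (default 0.5). Transfers
are placed after losses, a deliberate simplification: the log is ground
truth for screen testing, not a time-resolved gene history.

## Problem sizes and determinism

The standard experiment sizes — 8-taxon, 500-codon selection simulations
over 20–50 seeds; 16-taxon profile evolution over 20 seeds; 50-replicate
null tests at 200 inner simulations — were chosen so each summary rate has
a Monte-Carlo standard error of a few percent while a full acceptance run
completes in well under a minute. Every generator and test is
seed-deterministic: identical inputs give byte-identical outputs, replicate
seeds are spawned from a single `SeedSequence`, and the pipeline writes a
manifest of input checksums so reruns can be verified byte-for-byte.
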