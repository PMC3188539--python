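# Methods

## Substitution counting

All sequence evolution in the package — reconstruction, correction, and
simulation — uses the equal-exchangeability (Poisson) amino-acid model:
20 states, uniform stationary frequencies, equal exchange rates, branch
lengths in expected substitutions per site.  Its transition probability is
closed-form (`P(same|t) = 1/20 + (19/20)·exp(−20t/19)`), which keeps the
pruning recursions vectorizable across alignment columns and keeps the
simulator and the estimator consistent with each other.

Per-column substitution counts for a subfamily are obtained by assigning one
amino-acid state to every internal node of the subfamily tree and counting
edges whose endpoint states differ.  Two reconstruction modes are provided:

* **marginal** (default): marginal maximum-likelihood posteriors under the
  Poisson model with the tree's branch lengths, argmax per node, ties broken
  alphabetically;
* **fitch**: unit-cost Sankoff dynamic programming, which attains the exact
  minimum-change count on any binary tree; the backtrack also breaks ties
  alphabetically, so outputs are deterministic.

Gapped leaves are missing data for the reconstruction, but ancestors always
receive amino-acid states, so every gapped leaf contributes one inferred
substitution: a column with N gaps gets at least N counts.  This is
deliberate — segments conserved in one subfamily but deleted in another
surface as high-rate (type I) segments rather than disappearing from the
analysis.  A column gapped across an entire clade is flagged uninformative;
its ancestors are set to the alignment's most common residue and the count
becomes the number of leaves (one per terminal edge).

**Multiple-hit correction.**  Raw edge counts undercount at high rates.  The
default correction fits a per-column rate multiplier λ̂ by maximizing the
pruning likelihood of the column pattern (coarse log-grid over
λ ∈ [10⁻⁵, 50], then vectorized golden-section refinement) and reports
`x = λ̂·T + G`, where T is the clade tree length and G the gap count.  An
`identity` mode returns raw counts unchanged for transparency.  Columns with
no observed change get x = G exactly.  Note that λ̂ is weakly identified for
saturated patterns (likelihood nearly flat near the cap); such columns carry
little rank information either way, but their corrected values should not be
over-interpreted.  Users who prefer external ancestral-reconstruction
pipelines can import a per-site counts TSV instead; all downstream stages
consume the same table.

## The type I mixture

For a clade pair (A, B) with tree lengths t_A, t_B, the per-column counts
are modeled as a two-state mixture: with probability 1 − θ one rate
λ ~ Gamma(α, β) is shared (counts conditionally independent Poisson with
means λt_A, λt_B; marginally a correlated pair with negative-binomial
margins), with probability θ the clades draw independent rates from the same
gamma.  Both marginals are closed-form, so the likelihood is exact.  The
gamma-function form of the Poisson mass extends to real-valued corrected
counts, which are the default input (tree lengths enter separately).

Optimization is L-BFGS-B on (logit θ, log α, log β) from five deterministic
starts (θ₀ ∈ {0.1, 0.3, 0.5, 0.7, 0.9}; α₀ = 1; β₀ matched to the pooled
mean rate); the best final likelihood wins.  The standard error of θ̂ comes
from a finite-difference observed-information matrix; boundary estimates are
flagged and given no SE.  Per-site posteriors are
`θ·m₁ / (θ·m₁ + (1−θ)·m₀)`; the default call cutoff is 0.90.  The rate
direction of a type I site orders the pair by observed x/t.

Because the alternative component shares its gamma with the null, strongly
bimodal alternatives (e.g. rates shifted by a fixed large factor) are mildly
misspecified; simulations show this inflates θ̂ by a few hundredths while
leaving the posterior ranking intact.  θ estimates are validated by
simulation, not against any particular third-party implementation, since
published variants of the estimator differ.

**Type II.**  No likelihood is fitted: a column is type II iff the
reconstructed root states of the two clades fall in different radical groups
(positive / negative / hydrophilic / hydrophobic) and the corrected
within-clade counts are ≤ 0.5 (configurable) in both clades.  θ_II is the
proportion of type II columns among columns conserved in both clades — a
deterministic proportion, reported as such.  Site classes are mutually
exclusive with precedence typeII > typeI > type0 (zero corrected counts and
identical consensus in both clades) > none.

## Structural statistics

The contact graph joins typed columns whose residues lie within 4 Å.  The
default uses α-carbon distance per the classical definition; because Cα–Cα
at 4 Å captures almost exclusively chain neighbors, `CB` and `any-atom-min`
modes are exposed for more permissive side-chain contact rules.

The quartet clustering statistic counts same-edge, graph-adjacent pairs
among the top-N posterior-ranked type I sites of the two quartet edges
(N = 25 by default; sites ranked for both edges are discarded from both).
The permutation null re-assigns the pooled 2N′ sites to the two edges:
exhaustive enumeration of all C(2N′, N′) assignments when the pool is small
(≤ 16 by default), otherwise Monte-Carlo with the add-one correction
p = (1 + #{S* ≥ S})/(1 + n).  Conditioning on the *observed* site set is
essential: rate shifts may legitimately concentrate in particular regions,
and only the edge labels are exchangeable under the null.  The companion
consecutive-pair statistic counts sequence-adjacent same-edge pairs,
separating chain adjacency from genuine 3D clustering.  The upper tail is
tested (clustering = larger S).

Region tests compare a named column range (e.g. a recognition loop) against
random same-size column subsets, using the mean (location) and the rank sum
with mid-ranks (distribution); small pools are enumerated exactly, and the
default lower tail asks whether the region evolves more slowly, with
`greater`/`two-sided` flags available.  The Poisson LRT for rate uniformity
across n trees uses −2 log Λ = 2 Σ xᵢ log(xᵢ/(λ̂tᵢ)), λ̂ = Σx/Σt, against
χ²(n−1); it is invariant under common rescaling of the tᵢ and degenerates
gracefully (all-zero counts give statistic 0, p = 1).

## LSCs, states, and parsimony

LSCs are maximal connected components of the typed-column contact graph with
at least two members and at least one type I/II member, numbered by smallest
member column.  When more than one clade pair is scanned, typed columns are
merged across pairs before component extraction, keeping each column's
strongest class (II > I > 0) — the automated analogue of curating one
catalog from per-pair site sets.

Per-clade LSC states are assigned automatically from consensus profiles: two
clades share a state iff, at every member column, their conservation status
matches (consensus frequency ≥ 0.7 in both or neither) and conserved
consensus residues share a radical group.  States are single-linkage
components of this relation; intransitive similarity flags the character.  A
clade gapped across the whole LSC is missing (`?`, a Fitch wildcard).  The
original analyses of this kind assigned states by expert inspection of logos
and structures; the automatic rule is a reproducible surrogate, and a
manual-override table is first-class so published assignments can be encoded
verbatim.

Parsimony over the clade × LSC matrix is exhaustive: every unrooted binary
topology (generated once each by stepwise addition; (2n−5)!! trees, feasible
to n = 9 ≈ 135,135) is scored by Fitch counting with bitmask state sets;
all optimal topologies are reported (unrooted; the Newick rendering roots at
the first taxon's neighbor for display only), with per-character change
counts on the first optimum.  Heuristic search for > 9 taxa is out of scope.

## Synthetic data

The generator emulates the study conditions the method targets, using the
same Poisson substitution model as the estimator:

| parameter | default | meaning |
|---|---|---|
| clades / leaves | 2 × 16 | balanced binary subfamily trees |
| tree length | 6.0 per clade | ≈ 0.2 substitutions/site per edge, the per-edge divergence regime of real subfamily trees (total length is not the right invariant when leaf counts differ) |
| columns | 500 | alignment length |
| gamma shape | 1.0 | site-rate heterogeneity (mean rate 1) |
| θ | 0.5 | fraction of type I columns |
| shift ratio | 8 | type I columns redraw the last clade's rate independently and scale it ×8 or ÷8 with equal probability |
| type II fraction | 0.05 | columns fixed for radically different residues between the first clade and the rest, invariant within clades |
| gap fraction | 0.05 | one contiguous gap block per sequence (the structure reference row is never gapped) |

Coordinates place the reference chain on a 3.8 Å-spaced line — so
chain-consecutive pairs are genuine contacts at 4 Å, as in real backbones —
and lift designated column sets onto compact off-chain grids (diameter ≤
threshold, 40 Å from everything else).  The quartet fixture plants the type
I truth of pair (A,B) in one cluster and of (C,D) in another, or scatters
both when generating a null dataset.

What the generator does *not* emulate: empirical exchangeability matrices,
among-branch rate variation within a clade, realistic indel evolution, or
actual protein geometry.  Passing tests therefore demonstrate correctness
and calibration of the statistics under the stated generative assumptions,
not performance on any particular real protein family.

## Numerical and design choices

* Columns are 1-based in every report; sequence order follows the input.
* All ties (reconstruction states, posterior ranking, state labels,
  component ordering) break deterministically, and every resampling
  operation takes an explicit seed, so identical inputs and seeds give
  byte-identical outputs; reports carry no timestamps.
* Monte-Carlo p-values use the add-one correction and never report 0; exact
  modes report the true tail proportion.
* Alignment-to-structure mapping pairs the k-th non-gap reference column
  with the k-th resolved residue, sliding the shorter sequence along the
  longer when lengths differ and tolerating ≤ 5 % residue-identity
  mismatches (crystallized constructs frequently differ from database
  sequences); mismatches are logged.
* Problem sizes in the test-bench (20 replicates of the standard fixture for
  parameter recovery; 10,000 null replicates for LRT calibration; 100
  replicates for region-test power; 10,000–100,000 permutation resamples)
  were chosen to bound the Monte-Carlo error of each check well below its
  decision margin.

## Known limitations

* The Poisson amino-acid model ignores unequal exchangeabilities and
  stationary frequencies; corrected counts are accordingly approximate for
  real proteins.
* θ_II is a plug-in proportion without a standard error.
* The multiple-hit correction is per-column ML, which is noisy for short
  trees and unidentified deep in saturation.
* One reference structure defines the contact graph; families with mobile
  elements may need per-clade structures, which is out of scope.
* Exhaustive parsimony caps at nine subfamilies.
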