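# Methods

## Model

Sequences evolve along a fixed phylogeny with branch lengths in expected
substitutions per site. Three parameters describe indel dynamics:

- **IR ≥ 0** — indel-to-substitution rate ratio. With the substitution
  rate normalized to 1 per site per unit branch length, indel events
  occur at a total rate of IR per site. By default the rate is split
  equally between insertions and deletions (so insertion rate =
  deletion rate = IR/2 per site, and the expected sequence length is
  stationary); `ir_split="each"` instead uses IR for each side, for
  sensitivity checks against tools that define the ratio per side.
- **a > 1** — slope of the indel length distribution
  Pr(k) = k⁻ᵃ / Σ_{j=1..max_len} j⁻ᵃ, a Zipf (power) law truncated at
  `max_len` = 50. This reflects the widely observed inverse relation
  between indel length and frequency.
- **RL ≥ 1** — integer length of the ancestral sequence at the root.

The per-branch process is an exact Gillespie simulation: at current
length L the insertion rate is IR/2·max(L, 1) spread uniformly over the
L+1 junctions (an empty sequence keeps one junction so it can regrow),
and the deletion rate is IR/2·L with a uniformly chosen start site.
A deletion whose drawn length overruns the end of the sequence is
truncated there. This boundary convention is the simplest well-defined
one; it slightly shortens the average *realized* deletion relative to
the drawn length distribution. Because inference compares simulated
alignments against the input under the *same* convention, the
convention cancels when the input is itself simulated data; on real
data produced by other processes it is one of several model
idealizations (see Limitations).

Every residue carries a globally unique homology id, and a master
ordering of ids is maintained across the whole simulation, so the true
alignment of the leaves is assembled exactly from the event history:
columns are ids observed in at least one leaf, ordered consistently
with every leaf's token order. All-gap columns cannot occur, and each
column contains exactly one homology id.

Substitutions never alter any of the summary statistics below, so the
inference loop does not sample them; dropping events that cannot change
the observed state is exact Poisson thinning and leaves the indel
process identically distributed. When residue-level output is requested
(`indelfit simulate`, or `simulate_true_msa` with a sampler),
substitution events compete in the Gillespie process and a pluggable
replacement layer (default: uniform over the 20 amino acids) mutates
residues; without a sampler each homology id receives one conserved
residue. Residue realism is cosmetic by construction — no analysis in
this package depends on residue identity.

## Summary statistics and fit measure

An alignment is summarized by v = 5 attributes: number of columns;
total number of gap blocks (maximal runs of `-` within a row, summed
over rows — a proxy for the number of indel events); average gap block
length (total gap characters / total blocks, 0 if gapless — a proxy for
mean indel length); and the minimal and maximal ungapped sequence
lengths. Gap blocks are counted per row, matching the reading of the
block count as "indels per sequence over the whole alignment".

For a candidate Θ, N simulated alignments give a mean μ and unbiased
(n−1) sample covariance S of the attribute vectors; the objective is
the squared Mahalanobis distance D² = (x−μ)ᵀS⁻¹(x−μ) of the input's
attributes. The quadratic form itself is the χ² statistic; no square
root is ever taken internally (a printed "distance" is √D² for display
only). The fit p-value is 1 − CDF_χ²(v−1)(D²), with v−1 = 4 degrees of
freedom. The attributes are correlated and only approximately
multivariate normal, so the p-value is a calibrated-in-the-bulk
diagnostic rather than an exact test; under the generating model the
empirical Pr(p < 0.05) sits near, but not exactly at, 0.05 (asserted as
a [0.01, 0.15] sanity band in the tests).

Five attributes estimated from N ≈ 100 simulations can be
near-collinear (e.g. min/max length under tiny IR), so if S is singular
or has condition number above 1e12, a ridge ε·tr(S)/v·I with ε = 1e−8
(escalated tenfold as needed) is added and recorded in the moments'
diagnostics.

## Search

Coordinate-wise golden-section minimization of D² over RL ∈ [50, 1800],
IR ∈ [0, 0.16], a ∈ [1, 2], cycling RL → IR → a, from three RL starting
points: the minimal ungapped length, the maximal ungapped length, and
the number of columns (duplicates merged). IR starts at 0.075 and a at
1.55. Golden-section returns the best *evaluated* point; RL is searched
on the continuous interval and rounded at evaluation time.

Two structural choices matter:

- **First cycle holds RL at its starting value** while IR and a adapt.
  Re-optimizing RL over the full interval immediately — with IR and a
  still at their generic starts — produces the same RL trajectory for
  every start, collapsing the multi-start into one search and letting
  coordinate descent lock onto IR-high/RL-low local minima. Anchoring
  the first cycle preserves the start diversity the multi-start exists
  for; subsequent cycles search all three coordinates over their full
  intervals.
- **Common random numbers** (default): the N simulation seeds are a
  fixed function of the search seed and the replicate index, identical
  for every evaluated Θ. The objective is then a deterministic function
  of Θ, which golden-section (built for unimodal noiseless functions)
  needs; repeated triples are served from a memo table instead of
  re-simulated. `crn=False` restores independent ensembles per
  evaluation.

Numerical defaults: golden-section tolerances 1.0 (RL), 5e−4 (IR),
5e−3 (a) — roughly an order of magnitude below the sampling error of
the corresponding estimates; a start stops when a full cycle improves
D² by less than 1% (improvements below that do not move the parameters
measurably) or after 5 cycles; from the third cycle each coordinate is
refined within a local window (max of 25 tolerances and 2% of the
interval) around the incumbent rather than the full interval; a start
that lands within twice the tolerances of a finished start is stopped
early, since it would converge identically. Ties across starts are
broken toward smaller D², then smaller RL. The reported D² and p-value
come from a fresh confirmation ensemble of 10·N simulations at the
optimum, so the headline fit test is less noisy than search-time
evaluations.

One generator per simulation is consumed along a canonical preorder
edge list compiled once per tree, making results independent of
traversal implementation details; every stochastic entry point takes an
explicit seed.

## Synthetic benchmark

The recovery experiments are fully self-contained: a seeded surrogate
tree (Yule topology, i.i.d. exponential branch lengths rescaled to a
chosen total) stands in for a real single-protein phylogeny. Defaults
are 29 taxa — the size of a classic bacterial azurin alignment — and a
total branch length of 5.0 substitutions/site, typical of a deeply
diverged protein family; any user newick can be substituted. Seven
standard parameter configurations vary one parameter at a time around
a = 1.3, IR = 0.02, RL = 350 (RL ∈ {100, 350, 500}, a ∈ {1.1, 1.3,
1.7}, IR ∈ {0.01, 0.02, 0.1}). Full-scale experiments use 50 replicate
alignments and N = 100; the default harness and the acceptance script
run a reduced protocol (10 replicates, N = 50; the N-sweep uses 20
replicates over N ∈ {10, 30, 100}) so a complete run finishes in
minutes on one CPU. At either scale the tabulated report is mean ± SE
(sample SD/√replicates) per parameter and configuration.

What the synthetic benchmark does and does not show: inputs are *true*
alignments from the same generative process the search simulates, so
recovery accuracy isolates the estimator itself. Real alignments are
reconstructed by alignment programs with their own biases (over- or
under-alignment shifts the apparent indel rate), may contain paralogs
or partial sequences, and evolve under selection that varies along the
sequence — none of which the generator emulates. Passing recovery tests
therefore demonstrates correctness of the machinery, not immunity to
alignment error.

## Performance

The inner loop dispatches to a numba-compiled kernel that reproduces
the pure-Python branch simulation draw-for-draw (bit-identical output
from the same seed, asserted in the tests), at roughly an order of
magnitude lower cost; a full search on a 29-taxon, 500-column alignment
evaluates a few hundred parameter triples (~20,000 simulations) in
seconds.

## Degenerate inputs and edge cases

- A sequence may shrink to length 0 along a branch; it can regrow via
  its single remaining junction, and an empty leaf contributes one
  all-gap row (one gap block spanning the alignment).
- If every leaf is empty the attribute vector is all zeros.
- Gapless inputs drive IR to the lower bound 0; IR = 0 simulation is
  well-defined (no indels, alignment width exactly RL).
- Trees may be rooted or unrooted; unrooted newick is anchored at the
  parsed top node. MSA names need not match tree leaf labels (only
  topology and branch lengths enter the simulation); a mismatch is
  logged as a warning.
- `.` and `*` gap glyphs are normalized to `-` on read; rows are
  uppercased.

## Limitations

Indel parameters are assumed homogeneous across sites and lineages;
length distributions other than the truncated Zipf are not implemented;
the method fits the single best triple rather than a posterior; and
biases introduced by alignment programs are not modeled (re-aligning
simulated data with the same aligner as the input would be the natural,
if expensive, correction). The goodness-of-fit p-value inherits the
approximate normality of the attributes and should be read as a
diagnostic, not an exact error rate.
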