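# Methods

This note documents the models, statistics and design choices behind
`radsig`, in the spirit of a package methods appendix. It states what
each procedure assumes, which knobs matter, and what the synthetic-data
calibrations do and do not demonstrate.

## Substitution models and likelihoods

Amino-acid evolution is a stationary, reversible 20-state CTMC. The rate
matrix is assembled as `Q = S diag(π)` from a symmetric exchangeability
matrix `S` and equilibrium frequencies `π`, the diagonal set so rows sum
to zero, and the whole matrix scaled so `-Σ_i π_i Q_ii = 1`; branch
lengths are therefore expected substitutions per site. Two matrices are
built in:

- **poisson** — all exchangeabilities equal, uniform frequencies. Its
  closed forms (`P_ii(t) = 1/20 + (19/20) e^{-20t/19}`) make it the
  analytically checkable default for tests and simulations.
- **rtrev** — the published reverse-transcriptase-derived matrix
  (Dimmic et al. 2002, J Mol Evol 55:65–73) with its frequencies,
  appropriate for retroelement ORF proteins.

Rate heterogeneity uses the discrete-gamma approximation with `k`
equal-probability categories whose rates are the bin means of
Gamma(α, 1/α) (mean of the category rates is exactly 1). Defaults:
`α = 1.0`, `k = 4` for rtREV, `k = 1` for the Poisson model. α may be
fixed by the user or estimated by a 1-D bounded ML search on a fixed
tree; no claim is made that a particular α reproduces any published
analysis, which did not report one.

Transition matrices come from the symmetric eigendecomposition of
`diag(π)^{1/2} Q diag(π)^{-1/2}`; tiny negative entries from floating
point are clipped at zero. Log-likelihoods use Felsenstein pruning,
vectorised over compressed site patterns and rate categories. Gaps and
`X` are fully ambiguous states (leaf conditional = 1 for every state).
Reversibility makes the likelihood independent of root placement (pulley
principle); the tests enforce this to 1e-8 and check 4-taxon likelihoods
against a brute-force sum over internal states computed with
`scipy.linalg.expm`.

## Quartet likelihood mapping

For a quartet `{a,b,c,d}`, each of the three unrooted topologies has
five branches. These are ML-optimised by coordinate descent: bounded
Brent on each branch (bounds `[1e-6, 10]`, tolerance 1e-6), internal
branch last in each sweep, up to 50 sweeps, stopping when a sweep
improves the log-likelihood by less than 1e-6. The fixed sweep order and
deterministic optimiser make results reproducible bit-for-bit. Sites
that are gap/X in all four taxa are dropped. Evaluations are done in the
eigenbasis of the rate matrix so a single-branch move costs one small
matrix product.

The three optimised log-likelihoods map to barycentric weights by
softmax (equal topology priors). Classification into the seven simplex
regions uses an explicit rule: *center* if the largest weight is below
1/2; otherwise *corner* of the largest weight if the second-largest is
below 1/3; otherwise the *edge* between the two largest. Ties break
toward the lower topology index. Both thresholds are configurable; the
defaults give region areas that qualitatively match published
likelihood-mapping figures, but they are a documented approximation of
the original tool's geometry, not a reproduction of it.

Two runs are compared on their (resolved, conflicting, unresolved)
triples with a χ² goodness-of-fit of the second run's counts against the
first run's proportions (df = 2); a 2×3 contingency test is available as
an option. The two orientations give different statistics; the
goodness-of-fit form is primary because the reference run plays the role
of an expected distribution.

**Calibration on synthetic data.** With 500 sites and terminal branches
0.225, quartets simulated on a resolved topology (internal branch 0.5)
classify to the correct corner essentially always. Data simulated on a
star (internal branch 0) land mostly in the center, but not ≤20% in
corners: the best-vs-second log-likelihood gap at the internal-branch
boundary is O(1) noise (observed median ≈ 0.2 nats), which spuriously
resolves roughly a fifth to a quarter of star quartets under the default
thresholds, essentially independent of sequence length. This is a
property of the statistic at these settings, not an optimiser artefact
(the spurious corners are symmetric across topologies).

## Tree building

p-distances use pairwise deletion: positions with a gap or `X` in either
sequence are excluded per pair; a pair with no comparable positions is
an error. Neighbor joining follows Saitou–Nei with two deterministic
conventions: Q-criterion ties break on the lexicographically smallest
pair of subtree keys (smallest leaf label in each subtree), and negative
intermediate branch lengths are clamped to zero with the deficit moved
to the sibling branch so the pair's summed length is preserved. On
additive matrices NJ recovers the generating topology and lengths to
1e-10 (tested on random trees up to 12 taxa). NJ stands in for
minimum-evolution searches at desk scale; externally inferred trees can
be imported instead (newick, supports as internal-node labels, posterior
probabilities in [0,1] rescalable to percent).

Bootstrap supports resample alignment columns with replacement; the
support of each internal bipartition of the full-data tree is the
percentage of replicate NJ trees containing it.

## Radiation diagnostics

Edges partition into terminal (child is a leaf) and internodal (child is
internal). A degree-2 root is treated as a serialisation artifact of an
unrooted tree: its two edges are merged into one, classified terminal if
one endpoint is a leaf (the root sat on a terminal branch) and
internodal otherwise. This keeps the terminal count equal to the leaf
count and matches the unrooted reading of the tree.

The two partitions are compared with Welch's unequal-variance t-test
(Satterthwaite fractional df, two-sided p). Node height is the maximum
path length from a node to its descendant leaves (a mean-path mode is
provided); relative height divides by the total branch length of the
tree; rows are internal non-root nodes carrying a support. The
height/support association is Pearson's r with the usual t-transform
p-value. The combined verdict is *radiation-consistent* when the Welch
test is significant (terminal > internodal) **and** r is significantly
negative, both at a configurable α (default 0.05).

Choosing max (not mean) path length makes "deeper node" correspond to
larger height on non-ultrametric trees, matching the verbal reading that
deeper nodes carry lower support.

## Library test

The statistic `S` counts unordered conspecific lineage pairs whose MRCA
clade contains no leaf from any other species (the pair sits in an
all-conspecific clade). The null shuffles species labels across lineages
— within each clade when stratified — preserving the per-species lineage
counts. The one-sided p-value for "less clustering than chance" is
add-one: `p = (1 + #{S_null ≤ S_obs}) / (n_perm + 1)`; an exhaustive
enumeration mode replaces sampling for small tables. The statistic,
null and sidedness are this package's formalisation of a pattern that is
usually argued from co-occurrence tables and tree inspection.

**Power at small designs.** With two lineages per species only cherry
pairs can contribute to `S`, and a 12-leaf tree (6 species × 2 classes)
has at most six cherries, so the null itself puts more than half of its
mass on `S = 0`. Observing `S = 0` at this size is therefore consistent
with, but not significant evidence for, the library scenario — typical
one-sided p is ≈ 0.6–0.7 regardless of how cleanly the lineage classes
separate. The test gains power with more species, more lineages per
species, or both; the summary output reports the null mean of `S` so the
reader can see how informative the design was.

## Synthetic data

All generators are pure functions of their seed. Defaults mirror the
radiation regime the diagnostics target: 87 tips; terminal branch
lengths ~ Exponential(mean 0.225); internodal ~ Exponential(mean 0.042)
(substitutions per site); 542-column alignments under rtREV+G.
Exponential lengths were chosen for their analytic means, which the
tests check directly. Topologies come from uniformly random joins
(coalescent-style), giving a degree-3 root and `n−3` internodal edges.
Sequence evolution draws root states from π, fixes one gamma category
per site across the whole tree (a rates-across-sites model), and samples
child states from the transition matrices.

R2-like proteins plant the clade's zinc-finger motifs, in order, with
spacer lengths drawn inside the grammar bounds; spacer residues exclude
C and H so the planted motifs are provably the only grammar matches —
which is what makes exact round-trip recovery a meaningful test. rDNA
loci are tandem units carrying the exact 12-nt target, with elements
inserted between the half-sites at chosen units; background sequence is
scrubbed of accidental half-sites for the same reason. Library-scenario
trees place one lineage per class per species, with class stems diverging
before any species split (so conspecific lineages are never sisters);
the duplication mode nests all of a species' lineages in a cherry
instead.

What the generators deliberately do not emulate: indels and alignment
error, rate variation across lineages (heterotachy), model
misspecification (data are simulated under the analysis model),
recombination between elements, 5′-truncated copies, and rDNA concerted
evolution. Passing calibrations therefore demonstrate the statistics'
behaviour under their own assumptions, not robustness to real-data
violations of them.

## Numerical and interface conventions

Coordinates are 0-based half-open everywhere; the target-site cleavage
coordinate is the junction offset between `…AAGG` and `TAGC…` (window
start + 6). Junction detection requires the `AAGG` half-site exact and
allows mismatches only in the 2-nt `TT` context; inserted intervals
close at the first downstream `TAGC` at least 100 nt away (configurable;
the minimum prevents pairing a site with itself). Family clustering
scores global-alignment identity as matches over aligned columns (gaps
in the denominator) and joins families by single linkage, so one
borderline pair can merge two otherwise-distinct families — the
behaviour a bare pairwise threshold implies. Zinc-finger scanning is
greedy leftmost with lazy spacing (shortest match at each start), which
is deterministic and reads motifs N→C.

The pipeline report is JSON (schema version 1) with full-precision
numbers; every stochastic stage derives its seed from the master seed,
so reports are bit-reproducible. Simulation sizes in the test suite and
the acceptance script (e.g. 40–87 tips, 100–300 sites, 100–200 quartets,
100 bootstrap replicates) were chosen as the smallest sizes at which the
calibrated behaviours are stable.

## Known limitations

- The seven-region simplex geometry is an explicit approximation; if a
  reference tool's boundaries differ, adjust the two thresholds.
- NJ is a stand-in for ME/ML/BI tree searches; import externally
  inferred trees for real analyses.
- The library test is underpowered below roughly a dozen conspecific
  pairs (see above).
- Star-like signal is over-resolved by a few percent at the default
  region thresholds (see the quartet-mapping calibration note).
- The zinc-finger grammar's spacing tolerances and the alignment scoring
  behind the 90% family rule are conventions, not biological claims;
  both are configurable.
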