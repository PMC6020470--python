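# Methods

This note documents the models and procedures implemented in `phylotu`,
the defaults that matter, what the synthetic-data generator does and
does not emulate, and the numerical and design choices that were
genuinely open.

## Profile HMM

The profile is a plan7 architecture over the reference alignment's
match columns (columns with gap fraction ≤ 0.5; `K` match states).
Emissions and transitions are posterior means of position-specifically
weighted counts under Dirichlet priors — Henikoff position-based
sequence weights (each residue contributes `1/(r·s)` with `r` distinct
symbols in the column and `s` the count of its own symbol, normalized to
mean 1), and a symmetric Dirichlet(1) prior wherever no trained prior is
supplied. Dirichlet densities are fit by L-BFGS on log-concentrations
maximizing the Dirichlet-multinomial (Polya) marginal likelihood;
mixtures by EM with component-wise weighted Polya refits, initialized at
the pooled density fit so a 1-component mixture reduces exactly to the
density model.

Special states: N and C emit flanking read bases at background
frequency (self-loop 0.9); I_0/I_K model untemplated 5'/3' overhangs
(entered with probability 0.02 from B, and 0.05 from M_K,
respectively); entry is uniform wing-retracted B→M_k and exit M_k→E
uniform at 0.01 per state (M_K keeps its residual mass for E). These
constants are architectural, not trained; they make every outgoing
distribution a proper distribution and render empty match paths
impossible. Alignment is global in the read, local in the profile.
`N` read bases emit with probability 1 (score-neutral). Reads with no
usable seed fall back to the full (non-banded) Viterbi; unpaired reads
that fail to seed on the forward strand are retried reverse-complemented.

Banding: each FM-index seed defines a DP diagonal; cells farther than
`band_width` (default 100) diagonals from the seed diagonals' envelope
are excluded. The banded recurrence is otherwise identical to the full
one, so its score is a lower bound that matches the full score whenever
the optimal path stays inside the band. Seed finding uses maximal exact
matches of ≥ 20 bp anchored within the first/last 40 bp of the read,
rejecting seeds with more than 10 consensus hits as ambiguous; these
three knobs are exposed as configuration since fixed-primer amplicons
seed almost always at these defaults while random sequence does not.

Paired-end mates are aligned independently (reverse mate
reverse-complemented) and merged as one alignment spanning
`[min cs_start, max cs_end]`; columns between non-overlapping mates are
unobserved and excluded from placement likelihoods (identical to gap
handling). Overlapping columns take the forward mate's call.

## Substitution models and rate variation

GTR, TN93 and HKY85 are parameterized by equilibrium frequencies `pi`
and a symmetric exchangeability matrix `R`, with `Q_ij = R_ij·pi_j`
normalized to mean rate 1. `P(t) = exp(Qt)` is computed through the
symmetrized similarity transform `D^{1/2} Q D^{-1/2}` (real spectrum
guaranteed by reversibility); the implementation is checked against a
generic matrix exponential in the tests.

Training counts ancestral→derived substitutions either by the
three-sequence method (an outgroup resolves the ancestor of a pair at
sites where it matches one member) or the symmetric two-sequence
method. Triplet/pair enumeration is capped at 50 000 combinations,
subsampled deterministically from the seed. Exchangeabilities are
`R_ij ∝ F_ij/(pi_i·pi_j)` from the symmetrized count matrix, with the
TN93/HKY85 constraints applied by pooling the relevant entries.

Among-site rate variation uses k = 4 equal-probability discrete-Gamma
categories (category rates are conditional means, renormalized to
average exactly 1; k = 1 reproduces fixed-rate likelihoods to machine
precision). The shape is estimated by negative-binomial moment matching
`alpha = m²/(v−m)` on per-site mutation counts, where a mutation is a
branch whose ML parent/child states differ (ML-state comparison was
chosen over parsimony recounting; the tests pin this definition).
Under-dispersed counts return a rate-homogeneous sentinel. Rate
variation is off by default: on reference trees built under fixed-rate
models it degrades placement and costs a factor ~k in time.

## Reference tree engine

Leaves carry the alignment rows restricted to match columns; gaps and
ambiguity codes are fully ambiguous (likelihood 1 for every base) —
the standard pruning convention. Non-bifurcating input trees are
canonicalized by inserting zero-length branches. After one pruning pass
plus one preorder pass, every branch stores two matrices: the downward
message (subtree seen from the child end) and the upward message
(everything else, seen from the parent end), ~2·ncat·4·S doubles per
branch. Any branch can then serve as a local root in O(1) — verified by
the rerooting-invariance tests — which is what the placement step and
the read simulator rely on. The log-space convolution uses a
per-column max shift, stable for entries down to −10⁴.

Ancestral states are per-site maximizers of the marginal posterior
(up-message × down-message × pi), with a gap emitted where a node's
descendant leaves are gap-majority. Taxonomy is propagated to unnamed
nodes from the nearest annotated ancestor; the root must carry at least
a kingdom label.

The reference package is stored as a single self-describing JSON text
container (magic + version) bundling the alignment, tree, taxonomy and
model text; the index, profile and likelihood caches are re-derived
deterministically on load. This keeps the artifact inspectable and
byte-reproducible; at the cost of a re-evaluation on load, which is
negligible at the scales this package targets.

## Placement

Seeding ranks all nodes (observed and inferred sequences) by p-distance
over the read's consensus interval, keeping `max_seeds = 5`; candidate
branches are those incident to seed nodes. The estimate step splits the
branch proportionally to the read's p-distances to the two endpoints
(`w_ur/w0 = d_u/(d_u+d_v)`, 0.5 when both are zero) and sets the
pendant length to `max(min(d_u,d_v) − min(w_ur,w_rv), 1e-6)` — the
simplest triangle-consistent estimate. The place step refines the top
`top_n = 5` estimates by alternating bounded scalar likelihood
maximization of the attachment point and the pendant length
(convergence `tol = 1e-6`, `max_iter = 100`, pendant capped at 5
substitutions/site). An EM update for branch lengths would also work;
bounded 1-D maximization was chosen for robustness on the pendant
boundary. Non-convergence returns the best-so-far with a flag.

The assigned node is the branch's parent when the attachment collapses
onto it (`w_ur ≤ 1e-6`), otherwise the child; taxonomy is read off the
assigned node. The Q-score maps the placement's softmax weight `w`
among optimized candidates to a phred-like scale
`q = min(250, −10·log10(1−w))`; a single candidate scores 250, two tied
candidates ~3.01. An optional node-height prior
(`log prior = −h(node)/tau`, `h` = maximal branch-length path to a
descendant leaf, `tau = 1`) biases assignment toward near-leaf ranks;
the default is the uniform prior (pure maximum likelihood).

Chimera screening splits the alignment at its middle consensus column
(2 segments; reads narrower than 2×30 columns are flagged unknown
rather than judged), places both halves with the common seed set, and
flags the read when the halves' assigned nodes differ and the joint
LOD of best-vs-alternative placements reaches the cutoff (default 50;
0 is the most sensitive setting). Splices with breakpoints outside the
central half of the amplicon leave one segment essentially pure and are
not detectable by any half-split scheme; the tests therefore measure
sensitivity on centrally spliced simulations.

## OTU summarization

OTUs are assigned-node groups with at least `otu_min_reads = 1` reads
(chimera- and low-Q-flagged reads are excluded upstream). The
representative sequence is the per-site argmax of the Dirichlet
posterior mean of member base counts with prior
`alpha_b = 2 · softmax(node marginal log-likelihood at the site)`
(the concentration acts as two background pseudo-reads; `use_prior =
False` sets alpha to 0), with a gap when gap observations outnumber
bases. The OTU tree keeps OTU nodes plus minimal connectors, collapsing
pass-through nodes with branch-length summation, so pairwise distances
between OTU nodes are exactly preserved.

## Synthetic data and what the tests show

The toy reference generator grows a random bifurcating tree by repeated
leaf splitting (exponential branch lengths, mean 0.08
substitutions/site, +1e-3 floor), evolves sequences from a random root
under the chosen model, and assigns full 7-rank taxonomy strings by
depth quantiles so every per-rank metric is exercisable. The read
simulator draws a branch uniformly, a branching point uniformly along
it, a locus (fixed or uniform) and a length (fixed or truncated
Gaussian, defaults mu=150, sd=30, bounds [75, 300]), then samples each
base from the branch-point conditional posterior; gap sites are skipped
so reads are gap-free. The chimera simulator splices reference pairs
binned by p-distance at a uniform consensus breakpoint, labeling the
product a chimera only for breakpoints in [0.25, 0.75), and strips
alignment gaps.

The generator emulates the sampling structure of an amplicon library
but not sequencing error profiles, PCR bias, abundance skew, or
alignment columns with extreme gap structure; passing tests therefore
demonstrate correctness of the algorithms under the generative model
they assume, not robustness to platform-specific noise. Test problem
sizes (references of 5–24 leaves, 50–200 consensus sites, tens to
hundreds of reads) were chosen so exhaustive oracles — all-path Viterbi
enumeration, all-ancestral-state likelihood sums, every-branch
placement optimization — remain computable; all stochastic checks run
under fixed seeds.

## Known limitations

- Suffix arrays are built by direct sorting and profile DP loops are
  plain numpy; fine up to a few thousand consensus columns, not tuned
  for full-database scale.
- Q-scores are relative to the optimized candidate set; if the true
  branch is outside the seeded candidates the score can be confidently
  wrong (mitigated by `max_seeds`/`top_n`).
- Node ids (and hence OTU ids, branch ids in TSV/jplace) are stable for
  a given saved package, but canonicalization of multifurcating input
  can renumber nodes relative to the raw input tree.
- Paired-end merging takes the forward mate's call in overlap columns
  rather than quality-weighted consensus.
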