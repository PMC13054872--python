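# Methods

## Model

`taxopep` treats taxonomic profiling as inference in a bipartite factor
graph. Every candidate taxon `T` is a binary presence variable with prior
`P(T = 1) = γ`; every retained peptide `P` is a binary detection variable.
A peptide is linked to each candidate taxon whose proteome contains its
sequence (after aggregation to the target rank). Conditional on the number
`n` of present parent taxa, detection follows the leaky noisy-OR

    P(detected | n) = 1 − (1 − β)(1 − α)^n,

i.e. each present parent independently "emits" the peptide with probability
α, and a leak β covers random matches, search errors, and spurious
peptide–taxon links. The per-peptide search-engine score `s` (the
probability the peptide is truly present) attaches as the observation
likelihood `(s, 1 − s)` on the detection variable. The joint distribution
is the product of taxon priors, count-conditional noisy-OR factors, and
observation factors.

Assumptions worth keeping in mind:

* peptide emissions are conditionally independent given the parent count —
  correlated detectability (shared tryptic context, abundance) is not
  modelled;
* the score column is taken at face value as a calibrated probability;
* the candidate set truncates the true hypothesis space, so the modelled
  distribution is itself an approximation whenever more taxa could match.

### Count regularization

With `regularized = true`, the probability of a peptide having `n ≥ 1`
present parents is down-weighted by `1/n` inside each count factor (the
`n = 0` state keeps weight 1 and the factor is renormalized by message
normalization). This encodes the prior that reference collections contain
far more taxa than any sample: useful for small lab-assembled mixtures,
better left off (the default) for complex natural communities, where many
taxa genuinely co-occur.

## Candidate selection

Peptides matching more than 10,000 proteins are removed (conserved
housekeeping sequence, negligible taxonomic signal; the comparison is
strictly greater). Mappings are lifted to the target rank (default
`species`) by replacing each taxon with its ancestor at that rank; taxa
without such an ancestor are dropped. Each taxon then receives the weight

    W_T = Σ_{peptides i mapped to T} #PSM_i / Deg_i,

where `Deg_i` is the peptide's degeneracy **at the target rank, computed on
the full rank-aggregated mapping** (not within the candidate set). Weights
conserve PSM mass: summed over taxa they equal the total PSM count. The
graph admits the `taxa_limit` (default 150) heaviest taxa — ties broken by
taxid, ascending, for determinism — plus every taxon that is the sole
mapping of some peptide, however light. Peptide edges are then restricted
to admitted taxa, so a shared peptide whose other parents were not admitted
becomes unique *within the graph*; per-taxon unique-peptide counts are
recomputed on that basis and reported alongside the posteriors.

## Inference

Marginals are computed by loopy belief propagation with residual-priority
("zero-lookahead") scheduling: a priority queue keyed by the largest
pending L∞ message change decides which factor fires next, with no
lookahead to downstream effects. All variables are binary, so messages
reduce to their "present" component; per-variable products are maintained
in log space to avoid underflow under hundreds of incoming messages.
Messages through a count factor with `k` parents are computed exactly with
convolution trees — a balanced binary tree of pairwise convolutions for the
upward pass and prefix/suffix convolutions for the per-parent
leave-one-out ("downward") distributions — in `O(k²)` total rather than
`2^k`. Plain quadratic convolution is used; FFT convolution would only pay
off far beyond realistic parent counts.

Two implementation choices matter for accuracy:

* **Factor fusion.** Peptides with *identical* parent-taxon sets are fused
  into one count factor whose likelihood is the product of the members'
  observation likelihoods (with the `1/n` weight compounded per member).
  This is an algebraic identity — the joint distribution is unchanged — but
  it removes parallel cycles, so loopy BP on the fused graph is both faster
  and measurably closer to exact marginals. Genus-level shared peptide
  pools, which dominate real mappings, fuse heavily.
* **Damping.** Committed messages are `λ·old + (1−λ)·new` with `λ = 0.5`
  by default. Damping stabilizes cycles and does not move the fixed point;
  a factor whose damped output still differs from its undamped target
  re-enters the queue with that gap as its residual, so on acyclic graphs
  the algorithm still converges to exact inference (the test suite checks
  agreement with exhaustive enumeration to 1e-9).

Convergence is declared when the largest pending residual falls below
`bp_tolerance` (default 1e-6); the update budget is `bp_max_iters` (default
5000) full-graph sweep equivalents. Non-convergence returns the current
beliefs flagged `converged = False` with a warning, never an exception.
The schedule is deterministic — identical inputs give bitwise-identical
marginals regardless of seed.

On loopy graphs BP is an approximation: the fixed point itself deviates
from the exact marginals. On random ≤12-variable graphs with realistic
peptide degeneracy the deviation is typically negligible (median below
1e-3 in the test suite) but reaches a few times 1e-2 on the worst
densely-cyclic instances; `scripts/acceptance.py` measures this worst-case
deviation explicitly. This is a property of loopy belief propagation, not
of the scheduling.

## Parameter grid and selection

Defaults `α ∈ {0.85, 0.9, 0.99}`, `β ∈ {0.5, 0.6, 0.7}`,
`γ ∈ {0.1, 0.3, 0.5}` (27 combinations) span the regimes that fit
metaproteomic samples: near-certain emission from present taxa, a high
leak reflecting pervasive sequence sharing, and priors from "most
candidates absent" to "no prior knowledge". Each combination is scored
against the weight evidence:

1. Candidate taxa are greedily clustered on their detected peptide sets
   using the overlap coefficient `|A ∩ B| / min(|A|, |B|)` at threshold
   0.9, visiting taxa by detected-peptide count (descending), so each
   cluster head is its best-covered member. Min-normalization lets a
   sparsely covered taxon cluster under a well-covered relative. Heads are
   ranked by their own weight `W_T`.
2. The head list `L_W` is compared to the posterior-ranked list `L_S` with
   extrapolated rank-biased overlap (persistence `p = 0.9`, configurable),
   which tolerates nonconjoint lists and emphasizes top ranks.
3. The winner maximizes `M = RBO · S⁻²`, where `S` is the Shannon entropy
   (nats) of the normalized marginal vector, floored at `1e-3` so a
   near-point-mass posterior cannot produce an infinite metric. Exact
   metric ties prefer lower β, then higher α, then lower γ (more causal,
   less leaky explanations). If every RBO is zero the winner is still
   defined by the tie rule but flagged low-confidence.

## Synthetic communities

The generator emulates lab-assembled mock communities with known
composition. A root→genus→species taxonomy (default 4 genera × 4 species)
carries per-species proteomes of 60 synthetic peptide tokens: a fraction
`within_genus_share = 0.3` drawn from a genus-wide shared pool (every
sibling carries the whole pool, so the knob is the exact shared fraction),
`cross_share = 0.05` shared pairwise with random other species, the rest
unique. Six planted species are "present": each of their peptides is
detected with probability 0.5, scored from Beta(8, 2) (a rescored-search
shape concentrated near 0.9), with PSM counts `1 + Poisson(0.5)`; 30 noise
peptides are drawn from absent species' proteomes with Uniform(0, 1)
scores. Everything is reproducible from the seed, and file output is
byte-stable.

What the simulation does **not** emulate: realistic tryptic sequences and
peptide detectability, abundance-dependent coverage, database
incompleteness (present taxa missing from the mapping), contaminants, and
the heavy-tailed degeneracy of real UniProt mappings. Tests passing on
these fixtures therefore establish the correctness of the machinery and
its behaviour under controlled sharing/noise — not field performance on
real samples.

Evaluation reports precision/recall/F1 of `posterior > threshold` calls
(optionally requiring ≥1 unique peptide) against the planted taxa; the
"F1-optimal" threshold is defined as the *largest* grid threshold attaining
the maximal F1 — the most stringent cutoff that still keeps peak F1,
matching the practice of preferring conservative score cutoffs.

## Numerical choices and degenerate inputs

* Message components are floored at 1e-300 before taking logs; scores of
  exactly 0 or 1 are legal and handled without NaNs.
* All orderings (results, candidate ranking, clustering, winner selection)
  break ties by ascending taxid, making every output a total order.
* Scored-peptide files are parsed with exact (`float()`) conversion so that
  write→read round-trips preserve scores bitwise.
* Duplicate input peptide rows collapse to the maximum score; row
  multiplicity supplies the PSM count when no explicit column exists
  (explicit counts take the row maximum instead of summing).
* An empty peptide set for a graph yields prior marginals; an all-zero
  count distribution, empty ranked lists, and an empty ground truth raise
  errors rather than returning conventions.

## Problem sizes

The default test and acceptance workloads use 16-species communities
(~200 detected peptides, 27-point grids; about one second per fitted
model), 100 + 100 random ≤12-variable graphs for the enumeration oracle,
and 10 community seeds for recovery — sizes chosen so the full suite runs
comfortably on a laptop while exercising every code path at meaningful
scale.

## Known limitations

* Loopy BP marginals are approximate on cyclic graphs (quantified above);
  they are also poorly calibrated in the statistical sense — a posterior of
  0.9 should be read as a ranking score with uncertainty semantics, not a
  guaranteed frequency.
* Closely related taxa with near-identical detected peptide sets are often
  not distinguishable; the clustering step mitigates this for parameter
  selection but the posteriors themselves can split evidence between
  siblings.
* Taxa absent from the mapping cannot be inferred; their evidence is
  absorbed by the nearest relatives present in the candidate set.
* The live peptide→taxon annotation service is out of scope: the mapping
  is consumed from a documented JSON-lines file, which a thin HTTP client
  could produce.
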