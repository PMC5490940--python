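# Methods

This note documents the models implemented in `polypharm`, the parameter
choices that matter, what the synthetic data emulate (and do not), and
the numerical decisions taken where the procedure was genuinely open.

## Cavity similarity and group enumeration

Cavity-pair similarity scores in [0, 1] are consumed as input; the
package never computes them (cavity detection and molecular-interaction-
field comparison require structure-analysis tools outside its scope).
Pairs scoring **strictly above 0.6** are classified as similar. The
strict reading of "above" is deliberate and configurable
(`classify_similar(threshold=...)`); classification is monotone in the
threshold, which is property-tested. For the metabolic screen, where
structural coverage of the input is typically sparse, a lowered threshold
can be passed to obtain a longer candidate list; no specific value is
hard-coded.

A polypharmacology group is read as an **anchor star**: one cavity of one
member must be similar to at least one cavity of *every* other member.
An alternative, chain-connected reading (members pairwise linked through
different cavities without a common anchor) would admit groups no single
ligand could plausibly engage, so the anchor reading is used. Enumeration
emits every subset of the anchor's neighbor proteins (group size 2–5),
deduplicating identical protein sets across anchors by keeping the
anchor with the highest weakest-member score, ties broken by lexicographic
anchor id. Correctness is established against a brute-force oracle that
checks the group definition over all protein subsets on instances with up
to 10 proteins and 4 cavities each. Subset expansion is exponential in
the anchor's neighborhood; the `restrict_to` filter (normally the node
set of the network being screened) is applied *before* expansion to keep
the candidate pool bounded.

## Influence matrix and heat screening

The diffusion kernel follows the heat-propagation convention of
column-stochastic random-walk normalization:

    W_ij = A_ij / deg(j),        F = beta * (I - (1 - beta) * W)^(-1)

with restart parameter beta in (0, 1], default 0.5. Column-stochasticity
gives exact heat conservation (1ᵀF = 1ᵀ), which the whole screening
rests on; it also implies F_jj ≥ F_ij (a source retains at least the
directly absorbed share). Pairwise influence is symmetrized as
max(F_ij, F_ji) since the kernel is directional but group membership is
not; a group's representative influence is the maximum over its pairs.
Influence Z-scores are normalized against 10,000 random groups of the
same size drawn **uniformly** over nodes; degree-matched sampling was
considered and left as an option, since uniform sampling is the neutral
default when no stratification is specified.

A modulation assigns 1,000 heat units (h.u.) split equally across its
targets (a k-target intervention is a k-fold milder inhibition per node)
and diffuses them through F. Global heat is measured as the area under
the cumulative diffused-heat distribution, nodes sorted hottest-first,
computed as the mean of the cumulative shares over ranks (a right-Riemann
sum on the unit rank axis; the integration scheme only needs to be
consistent between numerator and denominator). The area is normalized by
the **ideal** distribution — the uniform 1000/n assignment pushed through
the *same* diffusion — with the ideal in the numerator:

    global_heat = AUC(ideal) / AUC(actual)  in (0, 1]

so 1.0 means the modulation's heat ends up as evenly spread as the ideal
gentle intervention, and a network screen reporting, say, 0.32 means 32%
of ideal. Feeding the ideal input through the diffusion (rather than
scoring the raw uniform vector) keeps both areas on the same scale and
makes the uniform modulation score exactly 1.0 by construction.
Advantage divides the combination's global heat by the best global heat
among its members, each given the full budget; a singleton is its own
reference, so its advantage is exactly 1. The 25% screening flag
(advantage > 1.25) is a reporting threshold, not a model parameter.

beta is selected per network by maximizing the average influence at the
inflection point of the per-probe cumulative influence curve over
level-one neighbors. Probes are sampled stratified across degree
quartiles so that hubs and peripheral nodes both contribute; the
inflection point of a discrete cumulative curve is operationalized as the
point of maximum perpendicular distance to the chord (the standard elbow
criterion), which is otherwise undefined for empirical curves. At
beta = 1 the kernel is the identity, neighbor influence is zero
everywhere, and beta = 1 can never win against any informative grid
point. On hub-dominated synthetic networks the selected beta typically
falls in 0.3–0.7 (logged by the tests, not asserted, since it is a
tendency of the topology rather than a contract).

## Seed connectivity and network growth

Percolation significance compares the largest connected component (LCC)
of the seed-induced subgraph with LCCs of uniformly sampled node sets of
the same size; the empirical p uses the add-one estimator
(1 + #{LCC_random ≥ LCC_obs}) / (n_random + 1), which is conservative
and never exactly zero. LCC sizes are computed by batched boolean
transitive closure, so 10,000 randomizations cost well under a second at
the sizes used here.

DIAMOnD expansion scores every non-member node with at least one link to
the current set by the hypergeometric tail P(X ≥ ks) with population
N − 1 (the candidate itself is excluded), successes = current set size,
draws = the candidate's degree; nodes without links to the set have
p = 1 and can never precede them. The seed-weighting parameter of the
original algorithm is fixed at 1. Ties are broken by larger ks, then
lexicographic node id; because mathematically equal tails computed from
different (k, ks) configurations can differ by floating-point noise,
candidates within a 1e−9 relative band of the minimum are treated as
tied before the deterministic tie-break is applied. The expansion is
verified against exact-rational exhaustive enumeration on ≥ 100 random
graphs.

The stopping rule is a sliding-window slope test on the two fold-averaged
cross-validation curves (held-out seed recall, and the fraction of all
seeds in the *major* — seed-richest — connected component of the growing
network): the flattening point of a curve is the smallest rank whose mean
forward increment over `window` ranks (default 10) falls below
`slope_tol` (default 0.002 per rank), and the cut is the rounded mean of
the two flattening points. Both knobs are exposed because "flattening"
admits no canonical formula. The major component is identified by seed
count rather than by node count: that is what the curve is meant to
measure, and it makes the curve provably non-decreasing (per-component
seed counts only merge as nodes are added), whereas the largest-by-size
component could transiently drop seeds. A curve that never flattens
returns the last rank with a warning flag rather than guessing.

## Ligand-set similarity (SEA-style)

The raw score between two ligand sets sums Tanimoto coefficients of
cross-pairs strictly above 0.55. The background mean and SD of the raw
score are fitted by least squares as **linear functions of the set-size
product** n1·n2: the mean of a sum of i.i.d. per-pair contributions is
exactly linear in the product, and empirically the SD is
well-approximated linearly over the size range screened here (a log-log
power-law fit is available as `sd_form="powerlaw"` for backgrounds where
the shared-ligand covariance term, which grows faster than the product,
becomes visible). Background Z-scores are right-skewed — the raw score is
a compound-Poisson-like sum dominated by rare high-similarity collisions
— and a maximum-likelihood Gumbel fit attains higher log-likelihood than
a Gaussian on such backgrounds, which the calibration tests assert. The
E-value is the SEA convention: per-comparison Gumbel upper-tail
probability times the number of comparisons performed, with E ≤ 1e−4 as
the significance call.

Fingerprints are plain fixed-length bitsets. The default molecule
backend is a deterministic hashed-substring fingerprint — a lexical
fingerprint that requires no chemistry toolkit and is entirely adequate
for set-level similarity of identifier-like molecule strings; an RDKit
Morgan backend is available for real SMILES.

## Metabolic co-inhibition

Models are steady-state stoichiometric networks (S·v = 0, bounds per
reaction) with GPR boolean rules; FBA maximizes the biomass flux as a
linear program (solved with HiGHS via scipy). Inhibiting a gene set
evaluates every GPR with those genes false; reactions rendered inactive
have **both** bounds multiplied by the residual 0.01 — applying the Vmax
reduction to |lb| as well as ub so that reversible reactions are
throttled in both directions. Inhibition is applied relative to the
model's recorded inhibition state, making it idempotent and monotone
(bounds only shrink as genes are added, so the FBA optimum never
increases — property-tested). The residual interpretation is "1% of the
bound"; scaling 1% of the wild-type FVA maximum instead would require an
extra LP per reaction and is not order-preserving across reactions, so
it was not adopted.

FVA of a hallmark reaction constrains biomass to ≥ 80% of that model's
own wild-type optimum and maximizes the hallmark flux. Using each
model's *own* optimum (rather than the uninhibited cancer optimum) keeps
the constraint feasible for strongly inhibited models, which is the case
of interest. Hallmark movement is classified by
ratio = (m_inhibited − m_cancer)/(m_healthy − m_cancer): strong reversal
above 0.5, mild reversal between, no effect within ±5% of the gap
(the tolerance replaces visual inspection and is configurable), and
mild/strong worsening mirrored below zero; a zero gap is flagged
degenerate.

Genuine polypharmacology requires the combined cancer biomass reduction
to exceed the best single-gene reduction by a margin (default 5
percentage points) while healthy biomass reduction stays within a
tolerance (default 10%). Both are config keys: the underlying concept —
an effect unreachable by any component alone, with selectivity — needs
explicit thresholds to be testable, and these defaults sit between the
planted fixture's contrast (≥ 50% combo vs ≤ 10% single vs ≤ 5%
healthy) and plausible noise in larger models.

## What the synthetic data emulate — and what they do not

- **Interactome**: preferential attachment (default), giving the
  heavy-tailed, hub-dominated degree distribution that the diffusion
  screening presumes; a configuration-model alternative is available. It
  does not reproduce curated-interactome features such as study bias,
  date-of-discovery effects or module overlap.
- **Seed modules**: a connected node set grown by a random neighbor walk
  and densified with extra edges (probability 0.6 by default), so that
  percolation and DIAMOnD have a recoverable target. Real driver-gene
  sets are noisier and only partially connected.
- **Cavity scores**: background pairs are truncated normal(0.2, 0.08)
  clipped to [0, 1] — mass far below the 0.6 threshold, as in empirical
  all-vs-all score distributions — with planted anchors scoring uniform
  in [0.8, 1]. The generator makes no attempt to mimic real score
  correlations between cavities of homologous proteins.
- **Ligand sets**: a universe of 100 scaffold bit-patterns (100 of 1024
  bits, 8 bits flipped per molecule) from which sets draw uniformly;
  planted pairs draw 90% of their ligands from one shared scaffold.
  Scaffold collisions give random set pairs a Poisson-like, right-skewed
  raw-score background — the feature the calibration needs — but no real
  chemistry (ring systems, physicochemical similarity) is modeled.
- **Toy metabolic models**: identical stoichiometry and GPRs, bounds-only
  differences, a redundant two-gene glycolysis-like pathway whose joint
  loss collapses cancer biomass while a gene-free bypass (open only in
  the healthy bounds) protects the healthy model, plus four labeled
  hallmark exchanges with different constrained maxima in the two
  models. The planted contrast is structural, holding for every seed;
  the rng only jitters non-limiting sink capacities.

Passing tests on these generators therefore demonstrate that each
algorithm recovers the structure it is designed to detect under its own
statistical assumptions — not that those assumptions hold in any
particular real dataset.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale by design:
interactomes of 100–200 nodes, 10,000 randomizations for percolation and
influence backgrounds, 10,000 background Z samples (1,000 per size cell
over six set-size cells) for the SEA calibration, brute-force oracles on
graphs of ≤ 12 nodes and cavity instances of ≤ 10 proteins, and toy
metabolic models with 10 reactions. These sizes are where the exhaustive
oracles are tractable and the statistical tolerances (|mean Z| ≤ 0.05,
SD within 5%) are comfortably within sampling error. All randomness
flows through `numpy.random.default_rng` seeds; every generator is
reproducible bit-for-bit under a fixed seed, and the acceptance script
derives all stage seeds from its single `--seed` argument.

## Known limitations

- Group enumeration is exponential in anchor neighborhood size; it is
  intended for use after restriction to a specific network.
- The influence matrix is dense (O(n²) memory, O(n³) inversion); the
  implementation targets therapy/tumor subnetworks (tens to hundreds of
  nodes), not the full interactome.
- The uniform (non-degree-matched) random backgrounds make influence
  Z-scores of hub-containing groups generous; degree-matched sampling
  would be the conservative alternative.
- E-values depend on the calibration universe; a calibration fitted on
  one compound library does not transfer to another.
- The LP layer handles models of toy-to-moderate size; genome-scale
  inputs are better served by dedicated solvers, for which the model
  JSON is easy to export.
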