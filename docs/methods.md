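# Methods

`shdelim` cross-checks species hypotheses (SHs) for DNA-barcode data — ITS-style
fungal barcodes are the motivating case — by running several delimitation models
over the same sequences and accepting a candidate species only when a majority
of methods return it as an exact cluster. This note records the models, the
parameter choices, the numerical decisions, and what the synthetic studies do
and do not demonstrate.

## Delimitation engines

**Greedy OTU clustering** (`shdelim.otu`). Sequences are processed in a fully
deterministic order (length descending, ties by id) and compared to existing
centroids by global-alignment identity. A query joins the *best*-matching
centroid if that identity reaches the threshold (ties to the earliest-created
centroid), otherwise founds a new centroid; centroids are static seeds and are
never re-elected. Identity is matches / alignment columns with terminal-gap
columns excluded, so internal indels count against identity; the alignment uses
match +2, mismatch −4, gap open 10, gap extend 1 (all configurable — published
SH counts from other tools are sensitive to these undocumented knobs, so they
are explicit here). Default thresholds: 0.97 and 0.985.

**ASAP-style hierarchical partitioning** (`shdelim.asap`). Single-linkage
agglomeration of the pairwise-distance matrix yields a nested chain of
candidate partitions, one per distinct merge height; the all-singleton
partition opens the chain unless duplicate sequences already merged at height
zero. Each candidate gets two scores:

* `p_panmixia` — how improbably small the mean within-group distance is under
  random regrouping at fixed group sizes. The observed mean is compared to the
  permutation null (999 seeded permutations) and converted to a left-tail
  normal probability of the effect size *scaled by the spread of all pairwise
  distances*. Two alternatives were rejected during development: the raw
  empirical fraction saturates at 1/(n_perm+1) and cannot rank candidate
  partitions that are all beyond the permutation floor, and scaling by the
  standard error of the permuted mean rewards merging closely related species
  because the SE shrinks with the within-pair count.
* `W` — the relative barcode-gap width (d_{k+1} − d_k)/d_{k+1} between the
  candidate's merge height and the next one (0 for the last candidate). A
  candidate formed at merge height exactly 0 receives W = 0: duplicate
  sequences would otherwise manufacture a maximal relative gap regardless of
  any structure in the data.

Both scores are ranked across candidates (average ranks on ties) and the
composite score is the mean rank; the lowest score wins, ties resolved toward
fewer clusters. This score is this package's own surrogate for the original
ASAP probability; any faithful reimplementation of that score can be swapped
in behind the same interface.

**Single-threshold GMYC** (`shdelim.gmyc`). On an ultrametric tree, a
threshold height T separates a species-level pure-birth process (nodes older
than T) from independent within-species coalescents (nodes younger than T).
For each inter-event waiting interval i of duration x_i,

    b_i = λ_spec · k_i^p_spec + λ_coal · Σ_j (n_ij (n_ij − 1))^p_coal
    log L = Σ_i (ln b_i − b_i x_i)

with k_i the species-level lineages crossing the interval and n_ij the
lineages inside cluster j. Exponents default to 1 (pure Yule/Kingman) and can
be optimized. Candidate thresholds are midpoints between consecutive distinct
branching times plus one position above the root, which reduces the model to
the single-process (all-coalescent) null; rates are maximized per candidate by
bounded quasi-Newton in log-rate space from three log-spaced deterministic
starts. The LR statistic 2(logL_alt − logL_null) is referred to χ² with 2 df
by default (3 df selectable — the appropriate df for this nonstandard mixture
test is genuinely unclear). Entities are the maximal clades whose stem crosses
the fitted threshold; tips crossing alone are singletons. Polytomies are
accepted; a multifurcation contributes a single shared waiting interval.

Calibration caveat: on single-species coalescent trees the LR test is
anticonservative (≈25–40% rejection at α=0.05 in our simulations, matching
reports about this class of test in the delimitation literature), because the
threshold is profiled by maximum likelihood over ~n candidate positions.
Entity counts, not p-values, are the quantity consumed by the consensus.

**PTP** (`shdelim.ptp`). On a phylogram, a delimitation is an antichain of
species-root nodes whose subtrees tile the tips. Edges strictly inside a
species subtree form the coalescent class, all other edges the speciation
class (the root edge belongs to neither); each class is modelled as iid
exponential branch lengths, with analytic rate MLEs (count/sum), so each
delimitation has a closed-form likelihood. ML search: steepest-ascent hill
climbing over single split/merge moves with 25 restarts (the one-species and
all-singleton extremes plus seeded random antichains); on trees of ≤6 tips it
matches exhaustive antichain enumeration. Bayesian mode: Metropolis–Hastings
over antichains with a uniform prior, single-move proposals and a Hastings
correction for the changing move count; per-species support is the post-burn-in
sampling frequency of the exact tip set, and the reported delimitation is the
modal one. When both modes are run, the result with fewer SHs is adopted
(ties → Bayesian, which carries support values) to avoid excessive species
division. One coalescent rate is shared across species (the simpler PTP
variant).

Known bias: PTP oversplits species with visible within-species coalescent
structure. Coalescent branch lengths are overdispersed relative to an
exponential — most within-species edges are very short while the deepest are
many times the mean — and moving a species' two deepest edges into the sparse
speciation class often raises the likelihood (we measured gains up to ~16 log
units over the true partition on strong-gap data). Under its own generative
model (iid exponential classes) the ML search recovers the truth essentially
always, so this is a property of the model, not of the search.

**Consensus** (`shdelim.consensus`). All methods reduce to a partition of the
same sequence ids. A candidate species is *supported* by a method when its tip
set equals one of that method's clusters exactly (a lenient mode accepting
unions of whole clusters exists behind a flag for explicit expert overrides).
The majority rule accepts a candidate when its support strictly exceeds the
cutoff (default 4, i.e. ≥5 of 7 methods). Candidates default to the clusters
of a designated reference method; in a real study they come from
morphology/phylogeny and are supplied externally.

## Synthetic data generator

`shdelim.simulate` chains three stages, all seeded from one master seed via
independent sub-streams (`numpy.random.SeedSequence`), so runs are exactly
reproducible and enlarging one stage does not perturb another:

1. **Species tree** — pure-birth (Yule) process written directly: with k
   lineages wait Exp(λk), split a uniform lineage, and after the n-th lineage
   appears wait a final Exp(λn); this makes E[root height] = Σ_{k=2..n} 1/(λk),
   the closed form the tests check.
2. **Gene tree** — multispecies coalescent via msprime: each species is one
   haploid population with coalescent scale θ (a pair coalesces in mean θ;
   E[TMRCA of k tips] = 2θ(1 − 1/k)), ancestral populations merging at the
   species-tree split times.
3. **Sequences** — Jukes–Cantor evolution along the gene tree with exact
   transition probabilities (substitution probability (3/4)(1 − e^{−4μt/3}) per
   site, substituted sites uniform over the other three bases). Simulating
   under JC69 makes the package's JC69 distance correction exact in
   expectation, which the closed-form tests exploit.

The **strong-gap preset** (5 species × 8 tips, 500 bp, λ=1, θ=0.005, μ=0.05)
emulates a barcode dataset with an unambiguous barcode gap. Because a Yule
tree can place a split arbitrarily close to the present, the species tree is
conditioned (seeded rejection sampling) on a minimum divergence depth of 0.6,
which bounds the smallest between-species JC distance near 2·0.6·0.05 = 0.06
(identity ≈ 0.94). θ=0.005 keeps essentially every within-species pair above
99.5% identity; the bound must hold per pair, so it is set from the tail of
the within-species TMRCA distribution, not its mean. What the preset does
*not* emulate: indels and alignment error, rate heterogeneity across sites
and lineages, ambiguous base calls, contamination/misidentification, and
uneven sampling — so passing recovery tests show the engines work where a
clean barcode gap exists, not that they resolve hard real-world cases.

## Numerical and degenerate-input choices

* Distances use pairwise deletion by default (complete deletion available);
  ambiguity codes are non-comparable rather than fractional matches. JC69 at
  p ≥ 0.75 raises a saturation error instead of capping.
* Coordinates are 0-based half-open everywhere; converters from 1-based
  inclusive (as printed in tables) sit at the I/O boundary. Residues are
  upper-cased on read and U→T.
* Site statistics ignore gaps/ambiguity when classifying a column by default;
  a gap-as-state policy is switchable since "variable site" conventions differ.
* Ultrametricity tolerance is relative (1e-3 of tree height) because
  externally estimated chronograms carry rounding.
* GMYC candidate evaluation is deterministic (no RNG anywhere in the fit);
  ASAP permutations, PTP restarts and MCMC all consume explicit seeds recorded
  in output metadata.
* All-singleton and single-cluster partitions get p_panmixia = 1 (no
  within-group evidence either way).
* Problem sizes used by the shipped studies — 25–50 replicates of the 40-tip
  preset, 20k-generation PTP chains, 100–200 null replicates for the GMYC
  calibration check — were chosen so the whole study reruns in minutes on one
  core while keeping Monte-Carlo error well below the effect sizes of
  interest.

## Known limitations

* The ASAP composite score is a surrogate; it reproduces the *behaviour*
  (barcode-gap seeking, oversplit/overmerge resistance) rather than the
  original score's numerical values.
* The GMYC LR p-value should not be taken at face value (see calibration
  caveat); use entity counts within a consensus, as this pipeline does.
* PTP oversplitting under deep within-species coalescence is inherent to its
  branch-length model; the majority-rule consensus is the mitigation.
* Tree inference is out of scope: GMYC consumes an externally estimated
  ultrametric tree and PTP a phylogram. The built-in UPGMA exists for tests
  and quick looks, not for publication-grade trees.
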