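# Methods

## The model

`drugnet` treats drug safety as a binary classification problem over
network-topology features of a drug's protein targets. The premise:
proteins whose sequences resemble many others (shared, widespread
domains) occupy hub positions in a protein similarity network (PSIN), and
modulating them perturbs many related proteins at once — a regime in
which drugs tend to be withdrawn or abandoned. Peripheral proteins with
rare domains are safer targets. The pipeline quantifies this with four
node measures, aggregates them per drug, and trains a heterogeneous
ensemble whose mean problematic-probability is the drug's Rejection
Score (RS).

### Network construction

A similarity search is not symmetric: a profile search from protein A may
retrieve B without the reverse holding. The PSIN therefore links A and B
only when both directed hits pass the e-value threshold (default 1e-3,
the same cut-off the upstream search uses; `BlastParams` records the full
provenance — BLOSUM matrix, gap open 11 / extend 1, inclusion threshold
1e-5, at most six profile iterations — but the package never runs the
search itself). Duplicate directed hits keep the minimum e-value; only
presence matters for the bidirectional rule. When a node universe (e.g. a
proteome id list) is supplied, proteins without any bidirectional hit are
kept as singletons; centralities that are undefined for isolated nodes
(closeness, constraint) are recorded as missing and flow into the
imputation step.

### Centralities

* **Degree** — neighbour count.
* **Betweenness** — `B(v) = Σ s_ij(v)/s_ij` over unordered pairs
  `{i,j}`, unnormalised; pairs in other components contribute 0.
* **Closeness** — default `r / Σ d(v,u)` over the `r` nodes reachable
  from `v` (inverse mean distance), which stays well defined on a network
  with hundreds of components; an inverse-total-distance variant
  (`1/Σd`) is a switch. The exact normalisation behind the integer-scale
  closeness values reported for the real networks is not recoverable, so
  no attempt is made to match those numbers.
* **Burt's constraint** — `C(i) = Σ_j (p_ij + Σ_q p_iq p_qj)²` with the
  unweighted proportional tie strength `p_ij = 1/deg(i)`, the standard
  specialisation for an unweighted graph. A leaf has constraint 1; a star
  centre with k leaves, 1/k; a node of `K_n`, `(2n−3)²/(n−1)³`. Low
  constraint marks brokers across structural holes.

networkx provides the graph container and the centrality kernels
(`betweenness_centrality(normalized=False)`,
`closeness_centrality`-equivalent BFS sums, `constraint`); the test suite
checks all of them against independent brute-force path-enumeration
oracles and the closed forms above, on hundreds of random graphs.

The **danger zone** flags use strict inequalities with defaults
PSIN degree > 110 & constraint < 0.025, PPI degree > 11 & constraint
< 0.1 — the empirically optimal separation points between targets of
problematic and approved drugs. A protein missing from a network has a
missing flag; a protein with no constraint value (isolated) cannot be in
the zone.

### Features

Per drug, each centrality is averaged over its targets. PSIN measures are
first log10-transformed: `log10(x+1)` for degree and betweenness (count-
like, may be 0), `log10(x)` for closeness and constraint (strictly
positive when defined). PPI measures are averaged on the raw scale by
default (a flag log-transforms them too). Targets lacking a value drop
out of that feature's mean; a drug-level feature with no contributing
target is missing. Missing entries are filled with the feature mean
*within* the training or test matrix separately; min-max scaling to
[0, 1] is fitted on training data only and applied with clipping to test
data (a deliberate leakage guard; a constant feature maps to 0.5).
Imputation happens at the drug level, after aggregation — missingness is
a property of where a drug's targets sit in the networks.

### Imbalance cascade

Training data are roughly 4:1 approved:problematic and the classes
overlap. Applied to the training split only, in order:

1. **SMOTE** (500 %, k = 8): each synthetic minority point is
   `x + u(nn − x)`, `u ~ U(0,1)`, `nn` uniform among x's k nearest
   minority neighbours.
2. **Tomek links**: opposite-class mutual nearest neighbours; both
   members are removed (the cleaning variant of the SMOTE+Tomek recipe;
   one-sided removal is a config option). Ties in nearest-neighbour
   distance break toward the lowest index.
3. **Border removal**: an instance that is the nearest neighbour of at
   least `border_threshold` (default 2 — the smallest reading of
   "several") opposite-class instances is dropped.
4. **Misclassification filter**: a small multilayer perceptron is fitted
   on the training set and instances it misclassifies are dropped; the
   filter is then discarded. If it fails to fit, the step warns and
   passes data through (strict mode errors instead).

Each cleaning step is evaluated once on its input (single pass). A step
that would eliminate an entire class — possible on heavily overlapping or
label-shuffled data — is skipped for that split and noted in the report,
since the classifiers downstream require both classes. Distances are
Euclidean on the scaled feature space. Preprocessing never touches the
test split, so no synthetic instance can leak into evaluation.

### Ensemble and evaluation

Three default classifier families, chosen for heterogeneity of principle
and all probabilistic: a distance-weighted k-nearest-neighbour learner, a
single-hidden-layer feed-forward network, and a rotation ensemble of
decision trees (per tree, the features are randomly partitioned into
small subsets, each rotated onto the principal axes of a bootstrap
sample; the block-diagonal rotation decorrelates trees without discarding
information). The registry accepts any sklearn-style factory, so wider
classifier comparisons plug in without code changes. RS = arithmetic mean
of the three problematic-probabilities.

Evaluation: stratified 70/30 split; any training drug whose target set
exactly equals a test drug's is removed (identical target sets mean
identical features — this prevents disguised train/test overlap); drugs
with identical target sets but conflicting labels are removed entirely
beforehand. AUC uses the Mann–Whitney rank formulation with ties counting
½, positive class = problematic. The whole loop is repeated (default
100; pipeline-level tests and the bundled study use 20 repeats to keep a
single-CPU run in minutes) with per-repeat seeds derived from a master
seed.

### Null models

* **Label/target shuffle** — labels permuted across drugs (class counts
  exact; status and failure reason travel with the label), target sets
  replaced by uniform same-size draws from the pooled target universe.
  One subtlety: a *single* fixed shuffle evaluated over many splits
  retains its chance label–feature correlations, which the classifiers
  partially re-learn (measured mean AUC ≈ 0.54 for one shuffle).
  Chance-level calibration is therefore estimated with a fresh shuffle
  per evaluation round, which is unbiased (measured mean 0.500,
  sd ≈ 0.055 per round).
* **Paired null panels** — a panel of shuffled datasets (default 40) is
  fixed; per round, one split of the standard data fixes a drug-id
  partition applied identically to every panel member. The exceedance is
  the fraction of paired comparisons the standard data wins (ties ½).
* **Network-identity shuffle** — node ids permuted on the same graph,
  preserving every topological invariant while destroying protein
  identity.
* **Neighbour targeting** — for drugs with ≥ 2 in-network targets, a 2×2
  table of (targets an adjacent pair? yes/no) against a null where each
  target is replaced by a uniform draw from its powers-of-two degree bin
  (a degree-preserving randomisation), tested with Fisher's exact test.
  The contingency construction is one reasonable interpretation of an
  under-specified design; the degree-binned null is documented as such.

### Failure-reason ablation and candidate scoring

Problematic drugs carry one of ten failure-reason categories (a single
primary reason per drug; real curation can be multi-label, which the
format does not attempt to represent). Ablation removes one group at a
time and re-runs the evaluation; removing a group that harbours label
noise (problematic-labelled drugs with approved-like targets, e.g. drugs
withdrawn despite sharing targets with approved drugs) raises the AUC.
Candidate scoring is leave-matching-targets-out: the training set
excludes every reference drug with the candidate's exact target set, and
by default the "withdrawn" group, the configuration found to classify
best; candidates are imputed with training means and scaled with training
bounds.

## Synthetic data

The generator's defaults are the study conditions: a 1000-protein
similarity network of 4 preferential-attachment components (3 edges per
new node — heavy-tailed degrees; exact power-law exponent matching is out
of scope), 400 approved + 100 problematic drugs (the real corpus is 1445
: 357 ≈ 4:1), problematic target draws ∝ degree², approved draws uniform
below the 0.9 degree quantile, target counts 1 + Poisson(2.5) for
approved vs 1 + Poisson(0.3) for problematic (approved drugs accumulate
reported targets; problematic ones usually have a single known target).
`label_noise` keeps class counts exact while a noise fraction of each
class draws targets from the other class's distribution; noisy
problematic drugs carry a designated failure reason so ablation has a
planted mechanism. The BLAST fixture emits both directed rows per edge
plus one-directional decoys and above-threshold rows over non-edges, so
parse→build reconstructs the generating network exactly.

What the synthetic data does **not** emulate: real sequence content,
domain architecture, correlated PSIN/PPI structure (the synthetic PPI is
an independent topology over a node subset), multi-database target
provenance, IC50 distributions, or multi-reason failures. Passing tests
demonstrate that the machinery is correct and that the pipeline recovers
a planted topology–safety association and calibrates to chance under
permutation — not that the association holds in any particular real
corpus.

## Numerical choices and degenerate inputs

* Strict inequalities throughout the danger zone and the IC50 filter
  (< 30 nM).
* Closeness/constraint of isolated nodes are missing, degree 0,
  betweenness 0.
* SMOTE requires more than k minority instances; splits require ≥ 2
  drugs per class; training requires both classes.
* Nearest-neighbour ties break toward the lowest instance index; AUC
  ties count ½; a constant feature scales to 0.5.
* All stochastic components (splits, SMOTE, neural nets, rotation
  ensembles, shuffles, generators) take explicit seeds; per-repeat seeds
  derive from a master seed via a seeded generator, so every reported
  number is reproducible bit-for-bit given the seed.

## Known limitations

Exact betweenness is O(nm) per network — fine at synthetic scale,
pedestrian for a ~17k-node, ~1.7M-edge network (hours, not days; no
approximation is provided by design). The misclassification filter and
neural-net component are the only steps whose behaviour depends on
optimiser convergence; both are small networks with fixed seeds. The RS
summary table uses the `RS ≥ cutoff` convention (cumulative from the
top); cumulative-from-below conventions in published tables can disagree
with in-text percentages, and this package standardises on the former.
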