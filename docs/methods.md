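# Methods

## The model

`simrepo` predicts drug-disease treatment associations under the
guilt-by-association premise: drugs similar to a drug known to treat a
disease similar to the query disease are themselves likely treatments.  The
evidence is organized as seven similarity kernels, four over drugs and three
over diseases, each a symmetric matrix with values in [0, 1]:

| kernel | entities | signal | measure |
|--------|----------|--------|---------|
| drChe  | drugs    | chemical structure (binary fingerprints) | Tanimoto |
| drSE   | drugs    | side-effect term sets | Jaccard |
| drTar  | drugs    | target protein sequences | normalized Smith-Waterman, max over target pairs |
| drGO   | drugs    | GO annotations of drug-related genes | Resnik + BMA |
| diGO   | diseases | GO annotations of disease-related genes | Resnik + BMA |
| diHPO  | diseases | direct HPO phenotype terms | Resnik + BMA |
| diPhe  | diseases | precomputed phenotypic similarity | ingested matrix |

A query pair (drug *i*, disease *i′*) is represented by comparing it with
every known association (*j*, *j′*): each drug kernel is combined with each
disease kernel by the geometric mean

&nbsp;&nbsp;&nbsp;&nbsp;F = sqrt( S_dr(i, j) · S_di(i′, j′) ),

giving 12 values per known association (4 × 3 Cartesian product, ordered
drug-kernel-major: drChe, drSE, drGO, drTar crossed with diGO, diHPO,
diPhe).  Each of the 12 indices is aggregated across the known association
set by **max** (default — distance to the nearest known association) or
**mean** (overall similarity to the known set).  The geometric mean requires
a common [0, 1] scale, which motivates two normalizations that are genuinely
open choices (see below).

The 12-feature vectors feed binary classifiers — logistic regression, SVM
(linear, RBF, quadratic, cubic) and random forest — trained on gold-standard
positives against randomly under-sampled negatives at a 1:2
positive:negative ratio, repeated over independent trials (default 30), each
trial evaluated by stratified 10-fold cross-validation on six metrics
(accuracy, AUC, AUPR, sensitivity, specificity, precision).  Novel
indication candidates are non-gold pairs predicted positive in **all**
trials, ranked by mean predicted probability.

## Normalization choices

* **Smith-Waterman.**  Raw local-alignment scores are unbounded, so target
  similarity uses geometric self-score normalization
  SW(p,q) / sqrt(SW(p,p)·SW(q,q)), which is 1 for identical sequences and
  lies in [0, 1].  Scoring defaults to BLOSUM62 with affine gaps (open −10,
  extend −1; a gap of length L costs open + (L−1)·extend).  Both the matrix
  and the penalties are configurable through `AlignmentScoring`.
* **Resnik.**  Raw Resnik similarity (the information content of the most
  informative common ancestor) is unbounded; it is divided by the corpus
  maximum IC so term similarity lies in [0, 1] and the max-IC term has
  self-similarity 1.  IC uses the natural log of the annotation frequency,
  with counts propagated through the is_a ancestor closure (an annotated
  entity counts once per closure term, so IC(root) = 0 always).  Only is_a
  edges are used; obsolete terms are dropped at parse time.
* **Entity-level semantic similarity.**  For multi-gene entities all genes'
  terms are pooled into one set and a single best-match average is taken
  over pairwise Resnik values.  Pooling is deterministic and order-free;
  per-gene-pair BMA is a plausible alternative the package does not
  implement.
* **HPO information content.**  GO IC comes from the gene→GO annotation
  corpus; for HPO the corpus is the disease→HPO table itself, each disease
  acting as one annotated entity.  This keeps both semantic kernels on the
  same corpus-frequency footing without requiring a gene→HPO resource.
* **Conventions.**  Jaccard of two empty sets and Tanimoto of two all-zero
  fingerprints are 0 (absence of evidence, not similarity).  Entity
  self-similarity is fixed at 1 on every kernel diagonal where the entity
  has the property at all.

## Undefined values and completeness

A drug without targets, or an entity whose term set is empty or entirely
outside the ontology, has no defined value under the affected kernel; such
entries are stored as NaN, never imputed.  During feature construction a
known association with an undefined kernel value is skipped for that feature
index only; a query pair left with no defined value on some index is dropped
with a logged reason.  The gold-standard completeness filter removes drugs
missing a fingerprint or side effects and diseases missing genes or (for the
training set only) lacking any surviving association; an external test set
keeps unassociated diseases since only the kernel inputs are needed there.

## Leakage

A labelled positive compared against the full gold set trivially matches its
own entry and every max-aggregated feature saturates at 1.  Training and
cross-validation therefore exclude each pair's own gold entry before
aggregation (`leakage_mode="train"`); prediction on unseen pairs never
excludes (`leakage_mode="predict"`).  The saturated literal reading remains
available via the `exclude_self` flag for comparison.

## Negative sampling

Negatives are drawn uniformly without replacement from the drug × disease
product minus a barred set.  The default barred set is the gold positives —
faithful to the real-data setting, where unknown true associations
inevitably contaminate sampled negatives.  `cross_validate` accepts a wider
`negative_exclude` set for simulation studies: when the generator's withheld
within-cluster positives are left in the candidate space they act as
mislabeled negatives and cap the measurable CV AUC (≈0.97 at the reference
conditions) regardless of property noise; excluding the full simulated truth
removes that cap, which is the appropriate design when the quantity of
interest is recovery of a known generative structure.

## The synthetic generator

Because the original data sources are licensed or versioned external
databases, all testing runs on synthetic data whose generative model encodes
the method's premise directly.  Each of `n_clusters` clusters owns a
prototype fingerprint (uniform random bits), side-effect set, target protein
sequence, gene subset and one GO and one HPO subtree (depth 3, branching 2,
under a shared root, giving controllable Resnik separation between
clusters).  Cluster members copy the prototype with independent per-element
corruption at rate `noise`: fingerprint bits flip, set elements and residues
are replaced by uniform draws from the global pool.  Associations connect
same-cluster drugs and diseases; 20% of within-cluster pairs are withheld
from the gold standard as a disjoint external-validation set.  The phenotype
matrix is a block matrix (0.9 within cluster, 0.1 between, diagonal 1) with
symmetric uniform jitter of ±noise/2, clamped to [0, 1].

Reference conditions used by the tests and the acceptance script: 4 clusters
of 5 drugs × 5 diseases (20 drugs, 20 diseases, 80 gold and 20 withheld
associations), fingerprint length 1021, one 60-residue target per drug,
noise 0.05.  Cross-validation in the test and acceptance runs uses 1–5
under-sampling trials rather than the production default of 30; at these
problem sizes the per-trial variance is small and the aggregate means are
stable to well under the asserted margins.

What the generator does *not* emulate: realistic fingerprint sparsity and
substructure correlation, hub drugs with many targets, the scale-free
incompleteness of real annotation databases, inter-cluster relatedness
gradients, or any herbal-compound-specific chemistry.  Passing recovery
tests therefore demonstrate internal consistency of the pipeline — that
cluster-coherent signal present in the inputs is carried through kernels,
features and classifiers — not expected performance on real databases.

A consequence of the deliberate redundancy of seven kernels is that
moderate property noise barely moves cross-validated performance: at the
reference conditions the task remains fully separable at noise 0.4, because
replacement corruption retains 60% of each prototype set and the phenotype
block matrix is only jittered, never destroyed.  Degradation is therefore
monotone but flat between noise 0.05 and 0.4; single-kernel ablations (the
`corrupt` operation at rate 1) are the sharper instrument for studying the
contribution of one property.

## Numerical and procedural details

* Decision threshold 0.5 for the thresholded metrics; AUC uses the
  Mann-Whitney tie convention (ties count 1/2); AUPR is the step-wise
  average-precision form.  Precision is 0 when nothing is predicted
  positive.
* Stratified folds preserve the 1:2 class ratio; folds missing a class are
  skipped with a warning.
* Hyperparameters: random forest 500 trees; SVM C = 1, RBF/poly gamma =
  1/(n_features · Var(X)); logistic regression with L2 default.  All exposed
  through `TrialConfig`.
* The master seed spawns per-trial seeds as seed + trial index; every
  stochastic step (negative sampling, fold shuffling, forest construction)
  derives from them, making full runs byte-reproducible.
* Consensus rule for novel candidates: positive in all trials.  Support
  counts are retained in the output so majority-vote variants can be
  analyzed after the fact.

## Known limitations

* Smith-Waterman runs exact dynamic programming (via Biopython's pairwise
  aligner); no heuristic seeding, so all-vs-all target comparison scales
  quadratically in total target count.
* Only is_a ontology edges are honored; part_of and regulates relations are
  ignored.
* GO sub-ontologies are not separated unless the input annotations are;
  cross-namespace term pairs with no common ancestor are skipped inside the
  best-match average.
* No hyperparameter search, probability calibration, or learned kernel
  weighting.
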