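# Methods

## Data model

A compound library is a CSV with a `compound_id`, a `smiles`, up to 10
binary attribute label columns and an optional `toxic` flag.  Labels are
1 (active), 0 (inactive) or blank (inconclusive/unlabeled); blanks are
carried as missing and dropped per attribute at training time, so a
compound with one inconclusive assay still contributes to the other
attributes.  An attribute schema names each attribute, routes it to a
model path (`tabular` or `graph`) and assigns its screening role;
exactly one attribute is the BBB gate.

Structures that fail to parse are excluded and logged
(`parse_failure`).  "Salt" is operationalized as any SMILES whose parsed
structure has more than one disconnected fragment; with
`exclude_salts=true` (the default) such records are excluded and logged
(`multi_fragment_salt`).  Survivors plus exclusions always partition the
input exactly.  Duplicate compound identifiers are an error at read
time, never silently deduplicated.

## Descriptor panel (tabular path)

Twelve descriptors: monoisotopic exact mass (Da), Crippen
atom-contribution LogP, Ertl fragment-contribution TPSA, Lipinski-style
H-bond donor (N/O bearing ≥ 1 H) and acceptor (N/O) counts, rotatable
bonds, sp³ carbon fraction (defined as 0 for carbon-free molecules),
aromatic ring count, Gasteiger (iterative partial equalization of
orbital electronegativity) maximum and minimum partial charge (e), and
nitrogen/oxygen atom counts.  When the charge scheme yields non-finite
values (exotic atoms), 0.0 is imputed and the event logged, so the
feature matrix never carries silent NaNs.  Mass and all counting
descriptors are verified in the test suite against brute-force
enumeration over the parsed atom list; LogP/TPSA are delegated to the
cheminformatics toolkit as the conventional realizations of those named
schemes.

## Molecular graphs (graph path)

Heavy atoms only, hydrogens implicit.  Feature widths are fixed at 30
per atom and 11 per bond; the concrete layout is this package's dialect:

* atom (30): element one-hot {C,N,O,F,P,S,Cl,Br,I,other} (10) | degree
  0–5 (6) | total H count 0–4 (5) | hybridization {sp,sp²,sp³,other}
  (4) | formal charge | aromatic flag | in-ring flag | radical electron
  count | chirality-specified flag.
* bond (11): type {single,double,triple,aromatic} (4) | conjugated |
  in-ring | stereo {none,Z,E,cis,trans} (5).

Values outside a one-hot range leave the block all-zero, so each block
sums to ≤ 1.  Elements outside the alphabet map to the `other` slot
(logged, never an error).  Edges are stored once as unordered pairs and
expanded to both directions inside the network.

## Models

**Tabular network.**  Feed-forward ReLU network (default hidden sizes
200/100) with batch-norm and optional dropout on descriptors
standardized with training-fold statistics only, Adam, minibatch 64,
early stopping on validation F1 (patience 20, internal stratified 20%
holdout).  Loss is plain cross-entropy or the focal loss.

**Graph network.**  Kipf-style graph convolution,
H′ = ReLU(Â H W + b) with Â = D^(−1/2)(A+I)D^(−1/2) over the bidirected
edge set, default two layers of width 64, mean-pool readout over atom
embeddings, dense logistic head, full-batch Adam with the same early
stopping scheme.  A whole training set is packed into one
block-diagonal sparse Â plus a mean-pooling operator, which makes the
forward pass directly checkable by hand arithmetic and keeps training
fast.  Bond features are retained in the graph format but not consumed
by this network family (its propagation is node-based); they are there
for extension.  Mean pooling and the symmetric propagation make
predictions invariant to atom relabeling (asserted to 1e-6) and to
duplicating a graph within a batch.

Both paths emit probabilities in (0, 1); the decision threshold defaults
to 0.5 everywhere and is configurable per model.  Training is
bit-reproducible under a fixed seed when run single-threaded; the
`training_fingerprint` (SHA-256 over config, seed and weights) makes
this testable.

**Focal loss convention.**  FL = −α_t (1−p_t)^γ log p_t with α_t = α for
positives and 1 for negatives, p clamped to [1e-7, 1−1e-7].  This keeps
the γ=0, α=1 case *exactly* equal to binary cross-entropy, which the
suite asserts to 1e-9 on a 1000-point grid; the variant that weights
negatives by 1−α cannot satisfy that identity.  γ and α are exposed as
configuration, not hard-coded.

**Imbalance remediation.**  SMOTE synthesizes p + λ(q−p) for a minority
point p, one of its k nearest minority neighbors q and λ ~ U[0,1];
ADASYN allocates synthesis across minority points proportionally to
hardness (fraction of majority among the k nearest neighbors in the
full data) with largest-remainder rounding, falling back to uniform
allocation when every hardness is zero (the original algorithm is
undefined there).  Neighbor metric is Euclidean on z-scored features.
Oversampling is applied to training folds only, after splitting —
applying it before the split would leak synthetic near-duplicates into
validation and test.  The graph path balances by random majority
downsampling instead, since interpolated feature vectors are not valid
molecular graphs.

**Cross-validation and search.**  Stratified k-fold (default 5) with
per-fold metrics; the reported fold is the one with the highest F1,
ties breaking toward the lowest index.  Hyperparameter search is seeded
random search over a declared space with a full trial log; model
selection by argmax of the objective.

## Screening

Funnel order is fixed: BBB gate → cumulative score ≥ threshold →
toxicity filter.  The cumulative score sums the *activity* attributes'
binarized predictions; the gate attribute is excluded from the sum by
default (a config switch includes it for the 10-attribute convention).
The score threshold defaults to 5 of 9 activity attributes.  Toxicity
is a user-supplied boolean column — toxicity triage is literature
curation, not an algorithm, so the toolkit only consumes the flag.
Hits are ranked by (score desc, mean activity probability desc,
compound_id asc), a deterministic total order.

**Applicability domain.**  Coverage of a query is its mean Euclidean
distance (z-scored by training statistics) to the k nearest training
points; in-domain means coverage at or below the 95th percentile of the
training set's own leave-one-out coverages.

**t-SNE.**  Exact-gradient O(n²) implementation: per-point Gaussian
bandwidths calibrated by bisection so that every row of the conditional
affinity matrix has perplexity 2^H(P_i) within 1e-3 of the target
(default 30); symmetrized affinities; Student-t output kernel; 1000
gradient-descent iterations with momentum 0.5→0.8, early exaggeration
×12 for the first 250 iterations, and the reference implementation's
adaptive per-coordinate gains with learning rate max(n/48, 50).  The
calibration is asserted as a postcondition, which is why the optimizer
is in-package rather than delegated.  Runs with n ≤ 3·perplexity warn
and shrink the perplexity to keep calibration feasible.

## Meta-analysis

Effects are pooled on the log scale (the only coherent scale for
ratio measures) with inverse-variance weights: pooled = Σwθ/Σw,
w = 1/se², pooled SE = (Σw)^(−1/2), 95% CI = exp(pooled ± 1.96·SE).
Cochran's Q = Σw(θ−pooled)² and I² = max(0, (Q−df)/Q)·100.  The
Cochrane heterogeneity bands overlap by construction (minor ≤ 40%,
moderate 30–60%, substantial 50–90%, considerable > 75%), so the
classifier reports *every* band containing the observed I².  The Egger
test regresses standardized effects θ/se on precision 1/se; the
intercept, its OLS standard error and a two-sided t-test with k−2
degrees of freedom are returned; it requires k ≥ 3 and non-degenerate
precision variance.  Random-effects pooling is intentionally out of
scope: the pooling model here is common-effect.  Study tables may give
(log_effect, se) directly or (effect, ci_low, ci_high), from which
se = (log ci_high − log ci_low)/(2·1.96).

## Synthetic fixtures and what they show

Generators sample from a fixed enumerated vocabulary (ring scaffolds ×
substituents, ~700 canonical single-fragment SMILES, of which 300+
contain an aromatic nitrogen and 390+ do not) rather than generative
SMILES sampling: every molecule is valid and substructure truth is
exact.

* **Tabular benchmark** (default n = 2000): labels are Bernoulli draws
  from a logistic model on z-scored descriptors, then flipped with rate
  0.05.  Default coefficients are +3 on LogP and −3 on TPSA — a strong,
  physically sensible permeability-like rule.  The intercept is
  calibrated by bisection so the expected post-flip positive fraction
  equals the requested minority fraction (default 0.2).  Recovery is
  scored as held-out AUC against the persisted pre-flip labels: because
  labels are Bernoulli draws plus flips, the Bayes-optimal score itself
  has an AUC ceiling of roughly 0.86–0.89 against *noisy* labels at
  these settings, so noisy-label AUC would measure noise, not recovery.
  Against clean labels the Bayes ceiling is ≈ 0.97 and the tabular
  model is expected to reach ≥ 0.90.
* **Graph benchmark** (default n = 500): labels are a registered
  substructure predicate (default: contains an aromatic nitrogen) XOR
  5% flips.  Tabular truth is planted on descriptors and graph truth on
  substructure deliberately, so each path's recovery is well-posed on
  its own route.
* **Screening fixture**: per-compound gate/activity/toxicity bits are
  drawn at configured rates, probabilities are then drawn so that
  binarization at 0.5 reproduces the bits exactly (positives in
  (0.5, 1], negatives in [0, 0.5)), and the expected stage counts are
  brute-forced from the bits inside the generator; the engine must
  match them exactly.
* **Meta fixture**: θ_i ~ N(true, se_i²), se_i ~ U(0.05, 0.3); with
  k = 200 the pooled estimate is expected within 3 pooled SEs of truth.

What passing these fixtures does **not** show: robustness to real
bioassay label noise structure (correlated errors, assay batch
effects), to chemistry far outside the small vocabulary (the
applicability-domain machinery exists precisely because real screens
extrapolate), or to label rules that are neither descriptor-linear nor
single-substructure.

## Numerical choices

* AUC ties get half credit (trapezoid AUC ≡ normalized Mann–Whitney U,
  asserted against exhaustive pair counting); zero-denominator metrics
  report 0.0 with an explicit `undefined` flag instead of NaN.
* Stratified splits round per-class allocations to nearest and error if
  any class has fewer than 3 members or a part ends up single-class.
* Largest-remainder rounding breaks ties toward the lower index.
* The pipeline derives per-component seeds as
  (global_seed + SHA-256(tag)) mod 2³¹, so adding a stage never
  perturbs earlier stages' randomness; manifests fingerprint artifacts
  by content hash and models by their training fingerprint.
* Batch-norm batches of size 1 are skipped (statistics undefined);
  inference uses running statistics, so predictions are
  batch-independent.

## Limitations

* The neural implementations are deliberately compact (NumPy, CPU,
  single-threaded determinism); they are sized for panels of thousands
  of compounds, not millions.
* No SDF ingestion, tautomer/charge standardization, 3-D descriptors or
  fingerprints; stereochemistry enters only through the graph stereo
  flags.
* The hyperparameter search is random search by design; no TPE/Bayesian
  sampler.
* Multi-task heads are out of scope (per-attribute models only).
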