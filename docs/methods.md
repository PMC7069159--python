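# Methods

## Data model

A cohort is a samples × n matrix over a declared feature schema: binary
clinical codes (ICD9-CM categories truncated to their first three
alphanumeric characters; ATC codes truncated to level 4, i.e. the first
five characters), continuous age in whole years, and binary gender, with a
categorical class label per patient (a mutually exclusive health status
such as a base Clinical Risk Group).  Code columns are strictly
presence/absence: repeated diagnoses or dispensations of the same truncated
code collapse to a single 1.  An absent patient–code pair means 0 by
construction; a missing age or gender is an error, not imputed, because
presence semantics make absence meaningful for codes but not for
demographics.

Screening is two-stage: binary columns with a zero count over all patients
are discarded, then the k features (default k = 50) with the highest
information gain against the label are kept.  Gain is Shannon mutual
information in bits, H(y) − Σ_v p(v)H(y|v); for the ranking, age is first
binarized at its best gain-ratio cut-off (the same rule the tree uses) so
it competes with binary codes on a single scale.  Rank ties break by schema
order, which makes builds deterministic.

## Projection

LDA is fitted on standardized data: all features centered, continuous
features scaled to unit variance, binary features left as centered 0/1
(their scale is meaningful presence; scaling them would let rare codes blow
up, while not scaling age would let years dominate every vector length).
The axis-vector matrix V solves the symmetric-definite generalized
eigenproblem S_B v = λ(S_W + ridge·I)v with eigenvectors normalized to
vᵀ(S_W + ridge·I)v = 1, computed with `scipy.linalg.eigh`.  The ridge
defaults to 1e-3·tr(S_W)/n: deep tree nodes hold few samples and
near-constant binary columns, and S_W is routinely singular there.
Constant columns are dropped from the node-local fit and assigned zero axis
vectors, so a feature already split on upstream can never re-enter through
a singular fit.  Each axis is sign-fixed so its largest-magnitude
coefficient is positive (eigensolvers are sign-ambiguous; with this
convention "the vector points toward presence").  With two classes only
C − 1 = 1 discriminant direction exists; the second axis column is zero,
scoring uses the first axis only, and plots render a strip with small
seeded jitter.

The separating direction d̂(c) for class c is the unit vector from the
pooled centroid of all non-target projected samples (class centroids
weighted by class size) to the class-c centroid — one-vs-rest, which
matches how an analyst reads "separates this class from the rest" without
requiring interaction.  The per-feature score is |vᵢ · d̂(c)|, a product of
length and alignment; how analysts weigh length against orientation is
informal in practice, and this product form is the package's explicit
formalization.  The overall ranking takes each feature's maximum score over
target classes, ties again by schema order.  Coincident centroids admit no
separating direction; such a class is skipped in scoring and flagged as an
error when requested directly.

## Trees

Binary trees only.  Binary features split by presence (satisfied branch =
code present) and are never reused on a root-to-leaf path, where they are
constant anyway; age splits at `value < t` with t the midpoint between
consecutive sorted distinct values maximizing the gain ratio (information
gain over split entropy), ties to the smallest t, and may recur on a path
with different cut-offs.  A node becomes a leaf when purity ≥ `purity_stop`
(default 0.9), size < `min_node_size` (default max(10, 1% of the root)),
level = `max_depth` (default 14), one class remains, or no usable feature
exists.  The stopping defaults quantify the informal "most samples belong
to one class / just a few samples" judgment and are fully configurable;
training-set consistency (100% training accuracy on separable data) holds
with purity_stop = 1, min_node_size = 1 and unlimited depth.  Leaf class is
the majority, ties by class order.  The node set inherited from the
balanced root is used as-is — balancing happens once, before training, not
per node.

The selector is pluggable: `"auto"` takes the top-ranked usable feature —
an explicit surrogate for the method's native interactive protocol — while
a callback receives the ranked candidates, score table, projection and
class counts and returns the feature, which is how a human (or a scripted
policy, as in the tests) drives construction.  Every choice is recorded in
a build log.

Node fill color encodes the predominant class (default palette: brown
healthy, orange hypertension, purple diabetes, green both, blue
multi-condition), with lightness mapping linearly from purity ∈
[threshold, 1] onto [0.85, 0.35] in HLS space; purity below the
predominance threshold (default 0.5, the natural reading of "no clearly
predominant class") renders white.  Trees serialize to JSON (round-trip
identity) and export to Graphviz DOT with counts in square brackets, leaf
percentages, and the satisfied branch emitted first so it renders left.

## Evaluation

`trial_split` draws, per class, ⌊f·m⌋ training and ⌊(1−f)·m⌋ test samples
(m = minority-class size, f = 0.8 by default) without replacement and
disjointly; the floor is guarded with a 1e-9 epsilon against binary
round-off of fractions like 0.2·10.  Trial t of `run_trials` uses seed
`base_seed + t`, making the 50-trial protocol exactly reproducible.  Both
evaluation modes exist because the original protocol is ambiguous about
whether structure was re-learned per trial: passing a fixed tree evaluates
it on resampled balanced test sets; passing none rebuilds a tree per trial
with the automatic selector.  Accuracy is reported in percent; F1 is macro
(unweighted over classes) — with balanced test sets macro and weighted
averaging coincide in expectation; confusion matrices are row percentages,
and on balanced test sets accuracy equals the unweighted diagonal mean, an
identity asserted on every trial.

## Synthetic cohorts

Codes are independent Bernoulli given the class — the simplest structure
that exercises screening, projection, scoring, tree construction and
evaluation; correlated-code generation is out of scope.  Under-coding is a
separate per-(class, code) dropout applied after the presence draw, so the
effective rate is presence·(1 − dropout).  Age is Gaussian truncated at 0
and rounded to whole years (EHR extracts store whole years); calibration
checks therefore compare empirical moments against the truncated
distribution's implied mean and std (via `scipy.stats.truncnorm`), not the
untruncated parameters — for a mean of 26 and std of 15 the truncation
shifts the mean by about +1.4 years, far beyond sampling noise at the test
sizes.  Gender is a fair coin by default.

The default five-class spec carries the published per-class age parameters
— 26 (15), 54 (14), 49 (15), 62 (11), 66 (12) years — and class sizes
scaled to 2% of the originals with a floor of 100 per class (the smallest
class would otherwise have ~11 patients), keeping full pipelines in
seconds.  Presence rates encode the documented qualitative pattern: the
hypertension code '401' near-universal in hypertensive statuses but dropped
in ~25% of the single-condition hypertensive class, the diabetes code '250'
missing in ~15% of pure diabetics, healthy patients carrying chronic codes
at low but nonzero rates.  Exact per-class rates for every code are not
published anywhere and the remaining values are free parameters chosen once
as clinically plausible; the generator is a structural emulation, not a
reproduction of the private cohort, and results on it show the machinery is
correct under the assumed structure — not what the method would score on
real claims data, where codes co-occur, classes drift and coding practices
vary by site.

A separate three-class spec encodes a known split hierarchy ('250' splits
the pure-hypertension class from the comorbid pair; 'N05AL' then '496'
isolate the multi-condition class) and is used to verify that the automatic
selector recovers a designed tree; `plant_marker` injects class-exclusive
codes for recovery tests with exact ground truth.

## Numerical and interface choices

Entropy is base 2 throughout (bits); the base affects no ranking.  The
gain-ratio search requires strictly positive gain, so a constant column or
single-class node raises a no-split error rather than returning an
arbitrary cut-off.  Threshold ties resolve to the smallest midpoint.  The
CLI writes a manifest (parameters, seed, version) beside every artifact,
storing file basenames so identical runs into different directories compare
byte-identical; SVG output uses a fixed hash salt and no embedded date for
the same reason.  Problem sizes in the test suite and acceptance script
(hundreds of samples per class; 10,000 per class for calibration; 50 seeds
or trials where the protocol says 50) were chosen once as desk-scale
conditions that keep full runs in seconds while leaving sampling error well
inside the asserted tolerances.

## Known limitations

No pruning or ensembling; no correlated or longitudinal code generation; no
graphical interactive front-end (the interactive selector is an API
callback); the exact entropy-gain variant used for the original screening
step is not published, so standard mutual information is used and noted as
an assumption.  Headline accuracies from the private hospital cohort are
not reproducible here by design — they depend on that data and on clinician
choices during construction.
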