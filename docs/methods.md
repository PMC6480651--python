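# Methods

## The prediction model

`nucloc` treats sub-nuclear localization as a multi-label classification
problem over a fixed vocabulary of 13 compartments (chromatin, nucleolus,
nuclear speckle, PML body, nuclear lamina, nuclear matrix, nuclear
envelope, Cajal body, nuclear pore complex, nucleoplasm, kinetochore,
spindle apparatus, perinucleolar), plus a separate binary task
distinguishing nuclear-only proteins from "travelers" that also function
outside the nucleus.

Prediction is an either/or protocol. If the query has an alignment hit to
an experimentally annotated protein passing the E-value threshold, the
complete label set of the highest-identity hit is transferred (homology
route, HB). Otherwise the de novo route (ML) runs a battery of one-vs-rest
SVMs over a profile string kernel and switches on every label whose
decision value is positive; if none fires, the outcome is "None". The
protocol never blends the two scores: transferring curated annotations
from a close homolog is assumed more reliable than any de novo score, and
the either/or rule makes the combined accuracy an exact weighted sum of
the HB accuracy on covered queries and the ML accuracy on the rest (an
identity the test suite asserts).

### The profile kernel

A profile assigns every sequence position a non-negative *conservation
cost* per amino acid; low cost means the residue is compatible with the
column of the underlying alignment. A k-mer counts as conserved at a
position when the sum of its per-position costs is **strictly below** the
threshold σ ("falls below" is read as strict; ties at exactly σ are
excluded). The feature map is the 20ᵏ-dimensional integer vector of
conserved-k-mer counts over all windows; the kernel is the cosine-
normalized sparse dot product (with the convention 0 when either
self-kernel vanishes).

Because costs are non-negative, partial sums grow monotonically along a
k-mer prefix, so the conserved set is enumerated by depth-first search
that visits residues per position in increasing cost order and abandons a
prefix the moment its cost reaches σ. This is exact — the test suite
checks set equality against exhaustive 20ᵏ enumeration on random
profiles — and fast whenever σ admits only a small fraction of k-mer
space. k-mer indices are base-20 integers with digit order
`ARNDCQEGHILKMFPSTWYV` (PSI-BLAST column order) for reproducible
cross-run indexing.

**Profile construction.** The PSSM reader derives costs from the
percentage columns of the PSI-BLAST ASCII layout via
`cost = −log(max(pct/100, 0.001))` (pseudo-frequency floor 0.001, so an
unobserved residue costs −log 10⁻³ ≈ 6.9), clipped at 0. The pruned
enumeration requires monotone non-negative per-position costs, and a
−log-frequency transform is the simplest monotone map with that property.
The log-odds columns are retained as an alternative
(`cost = max(0, −logodds)`), off by default. Unknown residue X costs
−log(1/20) uniformly.

**Defaults: k = 4, σ = 6.0.** The per-classifier optimum is dataset-
dependent and is exposed as configuration (`KernelParams`); k = 4 is the
practical middle of the 2–6 range and σ = 6.0 admits k-mers whose
positions average below the unobserved-residue cap, i.e. k-mers with
genuine support in the profile.

### The SVM battery

Each compartment classifier separates proteins carrying that label from
all others; multi-label proteins are positive examples for each of their
labels (the development-set accounting is per annotation, not per
protein). Training uses a soft-margin dual SVM on the precomputed
normalized kernel (scikit-learn's SVC, `kernel="precomputed"`); `C`
(default 10) and `tol` (default 10⁻³) are exposed. For the imbalanced
13-class task, class weights are inversely proportional to class
frequency — weight `n/(2·n_class)` per class, giving e.g. a 9:1
positive:negative ratio at a 10/90 split. The traveler task is roughly
balanced and unweighted. Classifiers are stored as their support
expansion (support ids, dual coefficients, bias), so decision values are
reproducible from the serialized archive alone; floats are serialized in
hex for exact round-trips. Decision values at the default `tol` carry the
solver's stopping slack (~10⁻⁴ across sample orderings); with
`tol = 10⁻⁸` they are order-invariant to 10⁻⁶.

### Reliability indices

- HB: `RI = int(10·(PIDE − 20)/8)` truncated toward zero and clamped to
  [0, 100]; PIDE 20 → 0, PIDE 100 → 100. Accepted hits below 20%
  identity (possible at permissive thresholds) clamp to 0 rather than
  going negative, which the formula leaves unspecified.
- ML: `RI = round(raw·100/max_raw)` clamped to [0, 100], nearest-integer
  rounding with halves away from zero; non-positive raw scores map to 0.
  `max_raw` is the largest decision value the classifier reaches on its
  *training positives*, recorded per label — per-label scaling matches
  the per-class SVM structure, and the training fold is the only data
  available at prediction time. For multi-label ML predictions the
  reported RI is that of the top-scoring label. For the binary traveler
  task the magnitude of the decision value is rescaled, so confident
  negative calls also receive high RI.

## Evaluation machinery

The confusion matrix has 13 observed columns and 14 predicted rows (13
classes + "None"). Every observed annotation contributes mass exactly 1
to its column: to the diagonal if predicted, to the "None" row if nothing
was predicted, and otherwise to a predicted row chosen by the
*attribution mode* — the top-scoring predicted label (default), or 1/|P|
to each predicted row (fractional). How a multi-label miss should be
distributed is genuinely underdetermined; both modes preserve column
sums. HB predictions carry no per-label scores, so their top-score
tie-break is the lexicographically smallest predicted label. Q(n) is
100·diagonal/total; reported percentages round half away from zero.

ROC/AUC uses the trapezoid-over-thresholds definition with tie averaging
(scikit-learn), which equals the Mann–Whitney pair-counting statistic;
the tests verify that equality to 10⁻¹² against an independent
pair-counting oracle. Per-class TPR/FPR with zero denominators are
reported as NaN with a warning rather than silently dropped.

Stratified k-fold assignment shuffles each class and deals members
round-robin with a rotating starting fold, guaranteeing per-class fold
counts within ±1 and balanced fold sizes. Multi-label proteins are
stratified on their globally rarest label, which protects the smallest
classes' representation.

The cumulative RI curve reports, for thresholds at 20-point steps,
coverage (fraction of proteins with RI ≥ t) and Q(n) restricted to those
proteins.

The "random performance" baseline has no canonical definition for
imbalanced multi-label data; two explicit baselines are provided
(majority-class and frequency-squared) rather than one implicit claim.

## Spectra, bias correction, agreement

A composition spectrum is the per-compartment fraction of predicted label
assignments over a protein collection (empty predictions excluded).
Classifier bias — systematic over-calling of some compartments — is
corrected with the development-set confusion: with M the observed×
predicted row-normalized confusion (the "None" outcome is a 14th
predicted column), predicted counts satisfy q = Mᵀp, and the underlying
class distribution p is recovered by non-negative least squares followed
by simplex normalization. In the noiseless forward-model case this is
exact (the tests require 10⁻⁶); if the system is ill-conditioned
(condition number > 10¹⁰) a ridge-regularized solve (λ = 10⁻⁶) is used
with a warning. The solver accepts q with or without the "None" count;
the unnormalized-NNLS formulation makes the two equivalent.

Spectrum distances are Euclidean norms on the percent scale; the ± error
is the standard deviation of the distance over bootstrap resamples of
proteins within each collection (default 1000 replicates) — the
resampling unit is the protein, since label assignments within a protein
are dependent.

The agreement score between two predicted label sets A, B is
|A∩B|/max(|A|,|B|): the fraction of the larger set's labels found in the
other set, which is the closed form of summing membership indicators over
the larger set. It is symmetric, bounded in [0, 1] and equals 1 iff the
sets coincide.

## GO enrichment and PPI analytics

Enrichment of a target set within a background uses the upper-tail
hypergeometric probability per term, Benjamini–Hochberg adjustment across
all tested terms, and a significance call at **adjusted** p < 0.01.
Ancestor propagation is not applied by default; the term table is used
as supplied.

The PPI odds ratio compares observed to expected interactions between
compartments i and j: `odds = num_obs/num_exp`, where `num_exp`
distributes the total observed interaction mass proportionally to
`num_pos`, the number of *possible* protein pairs between the
compartments. A protein labeled with both i and j contributes to both
n_i and n_j; a protein pair counts once toward every unordered
compartment pair it can realize, with the identical rule for observed
edges, and the total observed mass is the sum over cells. This
numerator/denominator consistency makes a uniformly random network's
odds exactly 1 in expectation and conserves mass exactly
(Σ num_exp = total observed mass) — both asserted in the tests. Cells
with no possible pairs are reported as missing rather than 0. The
upstream evidence filter keeps binary/direct interactions validated by
yeast two-hybrid or by ≥ 2 independent publication identifiers;
self-loops and duplicate edges are dropped at graph construction.

Degree statistics (mean degree per protein group, component census,
fraction of each group inside the largest component) use networkx.

## The synthetic benchmark

The generator emulates the statistical structure the method assumes, with
ground truth recorded for every planted signal. Study conditions
(defaults chosen once): 13 classes × 20 proteins; profile length 60;
3 planted motif sites per protein, motif length 4 at cost 0
(`motif_strength`), off-motif residues at motif columns costing 4.0;
background costs i.i.d. uniform on [2, 4]; 15% multi-label proteins
(union of two classes' motifs); traveler fraction 0.5 (the real traveler
set is nearly balanced) with a dedicated traveler motif; homolog coverage
0.5 with donor PIDE uniform on [40, 95] and hit E-value 10⁻³⁰ (decoys at
10⁻³); PPI within/between rates 0.2/0.05; one designated GO term per
compartment at odds 8 over a base annotation probability 0.15 plus 15
uniform filler terms. With σ = 6 and background ≥ 2 per position, a
4-window of background never conserves anything (minimum cost 8), exact
motif windows always do, and flanking windows conserve a limited set of
partial-motif k-mers — so kernel counts are class-separating by
construction. Motif sites are separated by ≥ 2k−1 positions so no window
spans two sites and conserved counts decompose exactly per site. Class
sizes can decay geometrically (`class_decay`) to emulate the minority-
class regime of real annotation sets. All generators are pure functions
of their config; independent seed streams are derived per generator.

What the benchmark does *not* emulate: realistic amino-acid substitution
structure, sequence-level homology (hits are declared, not aligned),
correlated annotation noise, or database-scale class imbalance. Passing
the recovery tests therefore demonstrates that the machinery — kernel,
solver plumbing, fold logic, protocol bookkeeping — is correct, not that
real proteomes reach these accuracies; held-out accuracy on the synthetic
benchmark (Q13 ≈ 96% at the default conditions) is far above what real
evolutionary profiles support.

## Problem sizes and statistical checks in the test suite

Tests and the acceptance checks run at the synthetic study conditions
(260 profiles for the recovery runs; 50 replicate networks of 78 nodes
for the PPI calibration; 1000 draws for the p-value calibration; 100
random profiles for the enumeration oracle). Two statistical checks are
formulated to be exact rather than approximately expected to pass:

- p-value calibration uses the uniform-randomized p-value
  `P(X > k) + U·P(X = k)`, which is exactly Uniform(0,1) under the null;
  the raw upper-tail p-value of a discrete statistic is super-uniform and
  would fail a KS test against the continuous uniform by construction.
  A separate test asserts the raw p-values' super-uniformity bound.
- the PPI fixed-point check applies the 3-SE band per compartment-pair
  cell with an allowance of ≤ 2 exceedances among the 91 simultaneous
  cells (the number a 3σ band produces by chance with non-negligible
  probability), plus a grand-mean check; a genuinely inconsistent
  counting rule would shift many cells at once.

## Known limitations

- The per-classifier (k, σ, C, tol) optimum must be tuned per dataset;
  the defaults are sensible starting points, not fitted values.
- Homology inference consumes precomputed alignment tables; the package
  does not run PSI-BLAST or build profile databases.
- Bias correction assumes the development confusion is representative of
  the target collection's error structure; violations propagate directly
  into the corrected spectrum.
- The agreement score ignores label identity beyond set overlap; two
  predictions can disagree on reliability yet score 1.
- No probability calibration of SVM scores is attempted; the RI is a
  rescaling, monotone in the raw score but not a probability.
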