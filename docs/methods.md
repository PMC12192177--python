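# Methods

`oxipept` classifies short peptides (length ≥ 2, canonical 20-letter
alphabet) as antioxidant (AOP) or non-antioxidant from sequence-derived
descriptors. This note documents the model, the descriptor mathematics,
the defaults and why they were chosen, and what the synthetic benchmark
does and does not demonstrate.

## Descriptor encoders

All encoders are pure functions of the residue string; amino acids are
ordered alphabetically (`ACDEFGHIKLMNPQRSTVWY`) everywhere, which fixes
every feature layout.

**AAindex (566-D).** For property *j* with per-residue values
*v_j(a)*, the feature is the sequence mean *F_j = (1/L) Σ_i v_j(r_i)*.
Values are used raw (no z-scoring); a per-property min–max switch exists
but is off by default because the averaging formulation does not require
it. Missing entries in a property are imputed with that property's mean
over available residues and flagged. The bundled default table is a
deterministic *synthetic* stand-in with the real database's shape (566
properties × 20 residues); users holding the real AAindex1 flat file can
pass it to `load_aaindex(path=...)`, which parses the `H`/`I` record
format directly. Conclusions that depend on genuine physicochemistry
require the real table.

**CTD (273-D).** Thirteen physicochemical attributes each partition the
20 residues into 3 groups (bundled table: 7 hydrophobicity scales,
normalized van der Waals volume, polarity, polarizability, charge,
secondary structure, solvent accessibility — the standard 13-attribute
set). Per attribute: composition *C_i = N_i / L* (3 values); transition
*T_{ij} = (N_{ij} + N_{ji}) / (L − 1)* over unordered group pairs
(3 values); and distribution (15 values) — the normalized 1-based
position at which each group attains its first, 25%, 50%, 75% and last
occurrence, with the q-quantile milestone at occurrence `ceil(q · N_i)`.
A literal "fraction of the group within the first k% of positions"
variant (`d_variant="ratio"`) is retained for auditability; it is nearly
constant by construction and not recommended. Groups absent from a
sequence contribute zeros.

**ASDC (400-D).** Adaptive skip dipeptide composition counts the ordered
residue pair at *every* index pair i < j — adjacent dipeptides and all
skip distances — and normalizes by the total pair count L(L−1)/2, making
the vector a probability distribution over the 400 ordered pairs. The
normalizer is the only choice that makes the vector sum to exactly 1 for
every peptide, which the probability interpretation demands.

**BLOSUM62 (420-D).** The published 20×20 BLOSUM62 log-odds matrix
(consumed from Biopython's bundled NCBI copy, validated symmetric) is
extended with an all-zero 21st column. Feature block *a* is
freq(a) × row_a of the extended matrix, concatenated over the 20
residues in alphabetical order. "Frequency weighting" is interpreted as
per-residue-type scaling of that residue's matrix row — the only reading
that yields a fixed 20 × 21 = 420-dimensional vector for variable-length
peptides. Re-deriving the matrix from alignment block frequencies is out
of scope; the matrix is consumed, not computed.

**Fusions.** Any non-empty subset of the four encoders concatenates in
the canonical order (aaindex, asdc, blosum62, ctd) regardless of how the
user spells it, so feature indices are stable across runs. Four encoders
give 15 subsets, 11 of which are true fusions; CTD+BLOSUM62 is 693-D.

## Feature selection

An LGBM gradient-boosted tree ensemble (100 trees, library defaults,
fixed seed — recorded in the ranking for provenance) is fitted to the
encoded training data and each feature's importance is its *split
count*: the number of ensemble nodes that split on it. Features are
ranked by descending count with ties broken by original index (stable),
so constant features rank last with count 0. Nested top-k prefixes
(k = 5, 10, …, 300 — 60 candidates) are then swept with the RBF-SVM.

Sweep scoring default: stratified 5-fold cross-validation on the
*training* split. Scoring the sweep on the held-out test set (available
as `paper_mode=True`) selects features using test data and therefore
leaks; it is provided only to reproduce the published protocol for
comparison. `best_k` maximizes accuracy with MCC as tie-break and
resolves remaining ties to the smallest k (parsimony). The optimal k is
data-dependent — on the original benchmark the reported optimum is 80,
but re-ranking on different data (or with different ensemble settings)
legitimately yields different k.

## Classifiers

Six families: SVM, LGBM, logistic regression, random forest, KNN (k = 5,
a convention, not a tuned value), Gaussian naive Bayes — all at library
defaults with a fixed seed, since the comparison is between descriptor
sets rather than between tuned learners. The final model is an RBF-SVM
at `C = 2.782559402207126`, `gamma = 0.005994842503189409`. Features are
fed unscaled (all encoders emit bounded values by construction); an
optional standardization switch exists for users whose features have
heterogeneous scales. Splitting is stratified 8:2 with floor rounding of
the per-class test share (3022 balanced samples → 604 test).

## Evaluation

Seven metrics from the confusion matrix — ACC, MCC, Sn, Sp, Pre, F1, and
rank-based AUC. MCC uses the standard form
(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Zero-denominator
policy: Sn/Sp/Pre/F1 report 0 with a logged warning; MCC reports 0 when
a marginal is empty. AUC uses the SVM's signed decision value or the
class-1 probability of probabilistic learners; both are monotone
confidences, which is sufficient for a ranking statistic. The grid
summary `mean_score` averages ACC, MCC, Sn, Sp, AUC and Pre.

The Friedman test ranks k treatments within each of N blocks (average
ranks on ties) and reports the classical statistic
χ²_F = 12/(Nk(k+1)) Σ R_j² − 3N(k+1) alongside a tie-corrected variant;
the p-value uses the corrected statistic on k−1 degrees of freedom. In
the grid harness, blocks default to feature sets and treatments to
algorithms, but block construction is a caller-controlled parameter
because other pairings (metrics × models) are equally defensible.

2-D inspection uses supervised UMAP (n_neighbors = 10, min_dist = 0.2,
target_weight = 0.2, weighted-Minkowski metric with uniform weights
unless the caller supplies `metric_kwds`), deterministic given a seed.
Embeddings are qualitative; tests assert only shape, determinism and
that separable classes get positive silhouette.

## Synthetic benchmark

The generator emulates the single property the pipeline needs from real
data — a composition difference between classes. Positives sample
residues with a multiplicative bias (default 4×) toward {W, Y, C, H, M},
echoing the aromatic/sulfur-bearing residues often over-represented in
radical-scavenging peptides; negatives are uniform; lengths are uniform
on 2–50 (typical short-bioactive-peptide range). `enrichment=1` makes
the classes exchangeable — an exact null used for calibration checks. A
`motif` mode instead plants a fixed tripeptide in every positive, giving
order-sensitive features (ASDC, CTD transitions) unique signal for
feature-recovery tests.

What passing tests show: the pipeline extracts a composition signal when
present, stays at chance when none exists, and its selection stage finds
the order-sensitive dimensions a planted motif informs. What they do not
show: performance on real antioxidant data, whose signal is richer than
composition bias and whose redundancy structure (sequences are expected
to be pre-deduplicated, e.g. CD-HIT at the 90% identity threshold, which
this package deliberately does not re-implement) differs from iid
sampling.

**A deliberate limitation of the defaults:** with 5-of-20 residues
biased 4× and lengths uniform on 2–50, the enriched-residue count is a
sufficient statistic, and averaging the binomial likelihood-ratio
test's error over lengths bounds *any* classifier's accuracy at ≈ 0.93 —
short peptides are intrinsically ambiguous. The end-to-end pipeline
measures ≈ 0.90–0.94 test accuracy at these conditions, i.e. close to
the information-theoretic ceiling; a target of 0.95 is not reachable
without longer peptides or stronger enrichment, and the defaults are not
tuned to any target.

## Numerical and interface choices

- Determinism: every stochastic stage (generator, splits, CV folds, tree
  ensembles, UMAP) takes an explicit seed; repeated runs serialize to
  byte-identical feature tables, rankings and predictions.
- Degenerate inputs: sequences shorter than 2 are rejected at the
  boundary (transition and pair denominators need L ≥ 2); noncanonical
  residues reject the record, or skip it with a warning under
  `--drop-invalid`; no maximum length is imposed.
- Problem sizes in tests and the acceptance script (n = 500–1000
  peptides, 60-point sweeps, 1000-draw metric oracles) were chosen as
  the smallest sizes at which the statistical assertions are stable.
- Model bundles persist as a directory (metadata JSON + fitted-state
  file) so the deployable artifact is inspectable without unpickling.
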