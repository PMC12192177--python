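# oxipept

Sequence-based prediction of **antioxidant peptides** (AOPs) — short
amino-acid sequences that scavenge radicals and inhibit lipid oxidation,
of interest as natural food preservatives. Wet-lab identification of
AOPs is slow and costly, so the screening problem is cast as binary
classification: given a peptide's residue string, predict antioxidant
(1) or not (0).

The package is for bioinformaticians and food-science researchers who
want either a ready-made CLI pipeline or the individual building blocks
as a library.

## The method

A peptide of length *L* over the 20 canonical amino acids is mapped to
fixed-length descriptors from three information classes:

| descriptor | dim | captures |
|---|---|---|
| AAindex | 566 | mean physicochemical profile, F_j = (1/L) Σ_i v_j(r_i) |
| CTD | 273 | per-property group composition C_i = N_i/L, transitions T_ij = (N_ij+N_ji)/(L−1), and group distribution milestones (first/25/50/75/last occurrence ÷ L) |
| ASDC | 400 | ordered residue-pair frequencies at all skip distances, normalized by L(L−1)/2 |
| BLOSUM62 | 420 | residue frequencies × rows of the zero-column-extended 20×21 substitution matrix |

Any subset of the four concatenates into a fusion feature (15 subsets,
11 true fusions). Features are ranked by **split importance** — the
number of nodes splitting on each feature across a gradient-boosted tree
ensemble, Importance_split(f) = Σ_t Σ_n 1[v_{t,n} = f] — and nested
top-k prefixes (k = 5…300, step 5) are swept with an RBF-SVM
(C = 2.7826, γ = 0.005995) to pick a compact feature set. Models are
scored with ACC, MCC, Sn, Sp, Pre, AUC and F1, compared across the
15 × 6 feature/algorithm grid with the Friedman rank test
(χ²_F = 12/(Nk(k+1)) Σ R_j² − 3N(k+1)), and inspected with supervised
UMAP. See `docs/methods.md` for full definitions and design choices.

The bundled AAindex table is a clearly-labeled synthetic stand-in with
the real database's shape; pass a genuine AAindex1 flat file to
`load_aaindex(path=...)` for real physicochemistry.

## Worked example

Train and evaluate the final SVM on synthetic composition-biased data
(positives enriched 4× in W/Y/C/H/M):

```python
import oxipept as ox

bundle = ox.ResourceBundle.default()
data = ox.generate_dataset(ox.SynthesisConfig(n_pos=300, n_neg=300,
                                              enrichment=4.0, seed=7))
train, test = ox.split_dataset(data, ox.SplitSpec(seed=7))

spec = ox.FeatureSetSpec.of("ctd", "blosum62")        # 693-D fusion
X_train, _ = ox.encode_dataset(train, spec, bundle)
X_test, _ = ox.encode_dataset(test, spec, bundle)

ranking = ox.rank_features(X_train, train.labels, seed=7)
model = ox.train_classifier(X_train, train.labels, "svm", seed=7,
                            selected_indices=list(ranking.top(80)))
labels, scores = ox.predict(model, X_test)
report = ox.evaluate_predictions(test.labels, labels, scores)
for k, v in report.as_dict().items():
    print(f"{k:4s} {v:.4f}")
```

Output:

```
ACC  0.9153
MCC  0.8305
Sn   0.9153
Sp   0.9153
Pre  0.9153
AUC  0.9552
F1   0.9153
```

Of 120 held-out peptides, 91.5% are classified correctly; MCC 0.83
indicates a strongly better-than-chance balanced classifier, and
AUC 0.955 means a random positive outscores a random negative 95.5% of
the time. (This synthetic signal has an information-theoretic accuracy
ceiling near 0.93 — see `docs/methods.md`.)

The same pipeline from the shell:

```bash
oxipept simulate --n-pos 300 --n-neg 300 --enrichment 4 --seed 7 \
        --out-fasta peps.fa --out-labels peps.tsv
oxipept train peps.fa --labels peps.tsv --features ctd,blosum62 \
        --select-top-k 80 --seed 7 --out-model model/
oxipept predict model/ peps.fa --out preds.tsv
oxipept evaluate preds.tsv --labels peps.tsv --out metrics.json
```

`oxipept grid` runs the full 15 × 6 model grid with Friedman analysis;
`oxipept reproduce-paper` chains the published protocol (CTD+BLOSUM62,
split-importance ranking, test-set-scored sweep) on a user-supplied
benchmark — the original AOP benchmark datasets are an external download
and are not bundled. Input peptides are expected to be pre-deduplicated
(the usual convention is CD-HIT at 90% identity); redundancy filtering
itself is out of scope.

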