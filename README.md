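# savpath

Classification of human protein single amino acid variants (SAVs) as
pathogenic (P/LP) or benign (B/LB) from embedding-based encodings of the
wild-type sequence, the substituted sequence and the protein's GO
annotation, with calibrated probabilities and an integer reliability index.

## How it works

1. **Variant encoding.** Two per-residue embedding backends (pluggable; by
   default deterministic mock backends, with a precomputed-store backend for
   real protein-language-model matrices) embed both the wild-type and the
   substituted sequence. The rows at the variant position are concatenated
   as (backend-1 variant, backend-1 wild-type, backend-2 variant, backend-2
   wild-type); with 1280- and 1024-dimensional backends this is a
   4608-component positional encoding. Backends with a bounded input length
   (1024 residues by default for the first backend) see a 201-residue window
   centred on the variant, shifted — never truncated — at the termini.
2. **Function encoding.** GO annotations are reduced to leaf terms (terms
   that are not is_a/part_of ancestors of another annotated term), looked up
   in a precomputed term-vector table (200-dimensional by default) and
   averaged within each sub-ontology; the (MF, CC, BP) averages are
   concatenated into a 600-component block, zero where unannotated. The
   full feature vector is 4608 + 600 = 5208 components.
3. **Classifier.** Standardization → PCA (fitted on training rows only,
   default 2400 components) → RBF-kernel SVM, with optional grid search over
   (components, C, gamma) selected by cross-validated MCC. A variant is
   called pathogenic when the decision score is ≥ 0. An isotonic regression
   fitted on pooled out-of-fold scores yields a calibrated pathogenicity
   probability, and the reliability index is `round(20 * |p - 0.5|)`
   (0 = random, 10 = certain).
4. **Homology-aware evaluation.** Proteins joined by similarity edges
   (identity ≥ 25 %, coverage ≥ 40 %) are clustered into connected
   components; whole clusters are assigned to a ~10 % blind set and 10
   label-balanced cross-validation folds, so no similar pair ever crosses a
   fold boundary (auditable with `audit_leakage`).

## CLI

`savpath` exposes the workflow as subcommands (see `savpath --help` and
`savpath <cmd> --help`; exit codes: 2 usage, 3 missing input, 4 validation):

```sh
savpath fixture --out demo --seed 7                # synthetic input bundle
savpath curate  --fasta demo/proteins.fasta --variants demo/variants.tsv \
                --out curated.tsv --log exclusions.tsv
savpath cluster --fasta demo/proteins.fasta --clusters-out clusters.tsv
savpath split   --clusters clusters.tsv --fasta demo/proteins.fasta \
                --variants curated.tsv --seed 7 --out folds.tsv
savpath encode  --fasta demo/proteins.fasta --variants curated.tsv \
                --annotations demo/annotations.tsv --obo demo/go.obo \
                --vectors demo/term_vectors.tsv \
                --backend precomputed --emb1 demo/mockA.npz --emb2 demo/mockB.npz \
                --out-prefix features
savpath train   --features-prefix features --folds folds.tsv --out model.zip \
                --pca-components 60 --seed 7
savpath predict --model model.zip --features-prefix features --out predictions.tsv
savpath evaluate --predictions predictions.tsv --truth features.meta.tsv \
                 --out metrics.json --format json
```

Input formats are plain text: FASTA sequences; a tab-separated variant table
(`accession substitution label somatic disease_ids source`, substitutions in
`A123V` or `p.Ala123Val` form); an OBO ontology; `accession<TAB>go;ids`
annotations; a `go_id v1..vD` term-vector table. For real-scale clustering,
pass a precomputed edge file (`a b identity coverage`) via
`cluster --edges-in`. Prediction output is tab-separated or JSON with fields
accession, substitution, predicted_label, probability_pathogenic,
reliability_index, raw_score.

## Layout

- `src/savpath/variant_data.py` — records, FASTA/table parsing, curation rules
- `src/savpath/homology.py` — similarity edges, connected components, fold assignment
- `src/savpath/embeddings.py` — backend contract, mock/precomputed backends, window rule, positional encoding
- `src/savpath/go_encoding.py` — OBO parsing, leaf filtering, term-vector averaging
- `src/savpath/predictor.py` — feature assembly, PCA + SVM + isotonic calibration, persistence
- `src/savpath/evaluation.py` — confusion metrics, ROC-AUC, cross-validation, calibration diagnostics
- `src/savpath/fixtures.py` — synthetic data with controllable class signal
- `src/savpath/cli.py` — command-line entry points
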