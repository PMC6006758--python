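# apoloc

Profile-based prediction of protein subcellular localization.

The pipeline turns per-protein PSI-BLAST profiles (L×20 log-odds matrices)
into fixed-length feature vectors, reduces them with a supervised local
Fisher discriminant transform, and evaluates a one-vs-one RBF-SVM by
leave-one-out (jackknife) testing:

1. **I/O** — FASTA sequences, a two-column label TSV, and PSI-BLAST ASCII
   profiles (both the 40-column NCBI layout and a bare 20-column layout are
   auto-detected). Profiles are normalized elementwise by the logistic
   sigmoid 1/(1+e⁻ˣ).
2. **Pseudo-profile features** — the 20 column means plus, for each lag
   g = 1..ξ, the 20 mean squared differences between rows g apart
   (20 + 20ξ values; ξ=3 → 80).
3. **Detrended cross-correlation features** — for each of the 190 unordered
   column pairs, the detrended cross-correlation coefficient of the
   integrated columns over all overlapping windows of S+1 points (S=40 by
   default; values in [−1, 1]).
4. **Reduction** — local Fisher discriminant analysis: local-scaling
   affinities (K=7), locality-weighted within/between scatter matrices, and
   the top-r generalized eigenvectors (r=10 by default).
5. **Classification / evaluation** — RBF-SVM with an exhaustive power-of-two
   grid search (C ∈ 2⁻⁵..2¹⁵, γ ∈ 2⁻¹⁵..2⁵) scored by seeded stratified
   K-fold accuracy, then jackknife evaluation with per-class sensitivity,
   specificity, MCC, overall accuracy, and macro one-vs-rest ROC/AUC.

A synthetic-fixture generator draws labeled profile datasets whose column
means, row autocorrelation, and inter-column correlation differ by class, so
the whole pipeline is testable without any external database.

Running PSI-BLAST itself is out of scope: profiles are expected as files,
one `<protein_id>.pssm` per FASTA record (e.g. from
`psiblast -num_iterations 3 -evalue 0.001 -out_ascii_pssm <id>.pssm`).

## CLI

Generate a synthetic dataset, run the pipeline, and sweep a parameter:

```sh
apoloc synth --n-classes 3 --n-per-class 32,30,28 --separation 6 \
    --lag-signal 0.3 --pair-signal 0.3 --seed 1 --out data/

apoloc run --fasta data/proteins.fasta --labels data/labels.tsv \
    --pssm-dir data/pssm --xi 3 --S 40 --r 10 --lfda-mode paper \
    --seed 1 --out out/

apoloc sweep --fasta data/proteins.fasta --labels data/labels.tsv \
    --pssm-dir data/pssm --parameter xi --values 0..10 --out out/
```

`apoloc run` writes `report.json`, `metrics.txt`, `features.csv`, `roc.csv`,
`confusion.csv`, `grid.csv`, and `model.json` under `--out`. Reports carry
no timestamps, so identical configs and seeds reproduce them byte-for-byte.
Options may also come from a JSON/TOML file via `--config`; flags override.

Two evaluation protocols are exposed: `--lfda-mode paper` fits the reduction
once on the full dataset before the jackknife loop (reproducing the
published pipeline order, which leaks label information into the transform),
and `--lfda-mode strict` refits the reduction inside every jackknife fold.
Reports name the mode used.

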