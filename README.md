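# spectralhkg

Prediction of housekeeping genes (HKGs) from gene-expression time series.
The pipeline turns each probe's time course into a Fourier power spectrum and
uses an RBF-kernel SVM inside a bootstrap voting ensemble to decide which
genes are expressed stably enough to be housekeeping genes.

Stages:

1. **expression_io** — parse tab-separated (PCL-compatible) expression
   matrices and plain-text reference gene lists; partition probes into
   *standard* (gene in all three reference HKG lists), *putative* (one or
   two lists) and *non-HKG* (none) pools; read/write prediction tables.
2. **preprocessing** — missing-data triage (drop series with adjacent gaps,
   three or more gaps, or missing endpoints), monotone piecewise-cubic
   Hermite interpolation of one or two isolated gaps, and least-squares
   detrending against five bases (1, t, t², t³, ln t).
3. **spectral_features** — unnormalised DFT and the 24 independent
   power-spectrum components of a 47-point series (generally (N+1)/2 for
   odd N), used as classifier features.
4. **discrimination** — RBF SVM with grid-search hyperparameter selection,
   plus the HN-vs-NN model comparison (true model: standard-pool positives
   vs random non-HKG negatives; control model: two disjoint random non-HKG
   samples) over many replicates with 50/50 train/test splits.
5. **voting** — bootstrap voting: each round trains standard positives
   against freshly resampled non-HKG negatives and scores every putative
   and non-HKG probe; genes are selected per pool (putative: vote count ≥
   cutoff, default 3328/4096 = 81.25% ballot; non-HKG: count > cutoff,
   default 4085/4096 = 99.73% ballot; standard genes always selected).
6. **evaluation** — coefficient of variation (sample SD / mean) across
   tissue expression columns, median CV per gene set, and exon
   conservation scores (per-mRNA mean of base scores, averaged unweighted
   across mRNAs).
7. **synthetic_fixtures** — seeded generators for steady (HKG-like) and
   periodic (cell-cycle-like) series, labelled probe pools with planted
   mis-annotations, and tissue matrices with planted low/high-CV genes.

## Command-line usage

The `spectralhkg` entry point (equivalently `python -m spectralhkg.cli`)
exposes `simulate`, `preprocess`, `featurize`, `compare`, `vote`,
`predict` and `evaluate`. A quick synthetic end-to-end run:

```sh
spectralhkg simulate --out-dir demo --seed 1
spectralhkg predict \
    --matrix demo/matrix.tsv \
    --list1 demo/list1.txt --list2 demo/list2.txt --list3 demo/list3.txt \
    --rounds 256 --n-neg 40 --putative-cutoff 208 --nonhkg-cutoff 255 \
    --seed 1 --out demo/predictions.tsv
spectralhkg evaluate --tissue-matrix tissues.tsv --gene-list hkgs.txt
```

Any long option can also come from a YAML config file via `--config`;
explicit flags win. Every run logs its full effective configuration.
Defaults follow the reference configuration: 47 time points, 4096 voting
rounds, 234 negatives per round, cutoffs 3328 and 4085, 1024 comparison
replicates.

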