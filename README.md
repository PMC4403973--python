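# pyrodenoise

Two-stage error correction for 454 pyrosequencing amplicon reads, for
microbiome researchers who need mock-community-grade error rates before OTU
clustering. Pyrosequencing infers homopolymer lengths from analog flow
signals, so its reads are dominated by homopolymer insertions/deletions and
carry-forward artifacts; left uncorrected these inflate OTU counts and
diversity estimates in 16S rRNA surveys.

The method:

1. **Flag** — every called base gets a 13-attribute vector from the flowgram
   (position, Phred, homopolymer code, carry-forward sensitivity, flow
   intensity, plus eight neighbour-derived attributes including the strongest
   *uncalled* flow signal between adjacent calls). A support-vector machine
   with the Pearson VII universal kernel,
   `K(x,y) = 1 / [1 + (2·√(2^(1/ω)−1)·‖x−y‖/σ)²]^ω`,
   trained by sequential minimal optimization on reference-labeled mock
   reads (dereplicated, 1:9 stratified split, training subset balanced to
   132 per error type + 700 clean), marks positions predicted erroneous.
2. **Correct** — reads are dereplicated, projected into a template
   alignment's column space (NAST style), and preclustered from most to
   least abundant: a read merges into the first seed within
   `floor(0.02 × read length)` differences, where columns masked in either
   read are skipped. Merged reads adopt the seed; reads that never merge are
   restored byte-identical to their pre-masking originals.

The package also ships the evaluation machinery used to measure correction
(basic/strict trimming, reference-based per-position error labeling,
two-parent chimera detection, global and per-position error rates) and a
flowgram simulator with exact, generation-time ground truth, so the entire
pipeline is testable without downloading sequencing archives.

## Worked example

```bash
python examples/04_denoise_pipeline.py
```

builds an uneven 10-species mock community (length 350, 10% divergence,
log-uniform abundances), simulates 2,000 flowgram reads at the default error
model, trains and applies the classifier, runs masked preclustering, and
prints:

```
reads kept after trimming: 2000
flagged positions: 31012
clusters (corrected sequences): 11
error rate raw:      0.00556
error rate denoised: 0.00093
relative reduction:  83.3%
```

Read it as: the simulated plate has a realistic raw error rate of ~0.5% per
base; after the two-stage correction the surviving sequences — 11 abundance-
annotated cluster representatives — carry under 0.1% errors, an >80%
reduction, with total read abundance conserved exactly. `examples/03_train_classifier.py`
prints the classifier's held-out sensitivity/specificity and the confusion
matrix behind them; `examples/05_chimeras_and_profiles.py` shows chimera
flagging and the rise of the error rate toward read ends.

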