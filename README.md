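# stiffscan

Promoter and transcription-start-site (TSS) prediction from the *physical*
properties of DNA, plus the orthogonal analytics used to validate such
predictions — all exercisable end-to-end on synthetic data with known truth.

## The problem and the model

Core promoters are regions of unusual DNA deformability: even without
classical sequence motifs, the helical stiffness of the double helix around a
TSS differs measurably from bulk genomic background. `stiffscan` encodes this
idea as a comparative classifier:

* **Physical profile.** Each dinucleotide step *XY* carries a vector of six
  diagonal stiffness (force) constants
  *K* = (*k*<sub>twist</sub>, *k*<sub>tilt</sub>, *k*<sub>roll</sub>,
  *k*<sub>shift</sub>, *k*<sub>slide</sub>, *k*<sub>rise</sub>) — rotations in
  kcal/(mol·deg²), translations in kcal/(mol·Å²), symmetric under reverse
  complement. A sequence becomes a six-channel series annotated at the
  dinucleotide level and averaged linearly over 500-bp windows.
* **Feature grid.** A candidate TSS is described by the window means over a
  −250/+900 bp span tiled at 50-bp stride: *D* = 6 × 14 = 84 features.
* **Classification.** Two reference profiles (mean **μ** and covariance
  **Σ** of the feature vector) are fitted to known-promoter and background
  training sets. A candidate **x** is scored by Mahalanobis distances
  *d*<sub>c</sub>(**x**) = √((**x**−**μ**<sub>c</sub>)ᵀ **Σ**<sub>c</sub>⁻¹
  (**x**−**μ**<sub>c</sub>)) and called a promoter when
  *score* = *d*<sub>background</sub> − *d*<sub>promoter</sub> > 0.
* **Downstream bookkeeping.** Core-promoter regions span −1000/+200 bp around
  each predicted TSS (strand-aware); candidate selection keeps calls ≥ 1200 bp
  from annotated TSSs with ≤ 70% repeat-masked sequence.

Validation analytics included: strand-aware percent-distance-bin profiling of
CAGE/RNA-seq tag 5′-ends over candidate regions (100 bins; a TSS 1000 bp into
a 1200-bp region sits in bin 84, into a 2000-bp region in bin 50), TSS
re-location, Fisher's exact TFBS enrichment with Bonferroni control, bedGraph
signal averaging, DNase-cluster counting, and the predictor×activity subset
cross (PS±/L±).

## Worked example

Everything below is synthetic and seeded; the generator plants 20
promoter-composition spans in a 120-kb genome and the classifier must find
them.

```python
from stiffscan import (GridSpec, PromoterModel, SyntheticSpec, gen_genome,
                       gen_stiffness_table, gen_training_examples)
from stiffscan.synthetic import match_calls

spec = SyntheticSpec(seed=1)                 # 120-kb genome, 20 planted TSSs
table = gen_stiffness_table(spec.seed)       # rc-symmetric stiffness constants
grid = GridSpec()                            # -250/+900 bp, 500-bp windows

genome = gen_genome(spec, table, grid)
promoters = gen_training_examples(spec, table, grid, spec.n_training, "promoter", seed=1011)
background = gen_training_examples(spec, table, grid, spec.n_training, "background", seed=1012)

results = PromoterModel(promoters, background, table=table, grid=grid).fit()
print(results.summary())

tracks = results.scan(genome.genome, stride=grid.stride)
calls = results.call_tss(tracks, quantile=0.95, min_separation=1200)
print(match_calls(calls, genome.truth, tolerance=grid.stride))
```

prints

```
Stiffness-profile promoter classifier
=====================================================
grid span          : -250/+900 bp around TSS
windows            : 14 x 500 bp (stride 50 bp)
feature dimension  : 84 (6 channels x 14 windows)
covariance         : full + ridge
n training         : promoter 250, background 250
table checksum     : 29843376b3880fb5
training scores    : promoter   mean   +11.26  sd   1.48
training scores    : background mean   -11.68  sd   1.51
{'n_truth': 20, 'n_calls': 20, 'recall': 0.9, 'precision': 0.9}
```

The summary shows the two training classes separated by ~23 score units
(promoter features sit ~11 distance units closer to the promoter reference
than to background, and vice versa); scanning both strands at 50-bp stride
and peak-calling above the 95th score percentile recovers 18 of the 20
planted TSSs to within one grid stride, with 18 of 20 calls correct.

The same pipeline is available from the shell:

```sh
stiffscan simulate --outdir fixtures/
stiffscan train --fasta fixtures/genome.fa --tss-bed fixtures/truth.bed \
    --table fixtures/stiffness.tsv --label promoter --out promoter.json
stiffscan scan --fasta fixtures/genome.fa --model-promoter promoter.json \
    --model-background background.json --out scores.bedgraph --calls calls.bed
stiffscan tagprofile --regions regions.bed --tags fixtures/tags.bed --out profile.tsv
stiffscan enrich --incidence fixtures/incidence.tsv --out enrichment.tsv
```

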