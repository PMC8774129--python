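# ncscreen

Noncoding-RNA biomarker panels and neural-network classifiers for
multi-cancer screening from bulk RNA-seq TPM expression matrices.

## The problem

Population-level cancer screening needs a small, stable panel of
molecular markers and a classifier that works on raw measurements.
Given a samples-by-features TPM matrix with labels ("normal" or one of
C cancer types), this package answers three questions:

1. **Which noncoding RNAs are reliable markers?** Resampling stability
   selection: the training cohort is split into *m* random subgroups,
   an L1-penalized linear classifier (one-vs-rest) selects features in
   each subgroup, and the partition is redrawn *n* times. A feature's
   *frequency score* is the fraction of the m·n runs that selected it;
   the frequency-ranked list is the marker panel.
2. **How many markers does the screen need?** Accumulation curves:
   for k = 1, 2, …, K a fresh classifier is trained on the top-k
   markers and scored on a held-out test set (AUC for the binary
   cancer-vs-normal screen, accuracy for the C-way typer). AUC is the
   Mann–Whitney concordance P(score⁺ > score⁻) + ½·P(score⁺ = score⁻).
3. **At what panel size does performance stop depending on the random
   training resample?** The *turning point*: independent resamples
   produce independent panels and accumulation curves; at each panel
   size k a Kruskal–Wallis rank-sum test (tie-corrected H, χ²
   p-value) compares the runs' trailing windows of accuracies. The
   stable panel size k\* is the largest k before p falls below α
   (default 0.1) — beyond it, measured accuracy reflects sampling, not
   the system.

The classifiers are fixed-architecture feed-forward networks — dense
30→60→sigmoid for binary screens, six 240-unit layers→softmax for the
multiclass typer, each layer with relu and dropout 0.1, trained by Adam
for exactly 30 epochs in batches of 20 — plus random-forest and
decision-tree baselines behind the same interface for model comparison.
Everything consumes raw TPM: no filtering, no normalization, no log
transform (an opt-in `log_transform` flag exists for experimentation).

Because the real discovery cohorts are controlled-access consortium
downloads, the package ships a synthetic-cohort generator
(`ncscreen.synthetic_data`) producing TPM-like log-normal matrices with
dropout zeros, severe cancer:normal imbalance, planted informative
markers, and paired "external" cohorts that share only a subset of
feature identifiers — so every stage of the pipeline is testable
offline, end to end, against a known ground truth.

## Worked example

```python
import numpy as np
from ncscreen import (SyntheticConfig, generate_cohort, StabilityParams,
                      select_stable_features, split_samples,
                      accumulation_curve)

cfg = SyntheticConfig(n_classes=2, samples_per_class=(50, 50, 50),
                      n_features=200, n_informative=10,
                      effect_size=3.0, seed=7)
matrix, labels, truth = generate_cohort(cfg)
labels = np.asarray(labels)

panel, counts = select_stable_features(
    matrix, labels, StabilityParams(m=2, n=100, seed=1))
print(f"top 10 overlap with planted markers: "
      f"{len(set(panel.top(10)) & truth.marker_ids)}/10")

split = split_samples(matrix.n_samples, test_frac=0.2, val_frac=0.2, seed=3)
curve = accumulation_curve(panel, matrix, labels, split,
                           K=20, seed=3, task="binary")
for k in (1, 5, 10, 20):
    print(f"k={k:>2}  test AUC={curve.metric[k-1]:.3f}")
```

Output:

```
top 10 overlap with planted markers: 10/10
k= 1  test AUC=0.670
k= 5  test AUC=0.986
k=10  test AUC=1.000
k=20  test AUC=1.000
```

All ten planted markers land in the panel's top ten ranks, and the
accumulation curve shows the screen's signature shape: a single marker
is mediocre (AUC 0.67), a handful nearly saturate the screen, and
further markers add nothing — which is exactly the behaviour the
turning-point analysis quantifies across independent resamples.

The same workflow is available from the shell:

```bash
ncscreen simulate --n-features 200 --n-informative 10 \
    --effect-size 3.0 --seed 7 --out cohort/
ncscreen select --expression cohort/expression.tsv \
    --labels cohort/labels.tsv --m 2 --n 100 --resamples 8 \
    --seed 1 --out panels/
ncscreen run-all --config pipeline.yaml
```

`run-all` executes load → split → selection per resample →
accumulation curves → turning point → final model, writing panels,
curve CSVs, the p-trace, ROC points, a JSON summary and a reproducible
run log; reruns with the same master seed are byte-identical.

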