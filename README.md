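# cnlri

Retention-index prediction for structurally unknown chemicals, directly
from high-resolution tandem-MS spectra.

In non-target LC-HRMS screening, predicted chromatographic retention
helps rank candidate structures — but a truly unknown chemical has no
structure to compute descriptors from. `cnlri` sidesteps that by
training a model whose inputs are computable from any MS/MS spectrum:
the **cumulative neutral losses** (CNLs, all precursor-minus-fragment
mass differences) encoded as a ternary vector on a 0–1000 Da / 0.01 Da
grid (1 = loss present, 0 = absent, −1 = heavier than the precursor,
i.e. impossible), plus the precursor mass.

Because spectra with measured retention indices are scarce, the CNL
model is trained semi-supervised, in two stages:

1. a descriptor-based (QSRR) gradient-boosted model, fit on compounds
   with experimental retention indices r_i, **pseudo-labels** a large
   spectral corpus of known-structure compounds;
2. the CNL model trains on the pseudo-labeled corpus plus a minority
   share of the measured compounds, and is tested on the withheld
   measured compounds it has never seen.

Every prediction is gated by a leverage **applicability domain**:
h(x) = xᵀ(XᵀX)⁻¹x against the training design of the final model's
features, with the cutoff h\* set at the 95th percentile of
leave-one-out training leverages.

The package is aimed at computational mass spectrometrists and
cheminformaticians; it ships MSP/MGF readers, the featurizer, the
descriptor-curation step (min-max scaling + replicate-stability
variance filter at 0.01), both model presets, the AD, the pipeline
orchestrator and a synthetic-data generator with known ground truth.
See `docs/methods.md` for the full model description.

## Worked example

`examples/04_two_stage_pipeline.py` runs the whole workflow on a
300-compound synthetic world (seed 7) and prints:

```
world: 620 spectra, 120 measured compounds, 180 corpus compounds (15 out-of-distribution)

curation: kept 50 descriptors, dropped 10 unstable
pseudo-labels: 155 in-domain, 25 rejected by the AD
descriptor/train              R2= 0.984  RMSE= 20.9 r_i units  max|err|=111.2  n=102
descriptor/test               R2= 0.941  RMSE= 36.4 r_i units  max|err|= 73.3  n=18
cnl/train              R2= 0.969  RMSE= 28.8 r_i units  max|err|= 97.8  n=343
cnl/corpus_test        R2= 0.864  RMSE= 60.2 r_i units  max|err|=132.6  n=49
cnl/experimental_test  R2= 0.836  RMSE= 69.3 r_i units  max|err|=223.2  n=180
```

The curation step removed exactly the 10 replicate-unstable
descriptors designed into the world; the applicability domain rejected
all 15 out-of-distribution corpus compounds (plus a handful of
borderline ones) before pseudo-labeling. The last line is the honest
score: R² = 0.836 against measured retention indices of compounds
neither model saw during training. It is lower than the corpus test
above it because the CNL model's training labels are mostly
predictions — error propagates from stage one — which is the expected
ordering.

The other examples are single-capability walkthroughs: CNL
featurization (`01`), descriptor curation (`02`) and the applicability
domain (`03`). A thin CLI mirrors the file-based entry points:

```sh
cnlri simulate --n 300 --seed 7 --out fixtures/
cnlri featurize --in fixtures/spectra.msp --out matrix/
cnlri curate --replicates fixtures/descriptors_rep1.csv \
             --replicates fixtures/descriptors_rep2.csv \
             --replicates fixtures/descriptors_rep3.csv --out curation.json
```

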