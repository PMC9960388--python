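# Methods

## Problem and approach

In non-target LC-HRMS screening, candidate structures proposed from a
tandem-MS spectrum can be re-ranked by how well their predicted
chromatographic retention matches the observed retention. Retention
expressed as a retention index (r_i, on a homologous-series calibrant
scale, here spanning roughly 200–1041 units) transfers across
instruments, which makes it a practical target for prediction. The
difficulty is that for a truly unknown chemical no structure — and
hence no molecular descriptors — are available; only the spectrum is.

`cnlri` therefore trains a model that predicts r_i *from the spectrum
itself*, in two stages:

1. **Descriptor (QSRR) stage.** A gradient-boosted-tree regressor maps
   curated molecular descriptors to experimental r_i for the compounds
   that have both. The model is refit on its 40 most important
   descriptors, and a leverage applicability domain (AD) is derived
   from the refit training design.
2. **Pseudo-labeling + CNL stage.** The descriptor model predicts r_i
   for a large spectral corpus of known-structure compounds — but only
   for compounds inside the AD. Those predictions become training
   labels for a second regressor whose inputs are computable from any
   spectrum: the ternary cumulative-neutral-loss (CNL) encoding plus
   the precursor mass. A minority share of the experimentally measured
   compounds joins CNL training with their measured r_i; the rest are
   withheld as the honest test set, unseen by either model.

Because most CNL training labels are themselves predictions, the CNL
model inherits the descriptor model's errors; the error on the
withheld experimental set is therefore expected to exceed the error on
the held-out corpus share, and the test suite checks that ordering.

## CNL featurization

Cumulative neutral losses are all `precursor_mz − fragment_mz`
differences of a spectrum. Ions are treated as singly charged; the
precursor ion m/z is used as given with no adduct arithmetic, so losses
live in m/z space. Fragments above the precursor are physically
impossible as losses and are excluded (and counted).

Losses are encoded on a fixed grid of 100,000 bins covering
[0, 1000) Da with 0.01 Da spacing — equivalently a ±5 mDa tolerance
around each bin center at `k·0.01` Da. Each row is ternary:

* `1` — at least one loss in the bin (presence only; intensities are
  parsed but unused),
* `0` — no loss observed, though a loss of that mass would be possible,
* `-1` — the bin center exceeds the precursor mass, so a loss there is
  impossible. This lets a tree distinguish "absent" from "impossible".

The precursor m/z is appended as one continuous feature (100,001
columns total). Numerical conventions:

* bin assignment is round-half-to-even on `mass/0.01`; an exact
  half-boundary such as 18.005 Da follows that rounding rule;
* the `-1` band starts one bin past the precursor's own bin, so a loss
  (always ≤ precursor) can never land in a `-1` bin, even when the
  precursor itself sits within 5 mDa of a bin center;
* a 0 Da loss (surviving precursor ion) is a valid bin-0 entry;
* losses ≥ 1000 Da fall off-grid and are dropped with a counted
  warning.

Storage is sparse: only `+1` bins are materialized, and the `-1` band
is a single per-row breakpoint. For model fitting the matrix is
densified over the bins that carry at least one loss in the *training*
rows (plus the precursor column); bins never observed in training are
constant except through the `-1`/`0` boundary, which is redundant with
the precursor feature, and including all 100,000 would only inflate a
desk-scale matrix. Column choice never looks at test rows.

## Descriptor curation

Replicated descriptor calculations (triplicate by default) are min-max
scaled jointly per descriptor, then the across-replicate sample
variance (ddof = 1) is computed per compound and aggregated over
compounds. A descriptor is kept iff its aggregated variance is
*strictly* below the threshold (default 0.01 on the scaled scale).
Aggregation is by the maximum over compounds by default — the strictest
reading — with `mean` and `pooled` modes available, since the variance
could equally be read as a per-compound-then-aggregated or a pooled
quantity. Compounds with non-finite values (typically failed 3D
descriptor convergence) are dropped row-wise before curation and
reported, not imputed. The fitted (min, max) pairs and the kept list
are stored and re-applied verbatim to new tables; new values may fall
outside [0, 1] and are deliberately not clipped.

## Applicability domain

The leverage of a query x against a training design X is
`h(x) = xᵀ(XᵀX)⁻¹x` — for training rows, the diagonal of the hat
matrix. The in-domain cutoff h* is the 95th percentile
(linear-interpolation definition) of the leave-one-out leverage
distribution: each training row scored against the design with that row
removed. For an invertible (possibly ridge-regularized) Gram matrix
this equals the Sherman–Morrison downdate `h/(1−h)` of the full-design
leverage; otherwise the implementation falls back to explicit per-row
pseudo-inverses. The in-domain comparison is inclusive (`h ≤ h*`).

Only the features the final model uses enter the design: the 40 refit
descriptors for the descriptor model, the nonzero-importance bins for
the CNL model. The CNL design is near-binary and typically
rank-deficient, so its Gram matrix gets a small ridge (1e-8) inside the
pipeline; bins unique to a single training spectrum then legitimately
produce enormous leave-one-out leverages, and the CNL h* is
correspondingly large and dataset-dependent. Thresholds are recomputed
per model, never reused across feature spaces.

## Models

Both stages use gradient-boosted regression trees with an RMSE
objective, early stopping after 5 non-improving rounds on a validation
set, and these presets:

| preset     | iterations | learning rate | depth | max leaves | min leaf | L2 |
|------------|-----------:|--------------:|------:|-----------:|---------:|---:|
| descriptor |        450 |          0.03 |     8 |        256 |        1 | 10 |
| CNL        |       5000 |         0.077 |     6 |         64 |        1 |  3 |

The backend sits behind a thin contract (fit with early stopping,
predict, importance); LightGBM implements it, with its defaults for
everything not listed and the mapping iterations→`n_estimators`,
depth→`max_depth`, max leaves→`num_leaves`, min leaf→
`min_child_samples`, L2→`reg_lambda`. Training is single-threaded with
`deterministic=True`, so a fixed seed reproduces a model bit-for-bit.

Feature ranking for the 40-descriptor refit uses the backend's native
split-gain importance as a proxy for variance explained; ties break by
original feature order. "Used features" are those with nonzero gain.

Splits are stratified over three r_i classes (200–440, 440–700,
700–1041) to respect the skewed label distribution; within each class
the train fraction is honored to within one sample. All CNL-stage
splits are compound-grouped by default — every spectrum of a compound
falls on one side — so duplicate spectra (which are intentionally kept
as separate rows) can never leak a test compound into training; a
spectrum-level mode exists for comparison. Early-stopping validation
sets are carved from the training share (15%, stratified,
compound-grouped at the CNL stage) rather than touching any test set.
One pipeline seed deterministically derives every stage seed.

## Synthetic world

The generator emulates the workflow's three inputs from a single
standard-normal latent per compound (a hydrophobicity surrogate):

* **labels**: `r_i = 200 + 841·sigmoid(latent) + N(0, 45)`. The noise
  sd of 45 r_i units matches the residual scale typical of
  descriptor-based retention models and puts the noise-ceiling R²
  near 0.9, leaving headroom over the pipeline's expected performance.
* **descriptors** (60 columns): 25 informative columns, affine in the
  latent with compound-level noise (sd 0.15); 25 pure-noise decoys;
  10 designed-unstable columns whose replicate noise (sd 3.0 raw,
  ~0.2 scaled) guarantees the stability filter drops exactly them,
  while stable columns' replicate noise (sd 0.03 raw) stays at least an
  order of magnitude below the 0.01 variance cutoff even under the
  max-over-compounds aggregation.
* **spectra**: precursor mass `300 + 80·latent + N(0,15)` (clipped to
  [170, 950] Da); characteristic neutral losses drawn from a fixed
  12-mass vocabulary (water 18.011, CO 27.995, HCl 35.977, CO₂ 43.990,
  46.005, C₄H₈ 56.063, 59.037, SO₂ 65.97, 72.058, SO₃ 79.957, 98.984,
  155.00 Da) with inclusion log-odds monotone in the latent,
  alternating in sign across the vocabulary; 2–5 uniform decoy losses;
  fragment mass error sd 2 mDa (within the ±5 mDa bin tolerance ~98% of
  the time); 1–3 spectra per compound.

Of 300 compounds, 120 carry experimental labels (and triplicate
descriptors); the remaining 180 form the corpus, of which 15 are
generated far outside the descriptor cloud (+8 raw units on every
informative column) to exercise AD rejection. The labeled fraction is
much larger than in a realistic corpus; it was chosen so the held-out
evaluation sets remain large enough for stable R² estimates at desk
scale. Ground truth (latent, noise-free r_i, the vocabulary→latent
map) is persisted for oracle tests.

What the generator does *not* emulate: physically realistic
fragmentation (losses are drawn, not derived from structures), isotope
patterns, collision-energy dependence, adduct diversity, instrument
noise beyond a single mass-error term, and any correlation structure
among descriptors beyond their shared latent. Passing tests therefore
demonstrate that the pipeline recovers a retention signal carried by
neutral-loss presence and precursor mass under realistic noise — not
that it attains any particular accuracy on real libraries.

## Problem sizes and degenerate inputs

The default test world has 300 compounds (~600 spectra); an end-to-end
run takes a few seconds, and the distributional checks repeat it over
five seeds. Degenerate inputs are handled explicitly: empty fragment
lists reject a spectrum (listed, never silent); constant descriptor
columns scale to 0 and are flagged; constant labels refuse training;
zero-variance truth makes R² NaN with a warning; empty r_i classes are
skipped with a warning; near-empty test sets are flagged. Scaling
idempotence is exact to 1e-12; leverage arithmetic is verified against
an independent hat-matrix oracle to 1e-10.

## Known limitations

* The AD is purely leverage-based; it flags extrapolation in feature
  space but not label-space novelty, and for the near-binary CNL design
  the LOO threshold is dominated by unique-bin spectra.
* The monoisotopic-mass feature is the precursor ion m/z, not the
  neutral mass; for multiply charged or exotic adducts the loss grid
  would need adduct handling that is deliberately out of scope.
* Descriptor computation itself (e.g. PaDEL) is out of scope; the
  package consumes descriptor CSVs.
* Reported synthetic-scale metrics are not comparable to performance
  on real spectral libraries (see the generator's non-goals above).
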