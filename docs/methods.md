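# Methods

## The loop, formally

Inputs: a training set of `N_train` images (after augmentation), a test
set, the per-iteration annotation count `K`, the initial pseudo fraction
`p(0)` and its stride `δ`. State: the disjoint sets `X_M` (manually
labeled), `X_P` (pseudo-labeled, cleared every iteration), `X_U`
(unlabeled), and — in the pool variant — the image pool.

Initialization draws `K` training images uniformly at random (seeded),
charges the oracle for their labels, and fits the classifier once.
Each iteration then:

1. ranks `X_U` by the chosen certainty score, highest first;
2. pseudo-labels the top `N_pseudo(k) = ⌊N_train · p(k)⌋` images with the
   current model's argmax (ties to the smaller class index) and moves
   them to `X_P` for this round;
3. annotates the bottom `K` (charged) into `X_M` — or, in the pool
   variant, draws `K` banked associates uniformly at random with free
   labels whenever the pool holds at least `K`;
4. in the pool variant, banks every still-unlabeled augmentation
   associate of the manual set into the pool (the initial `K`
   annotations' associates enter at the first pass);
5. fine-tunes the classifier on `X_M ∪ X_P`, evaluates on the test set;
6. updates `p(k+1) = min(p(k) + δ·k, p_max)` — the printed form of the
   stride schedule, which accelerates: increments grow linearly with `k`;
7. returns `X_P` to `X_U` and clears it.

The loop stops when no unlabeled work remains, when a manual budget is
exhausted, or at `max_iterations`. "No unlabeled work" includes draining
a nonempty pool after `X_U` empties: those labels were already paid for,
so the loop keeps converting them into training data rather than
stranding them.

When both quotas cannot be honoured (the ranking is shorter than
`N_pseudo + K`), the manual quota wins and the pseudo quota shrinks —
annotation is the budgeted resource the framework optimizes. A final
partial iteration annotates whatever remains.

Defaults: `K = ⌈0.05 · N_train⌉`, `p(0) = 0.05`, `δ = 0.01`,
`p_max = 0.95`, all exposed in `LoopConfig`. Randomness (initial draw,
pool draws, random-selection arm) flows from one seeded generator, so
runs are bit-reproducible.

### Cost accounting

`manual_count` increments only on oracle charges — never on pool draws or
pseudo labels. Annotation percentages divide by the number of
*pre-augmentation* originals (augmentation groups), because a pool draw's
label was implied by an annotation already paid for. Note the corollary:
the plain loop pays per augmented image, so on a six-fold augmented
training set its percentage can exceed 100%. That is not an accounting
bug; it is precisely the redundant spending the image pool eliminates,
and plotting both variants on this common axis makes the saving visible.

## Preprocessing chain

Order: spectral window subset → `log10` → per-channel standardization →
bilinear resize → (training only) augmentation.

* Channel selection keeps every 5th channel of the 1-based inclusive
  window [470, 820] — `⌊(820−470)/5⌋ + 1 = 71` channels of a 1002-channel
  cube. For synthetic cubes with shorter spectral axes the same
  *fractional* window is used (`scaled_preprocess_config`), so the
  informative bands keep their relative position.
* The log transform is `log10(max(v, 1.0))`: transmittance counts span 0
  to tens of thousands, with specular hot spots far above the informative
  range; the clip floor makes the transform total on sensor zeros, which
  carry no information at the low end.
* Standardization is per image, per wavelength channel (the statistics
  are this cube's own spatial mean and variance, not dataset-wide);
  channels with variance below 1e-12 map to zeros. A consequence worth
  stating: every channel of a standardized cube has mean 0 and variance 1
  by construction, so *purely spectral* (spatially flat) class
  differences cannot survive this step — class information must live in
  spatial-spectral structure. Standardizing before the resize keeps the
  statistics exact on original pixels.
* Resize is pure bilinear interpolation (no anti-aliasing), applied per
  channel, to 32 × 32.
* Augmentation is the five deterministic transforms (vflip, hflip,
  rot90/180/270) plus the original: exactly 6×, all variants sharing the
  parent's group id and hence its label. No stochastic augmentation.

## Classifier backends

The full-scale system trains a residual network; its buildable
description is `ArchitectureSpec`: a first channel-mixing convolution,
27 residual blocks in three stages of nine (16/32/64 filters, stride 2 at
stage boundaries — the canonical small-image residual layout), batch norm
before each ReLU, global average pooling, a softmax head, cross-entropy
loss and a momentum optimizer (momentum 0.9, initial learning rate 0.1,
batch 32 — exposed, since the precise variant is a free design choice).

Day-to-day, the loop runs on the **reference classifier**, a
deterministic nearest-prototype model fast enough for CPU-only testing.
Its per-cube feature has three blocks:

1. *common-pattern loadings*: project each channel onto the cube's
   centered, unit-norm cross-channel mean map — on raw cubes this is a
   scaled mean transmittance spectrum;
2. *residual covariance*: remove that common pattern from every channel
   and take the channel × channel second-moment matrix of the residual,
   trace-normalized — a region-covariance descriptor. An interior region
   whose spectral contrast differs between classes appears here as a
   rank-one component with no sign ambiguity, and the descriptor survives
   per-channel standardization (see above) because it measures
   cross-channel spatial structure;
3. *orientation probe*: project each channel onto one fixed spatially
   asymmetric template.

Block 3 deserves explanation. Any feature built covariantly from the
image alone is *exactly* invariant under the five flip/rotation
transforms, so all augmented variants of a sample would receive identical
posteriors and tie in every certainty ranking; the bottom-`K` selection
would then consume whole augmentation groups at once, and the image pool
would starve. A trained network has no such exact symmetry. The probe,
together with a small content-keyed logit perturbation
(`logit_jitter = 0.05`, a fixed pseudo-random draw seeded from the
feature bytes — the same cube always gets the same perturbation), plays
the role of the network's SGD-induced asymmetry while keeping prediction
bit-reproducible and batch-order independent.

Fine-tuning semantics: a warm-started fit recomputes the prototype of
every class present in the batch and keeps the previous prototype only
for classes the batch lacks — the prototype analogue of fine-tuning a
network to convergence on the current training set. (Literal running
averages were rejected: they let early pseudo-label mistakes contaminate
prototypes permanently, which no converged fine-tune does.) Prediction is
a softmax over negative squared prototype distances scaled by the batch's
within-class scatter; temperature rescales logits without changing any
per-sample class ranking.

The **scripted backend** replays a fixed table of posteriors and trains
nothing; all bookkeeping, ledger and schedule tests run against it, so
loop logic is verified independently of any learning.

## Synthetic data

Each specimen is an elliptical mask on a dark background (ambient floor
50 counts — stray light/dark current, which also keeps the log transform
off its clip floor), times a smooth base transmittance spectrum, times
`exp` of log-normal pixel noise; a small fraction of pixels (0.1%) is
boosted 50–200× to emulate specular hot pixels. The full-scale geometry
is 100–130 px and 1002 channels (wavelength axis 328.82–1113.54 nm).

Class identity lives in the interior: a "pulp" blob whose absorption
contrast against the rim has a class-shared dip (−0.35 log10 units at
fractional wavelength 0.65) plus a class-specific band
(0.12·`separation` log10 units, centers 0.55/0.75, width 0.08). At
`separation = 0` the classes are generatively identical and any
classifier is at chance. This interior signal is deliberately
spatial-spectral so it survives standardization; a purely spectral class
difference would be erased by the preprocessing (see above) — a mask ×
spectrum factorized generator cannot produce a learnable task under this
chain.

Specimen-to-specimen heterogeneity has three knobs, all config-exposed:
`amplitude_jitter` (log-normal amplitudes of the shared/specific bands,
defaults 0.2/0.12), `spectral_jitter` (three narrow random absorption
wiggles per specimen, sd 0.06), and `geometry_jitter` (blob and outline
position/size jitter). Together they make single specimens unreliable
class exemplars while class averages separate cleanly — which is what
gives annotation count a visible effect on accuracy.
`SynthConfig.separable()` zeroes all heterogeneity and the hot pixels
(separation 3, pixel noise 0.1): the preset behind every
"well-separated" claim, on which the reference classifier's decision
rule tests at ≥ 0.95 accuracy. `degrade_separation_sweep` regenerates the
dataset along a separation grid and reports baseline accuracy — the
calibration utility used (once) to fix the constants above.

The simulated oracle returns the manifest's hidden label, charging one
annotation per `label()` call and nothing for `free_label()`; optional
label noise is a per-sample flip decided at construction, so the oracle
stays deterministic per id.

## Benchmark problem sizes

The multi-seed annotation-budget study runs at a reduced size chosen so a
five-arm, ten-seed comparison completes in minutes on one CPU: 2 classes
× 60 specimens, 40–50 px cubes, 120 spectral channels (fractional window
→ 9 selected channels), 6× augmentation (576 training images, 96
originals), `K = ⌈0.05·576⌉ = 29`. Every structural property of the
full-scale pipeline is preserved; only the array sizes shrink. Unit tests
use the same geometry with fewer specimens. The full 1002-channel
geometry is exercised per-cube (generation → chain → 32×32×71) rather
than per-dataset.

On these conditions, measured over seeds 0–9: the image-pool loop reaches
the fully annotated baseline's accuracy strictly cheaper than the plain
loop in 8/10 seeds (the other two are ties in which the initial 5%
annotation already matches that seed's baseline), and each uncertainty
criterion reaches baseline at most as expensively as random selection in
10/10 seeds. `scripts/acceptance.py` recomputes all of this.

## Numerical and degenerate-input choices

* Certainty criteria: entropy uses the natural log (base only rescales
  scores, never rankings) and the convention `0·ln 0 = 0`; probability
  rows must sum to 1 within 1e-6. Ranking is a stable descending sort
  with ties broken by original id order.
* A fit on a single-class batch needs an explicit class count (otherwise
  it is rejected); classes never seen by a fit predict with a distance
  beyond any observed one.
* ENVI I/O: float32 BSQ on write; BSQ/BIL/BIP and the common integer and
  float data types on read; truncated payloads and unknown interleaves
  are errors, a missing wavelength block is not.
* Cube stages only advance (raw → channel-selected → log → normalized →
  resized); every operation checks its input stage, so chain-order
  mistakes fail loudly.
* CSV outputs fix the float format (`%.6f`), making reruns with one
  config and seed byte-identical.

## Known limitations

* The reference classifier is a test double for the residual network: it
  reproduces the loop-relevant behaviours (probabilistic outputs,
  fine-tuning, augmentation asymmetry) but not a CNN's representation
  learning; absolute accuracies on real data would differ. No deep
  backend ships with the package.
* The generator emulates the statistical shape the algorithms consume,
  not fruit optics (no scattering or pigment absorption models); passing
  tests demonstrate algorithmic behaviour, not detection performance on
  real produce.
* Hot pixels at the default rate measurably perturb the trace-normalized
  covariance block on otherwise easy tasks; the reference classifier
  applies no outlier rejection, mirroring the preprocessing chain, which
  also has none.
* Per-image (not dataset-pooled) standardization statistics are a
  deliberate reading of an ambiguous step; the alternative pooled
  variant is not implemented.
* Reach percentages are resolved at `K`-sized increments; with
  `K = ⌈0.05·N⌉` two arms can tie at the same grid point even when their
  underlying curves differ.
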