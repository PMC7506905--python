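# alcube

Cost-effective active learning for hyperspectral image cubes: uncertainty
sampling with a pseudo-labeling curriculum, plus an augmentation-aware
"image pool" that turns data-augmented copies of an annotated sample into
free labels.

## The problem

In agricultural and biomedical imaging, images are multichannel cubes
(here: hyperspectral transmittance cubes, `H x W x C` with `C` on the
order of 1000 wavelength channels) and ground truth is expensive — e.g.
internal fruit damage can only be confirmed destructively, by cutting the
specimen. A classifier that needs every training image hand-annotated is
therefore costly to build. Pool-based active learning attacks this by
letting the current model choose which images a human should annotate
next, and pseudo-labeling lets the model annotate the easy ones itself.

## The method

In iteration `k`, the classifier (state `W(k)`) assigns every unlabeled
image `x_i` class posteriors `p(y_i = j | x_i; W(k))`. Three certainty
scores `C_i(k)` are supported — higher always means *more* certain:

* least confidence: `C_i = max_j p_ij`
* margin: `C_i = p_(1) - p_(2)` (top-two posterior gap)
* entropy: `C_i = Σ_j p_ij ln p_ij` (negative Shannon entropy)

For binary problems the three are equivalent: each is a monotone function
of `|p_i1 - 0.5|`.

Each iteration sorts the unlabeled pool `X_U` by certainty, pseudo-labels
the top `N_pseudo(k) = ⌊N_train · p(k)⌋` images with the model's argmax,
sends the bottom `K` to the annotation oracle (charged), fine-tunes on
`X_M ∪ X_P`, and grows the pseudo fraction by the stride schedule
`p(k+1) = p(k) + δ·k` (capped). Pseudo labels are transient: they return
to `X_U` and are re-derived from the newer model next round.

The image-pool variant additionally exploits augmentation groups. Each
training image is expanded six-fold (vertical flip, horizontal flip,
90/180/270-degree rotations), and all six variants share one true label.
When an image is manually annotated, its still-unlabeled associates are
banked in a pool; once the pool holds `K` images, the next iteration draws
`K` of them at random *instead of* paying the annotator. The manual-
annotation ledger counts only oracle charges, so the learning curve
(accuracy vs. percent of the original training set manually annotated)
shows directly how much human effort the pool saves.

The package also provides the full preprocessing chain for transmittance
cubes (spectral window 470–820 subsampled every 5th channel: 1002 → 71
channels; `log10` dynamic-range compression; per-image per-channel
standardization; bilinear resize to 32×32), a declarative spec of the
27-residual-block CNN the full-scale system would train, a fast
deterministic reference classifier so everything runs on one CPU, and a
synthetic generator that emulates the statistical structure of a
two-class fruit-transmittance dataset (class-dependent interior contrast
spectra, specimen heterogeneity, reflective hot pixels) together with a
simulated annotation oracle.

## Worked example

```bash
alcube synth --n-per-class 20 --n-channels 120 --size 40 50 --seed 1 --out raw
printf 'first_channel = 56\nlast_channel = 98\nstep = 5\ntarget_size = 32\n' > prep.cfg
alcube preprocess --manifest raw/manifest.csv --config prep.cfg --out proc
alcube run --manifest proc/manifest.csv --algorithm alg2 --criterion en --seed 1 --out run_alg2
```

prints

```
wrote 40 cubes and manifest.csv to raw
wrote 192 train + 8 test cubes to proc
alg2/entropy: 20 iterations, manual_count=103, accuracy=0.7500
```

The first command draws 40 synthetic cubes (two classes, 40–50 px,
120 channels) with hidden ground truth; the second pushes them through
the preprocessing chain and expands the 32 training originals six-fold to
192 images. The loop then runs the image-pool variant with the entropy
criterion: it finishes after 20 iterations having charged the simulated
annotator 103 of the 192 training images, at test accuracy 0.75 (8 test
images at this toy size). `run_alg2/curve.csv` holds the learning curve —
its first rows

```
k,manual_count,manual_pct,accuracy
0,10,31.250000,0.375000
1,20,62.500000,0.625000
2,20,62.500000,0.500000
```

show the cost ledger in action: percentages are relative to the 32
pre-augmentation originals, and iterations where `manual_count` does not
move are free pool draws.

The same experiment is available programmatically
(`alcube.experiments.annotation_experiment`), including the baseline
model (whole training set annotated), the plain-loop arm, and the
random-selection control.

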