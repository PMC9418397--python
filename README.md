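# thermofoot

Grading of plantar thermograms for diabetic-foot screening. The package
implements the full workflow around the angiosome-based **thermal change
index (TCI)**:

1. **I/O and preprocessing** (`thermofoot.core`) — read/write per-foot
   temperature matrices (headerless CSV, degC), segment the foot from the
   ambient background, and encode thermograms for a network in three input
   formats: `resized` (227x227), `padded` (227x227 canvas, native scale) and
   `rectangular` (180x80).
2. **Index and severity class** (`thermofoot.angiosomes`) — partition the
   foot into the four plantar angiosomes (MPA, LPA, MCA, LCA), compute
   regional mean temperatures, the TCI (mean absolute deviation from the
   control references 25.8 / 25.7 / 26.4 / 26.1 degC) and a six-way label:
   class 0 for control feet, classes 1-5 for diabetic feet by TCI bins
   (<=2, 2-3, 3-4, 4-5, >5, upper bounds inclusive).
3. **Synthetic phantoms** (`thermofoot.synthetic`) — foot-shaped temperature
   fields with the symmetric "butterfly" arch pattern for controls and
   per-angiosome warming solved so the analytic TCI hits an exact target for
   each diabetic grade; every downstream stage is testable without the real
   dataset.
4. **Imbalance handling** (`thermofoot.balancing`) — inverse-frequency class
   weights, offline augmentation to a common per-class target count
   (rotation, zoom, flip, shear, crop), and online per-batch augmentation
   (brightness, contrast, blur, small affine). Applied to training splits
   only; augmented copies inherit their source's label and never cross folds.
5. **CNN classifier** (`thermofoot.classifier`, `thermofoot.network`) — a
   small convolutional network with rectangular 180x80 single-channel input
   (conv/pool blocks, dropout, dense, softmax over 5 or 6 classes), built on
   a self-contained NumPy engine (im2col convolutions, Adam, class-weighted
   cross-entropy). No GPU or deep-learning framework required.
6. **Evaluation** (`thermofoot.evaluation`) — stratified k-fold splits,
   confusion matrices and one-vs-rest per-class accuracy / specificity /
   sensitivity / precision / F-measure with macro averaging.
7. **Pipeline + CLI** (`thermofoot.pipeline`, `thermofoot.cli`) —
   orchestration with provenance, logging and per-stage file interfaces.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes a seed-pinned end-to-end training run (a few minutes on
one CPU); everything else finishes in seconds.

## CLI

```sh
# generate a synthetic cohort
thermofoot simulate --outdir out/cohort --per-class "0=10,1=20,2=8,3=6,4=5,5=4" --noise-sd 0.1 --seed 1

# grade it (regional means, TCI, class per foot + histogram)
thermofoot label --manifest out/cohort/manifest.csv --out out/labeling.csv

# full workflow from a config file
thermofoot run --config config.yaml --outdir out/run --seed 1
```

Minimal `config.yaml`:

```yaml
seed: 1
simulate:
  per_class: {0: 10, 1: 20, 2: 8, 3: 6, 4: 6, 5: 6}
  noise_sd: 0.1
folds: {k: 5}
training: {epochs: 30, batch_size: 32, learning_rate: 0.001}
```

Other subcommands (`split`, `balance`, `train`, `evaluate`, `report`) replay
individual stages from the file artifacts of a previous stage. Externally
acquired matrix-format cohorts can be used by pointing `label`/`run` at a
manifest CSV with columns `subject_id, side, group, path` (paths relative to
the manifest, one headerless CSV temperature matrix per foot).

## Conventions

- Temperature matrices: rows anterior -> posterior (row 0 at the toes),
  columns medial -> lateral for a right foot, mirrored for a left foot.
- Background pixels are stored as ambient temperatures (not NaN); the foot
  mask separates foot from background.
- Normalization window defaults to 18-40 degC and is configurable
  everywhere (acquisition systems differ in their temperature ranges).
- The angiosome geometry is parameterized by a calcaneal length fraction
  (default 0.27) and a medial width fraction (default 0.5) over the foot's
  bounding box.
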