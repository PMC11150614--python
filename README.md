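# vesselseg

Retinal vessel segmentation with a dual-branch CNN/transformer network
and vessel-density quantification for longitudinal follow-up.

The segmentation encoder couples two heterogeneous representations of
the same fundus image: a hierarchical CNN branch (residual bottlenecks,
local detail) and a transformer branch (token sequence with a class
token, long-range context), exchanged through bidirectional fusion
blocks (1×1 projection + re-sampling + additive merge + normalisation).
Training uses the compound TopK + Dice objective on random rotated
patches; evaluation reports Acc/SE/SP/F1/AUROC inside the camera FOV
with bootstrap confidence intervals. A seeded phantom generator
(disc FOV, branching vessel trees, illumination gradient, sensor noise)
makes the whole pipeline runnable and testable without external
datasets, including simulated vascular constriction for the
vessel-density ratio R = N_v / (N_non − N_v).

Everything runs on plain numpy: the package ships its own small
autograd engine and layer library (`vesselseg.nn`), so no deep-learning
framework is required.

## Tests

```bash
python -m pytest tests/
```

The suite includes finite-difference gradient checks for the autograd
engine, oracle tests for the losses and metrics, architecture
contracts, and an acceptance module that trains the CPU desk preset on
16 seeded phantoms (a few minutes per training run on one core).

## CLI

```bash
# generate a seeded phantom dataset in DRIVE-style layout
vesselseg make-phantoms --out data/phantoms --n-train 16 --n-test 4 --seed 0

# train the desk preset (or pass --config train.yaml)
vesselseg train --root data/phantoms --out runs/desk --seed 0

# evaluate on the test split: writes report.{md,csv,json}
vesselseg evaluate --checkpoint runs/desk/checkpoint.npz \
    --root data/phantoms --out runs/desk/eval

# segment a single image
vesselseg predict --checkpoint runs/desk/checkpoint.npz \
    --image data/phantoms/test/images/phantom_01000.png --out preds/

# vessel-density ratio across visits (masks ordered by visit)
vesselseg quantify --masks visit1_mask.png --masks visit2_mask.png
```

Real datasets (DRIVE, CHASEDB1, STARE, HRF) are read from
`root/{training,test}/{images,masks,fov}/` or a flat
`root/{images,masks,fov}/` layout with the conventional split rules
(CHASEDB1: final 8 test; STARE: 10/10 or leave-one-out; HRF: 15/30 with
two-fold downsampling). See `vesselseg.data_io` for details.

## Configuration

Training and model configs are YAML files mirroring the
`TrainConfig`/`ModelConfig` dataclass fields, e.g.

```yaml
lr0: 1.0e-4
batch_size: 16
patch_size: 118
iterations: 2000
loss: {k_percent: 10.0}
model:
  backbone_name: resnet50
  n_trans_blocks: 12
  embed_dim: 384
  n_heads: 6
```

The `tiny`/`desk` presets (used throughout the tests) are available as
`ModelConfig.tiny()` and `TrainConfig.desk()`.
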