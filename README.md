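# swindiff

A denoising diffusion probabilistic model for 2D medical image synthesis,
built around a U-shaped denoiser that mixes residual convolutional blocks at
high resolution with shifted-window (Swin) transformer blocks at low
resolution. The reverse process learns both the noise field and a per-pixel
variance-interpolation coefficient, trained with a hybrid objective
(noise MSE + a down-weighted variational term), and samples with
spaced-timestep respacing. A four-metric evaluation suite (IS, FID, FDS, DS)
compares real and synthetic image sets.

The whole stack runs on plain numpy: the network and training loop sit on a
small reverse-mode autodiff engine (`swindiff.nn.autograd`), so no GPU or
deep-learning framework is required. A seeded phantom generator provides
anatomy-like toy images, making every component testable offline at desk
scale.

## Layout

| module | contents |
| --- | --- |
| `swindiff.diffusion` | noise schedule, forward corruption, Bayes posterior, noise-to-mean substitution, log-interpolated variance, hybrid loss |
| `swindiff.nn` | autograd engine, layers, the U-shaped Swin denoiser |
| `swindiff.sampler` | spaced-chain construction and reverse-diffusion generation |
| `swindiff.trainer` | AdamW loop (lr 2e-5, wd 1e-4, batch 8 defaults), checkpoints, loss trace |
| `swindiff.metrics` | IS / FID / FDS / DS with pluggable feature extractors |
| `swindiff.dataio` | PNG/NIfTI I/O, modality normalization (x-ray, MRI, CT), geometry conforming |
| `swindiff.phantom` | seeded ellipse-phantom generator |
| `swindiff.cli` | `swindiff` command with `train`, `sample`, `evaluate`, `make-phantoms` |

## CLI

```bash
# make a toy dataset
swindiff make-phantoms --n 64 --side 32 --seed 1 --out-dir data/phantoms

# train (YAML holds 'network:' and 'train:' sections; flags override)
swindiff train --data-dir data/phantoms --modality phantom \
    --config configs/tiny.yaml --out-dir runs/toy --seed 3

# generate with 500 spaced steps (the default) from a checkpoint
swindiff sample --checkpoint runs/toy/checkpoint_final.npz \
    --n 16 --steps 500 --seed 11 --out-dir runs/toy/samples

# IS / FID / FDS / DS between two directories
swindiff evaluate --real-dir data/phantoms --synth-dir runs/toy/samples \
    --extractor toy --seed 4 --report runs/toy/report.json
```

Every command writes a `run_manifest.json` (resolved config, seed, paths);
rerunning with the same seed reproduces all outputs byte-for-byte.

Full-scale defaults are T = 4000 with beta_t = 5e-6 t, 250 epochs, 256x256
inputs and the 2 conv-down + 4 swin-down encoder / 3 middle / mirrored
decoder plan; the `reduced` depth preset and small `base_channels` keep
desk-scale runs tractable (see `configs/tiny.yaml`).

The `inception` feature extractor for IS/FID requires torch/torchvision and a
pretrained network download; offline, use the `toy` (phantom-trained
classifier) or `random` (seeded projection) extractors.

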