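# mindfuse

Multimodal behavioural feature extraction, attention-weighted fusion, and
multi-indicator SVM screening.

The toolkit turns three behavioural streams per subject into a screening
decision for ten binary mental-health indicators (somatization,
obsessive-compulsive, interpersonal sensitivity, depression, anxiety,
hostility, dreadness, crankiness, psychopathy, other):

1. **Keypoint features** — face (68 landmarks/frame) and gait (18
   joints/frame) streams in the OpenPose output convention are validated,
   gap-interpolated, segmented (30 s face / 8 s gait), and converted to one
   displacement-magnitude series per landmark.
2. **Voice features** — WAV audio is Wiener-denoised, cut into 1 s
   segments, and reduced to 17 per-frame descriptors: short-time energy,
   cepstral pitch (0 = unvoiced), three LPC-root formants, and 12 MFCCs.
3. **Temporal statistics** — each channel series is summarized by a
   configurable statistic set (default: mean, std, skewness, kurtosis),
   giving 68×4 / 17×4 / 18×4 modality matrices.
4. **Attention fusion** — modality descriptors are compared to a shared
   query via dot / cosine / bilinear / scaled-dot similarity; a softmax
   yields three weights that scale the blocks before stacking them into a
   103×4 fused matrix (412-D flattened).
5. **Classification** — ten independent Gaussian-kernel soft-margin SVMs
   (binary relevance, C = 1, sigma from the d·Var "scale" heuristic).
6. **Evaluation** — accuracy / precision / recall / F1 per indicator from
   pooled out-of-fold predictions (stratified 5-fold), plus an 8-condition
   modality-ablation grid (F, V, G, pairs, tri-modal, tri-modal+attention).
7. **Synthetic cohorts** — a fully seeded generator (source–filter voice
   with planted f0/formants, sinusoidal keypoint motion with
   label-dependent amplitudes) makes everything testable offline.

## Test

```bash
python -m pytest tests/          # full suite incl. acceptance (~3 min)
```

## CLI

```bash
# generate a synthetic cohort and run the full pipeline on it
mindfuse simulate --out cohort/ --n 40 --seed 1 --effect 2.0
mindfuse run --data cohort/ --out report/

# individual stages
mindfuse keypoints extract --modality face --fps 25 --in seq.json --out channels.csv
mindfuse audio extract --in voice.wav --out features.csv
mindfuse stats --in channels.csv --out matrix.csv
mindfuse fuse --face f.csv --voice v.csv --gait g.csv --out fused.csv
mindfuse train --features X.csv --labels y.csv --out model.bin
mindfuse predict --model model.bin --features X.csv --out preds.csv
mindfuse evaluate --data cohort/ --condition "(F+V+G)att"
mindfuse ablation --data cohort/ --seed 42 --out report/
```

Configuration is YAML with strict key checking; see
`mindfuse.config.DEFAULTS` for every key (audio framing, statistic set,
similarity mode, SVM parameters, CV folds/seed, simulator settings).

## Layout

```
src/mindfuse/
  keypoints.py   keypoint I/O, validation, segmentation, channel series
  audio.py       WAV I/O, Wiener denoise, framing, energy/pitch/formants/MFCC
  stats.py       time-domain statistics, modality feature matrices
  fusion.py      similarity, softmax attention weights, fused features
  classify.py    Gaussian kernel, 10-SVM bank, persistence
  evaluate.py    confusion metrics, cross-validation, ablation grid
  synth.py       synthetic cohort generator
  pipeline.py    cohort loading and end-to-end wiring
  config.py      YAML config with defaults and strict validation
  cli.py         `mindfuse` command-line interface
```
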