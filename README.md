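# crossadapt

Analysis tools for **cross-feature adaptation** in visual cortical
population recordings: how brief exposure to a stimulus on one feature
axis (say, an oriented grating) reshapes single-neuron tuning and
population coding of an *orthogonal* feature (say, color), both during
free viewing and passive fixation.

The package is written for systems neuroscientists who record
populations (e.g. multi-electrode arrays in mid-level visual cortex)
and want a tested, reusable implementation of this analysis chain:

- **Image features** — Sobel-gradient orientation histograms of image
  patches, the orientation selectivity index
  `OSI = |Σ_b h_b e^{2iθ_b}| / Σ_b h_b`, and classification of patches
  as *oriented*, *colored* (RGB channel-peak criteria with threshold
  Δ = 30) or *neither*.
- **Scanpath simulation** — pseudo-saccades sampled from empirical
  amplitude/direction distributions, chained over images to tally how
  often successive fixations land on patches of dissimilar features
  (iso- vs cross-feature saccades).
- **Eye events** — fixation detection by a 100 deg/s velocity
  threshold on 1 kHz gaze traces, extraction of unadapted/adapted
  pseudo-trials from quadrant fixation sequences, receptive-field
  confinement filtering, and covariate confound checks.
- **Tuning** — circular selectivity index
  `CSI = |Σ_i r_i e^{iφ_i}| / Σ_i r_i` (angles doubled for
  180°-periodic orientation data), a dispersion-calibrated Rayleigh
  test, preferred angle, sliding-window (200 ms / 5 ms) tuning
  timecourses with Holm-Bonferroni correction, and tuning latency.
- **Population statistics** — stimulus-wise pairwise noise
  correlations; the projected-PC variance ratio (PCs fitted to the
  unadapted condition, both conditions projected, per-axis
  unadapt/adapt variance ratio averaged over the components capturing
  90% of unadapted variance, with subsampled error bars); and
  cross-validated linear-discriminant decoding of neighboring stimuli
  reported above the 50% chance level.
- **Synthetic data** — von Mises-tuned populations with
  low-dimensional shared variability and controllable adaptation
  effects (rate gain, tuning sharpening, shared-variance shrink,
  latency shift), patch-structured scenes, and free-viewing eye traces
  with ground truth, so every analysis is testable by parameter
  recovery.

See `docs/methods.md` for models, parameter choices and limitations.

## Worked example

Run a passive-fixation adaptation session on synthetic data carrying
the canonical effect configuration (−3.3% rate gain, tuning-sharpening
κ-boost 0.5, shared-variance shrink 0.7):

```python
from crossadapt import synthetic_data as synth, pipeline

cfg = synth.adaptation_effect_config(seed=1)
report = pipeline.run_fixation(cfg, decode_iterations=150, n_pca_reps=30)
for k in ("delta_csi_mean", "delta_firing_rate_pct", "pc_mean_ratio",
          "decode_above_chance_unadapt", "decode_above_chance_adapt"):
    print(k, round(report.summary[k], 3))
```

prints

```
delta_csi_mean 0.031
delta_firing_rate_pct -4.855
pc_mean_ratio 1.118
decode_above_chance_unadapt 12.627
decode_above_chance_adapt 15.51
```

Read: after adaptation to the orthogonal feature, the mean color
selectivity index rose by 0.031 while peak firing rates *fell* by
4.9%; the population variance along the unadapted PC axes dropped
(unadapt/adapt ratio 1.118 > 1, i.e. the population decorrelated); and
decoding of two neighboring color stimuli improved from 12.6 to 15.5
percentage points above chance. Improved coding with decreased rates
and reduced shared variability is the signature pattern of
cross-feature adaptation.

The same drivers run the other experiments:

```python
report = pipeline.run_freeview(pop_cfg, eye_cfg)   # free-viewing session
report = pipeline.run_scenes(n_images=20)          # scanpath statistics
```

or from the shell:

```bash
crossadapt fixation --seed 1 --out-dir out/
crossadapt scenes --seed 1 --n-images 20 --out-dir out/
```

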