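# actibrain

Estimating regional gray-matter volumes from wrist-worn accelerometer data.

Structural MRI is the reference standard for measuring brain atrophy in
cognitive decline, but it is expensive and episodic. Wearable activity
monitors are cheap and continuous, and rest–activity patterns carry
information about brain health. `actibrain` implements, as a tested and
reusable pipeline, a procedure for modelling the volumes of 116 anatomically
labelled brain regions (AAL parcellation: 90 cerebral, 18 cerebellar
hemisphere, 8 vermis) from per-minute activity counts:

1. **Preprocessing** — per-minute counts (1,440 epochs/day; triaxial devices
   collapsed by the vector magnitude √(x²+y²+z²)) are standardized, nighttime
   (21:00–09:00) is removed because subjects take the device off at bedtime,
   and days with a missing run longer than 30 consecutive minutes are
   excluded, leaving 720-point daytime segments.
2. **Autoencoder features** — a 1-D convolutional autoencoder
   (720 → 240 → 120 → 60 time steps, ReLU, Adam, RMSE objective, 8:1:1
   subject-level train/validation/test split) is trained to reconstruct day
   segments; the encoder's C×60 latent is averaged over channels and over a
   subject's days to give **60 features** per subject.
3. **Time-frequency features** — a short-time Fourier transform (60-min
   Hamming window, 50 % overlap, 256-point transform, 1 sample/min) gives a
   129-bin magnitude spectrogram; time-averaged magnitudes with the DC bin
   dropped (128 indices) are pooled in consecutive pairs to **64 features**.
4. **Regional models** — each region's volume, residualized for age, sex,
   total intracranial volume and education, is regressed on the features with
   backward elimination (drop the least significant feature until all
   retained p < α = 0.05). Each model's in-sample Pearson r and R² are
   recorded; the 116 model F-test p-values are controlled with the
   Benjamini–Hochberg procedure at FDR q = 0.05.
5. **Lobe summaries** — per-lobe mean (SD) of r and R², and paired t-tests
   (Bonferroni-corrected over 9 lobes) comparing the combined
   autoencoder + time-frequency feature set against time-frequency features
   alone.

Original cohort data (population actigraphy for training, memory-clinic
actigraphy + MRI for modelling) are not required: a first-class synthetic
module generates multi-day count series with circadian structure, non-wear
nights and missing runs, and matching volume tables with **stored generating
coefficients**, so the whole pipeline is testable as a parameter-recovery
problem. A caution built into the test suite: at the analysis dimensions
(~132 subjects, 124 candidate features) backward elimination inflates
in-sample correlations substantially even on pure noise, so the high r values
this class of model reports are in-sample quantities, not predictive accuracy.

## Worked example

```python
import numpy as np
from actibrain.synthetic import gen_subject_traits, gen_activity_records
from actibrain.preprocess import preprocess_records
from actibrain.timefreq import tf_features_subject

traits = gen_subject_traits(20, 3, seed=7)
records = gen_activity_records(traits, days_per_subject=7, missing_run_prob=0.2, seed=8)
segments, exclusions = preprocess_records(records)
print(f"generated {len(records)} subject-days; retained {len(segments)}, excluded {len(exclusions)}")

sid = traits.subject_ids[0]
days = [s for s in segments if s.subject_id == sid]
feats = tf_features_subject(days)
print(f"subject {sid}: {len(days)} retained days, tf feature vector length {len(feats)}")
print("first five tf features:", np.round(feats[:5], 4))
```

prints

```
generated 140 subject-days; retained 115, excluded 25
subject S00000: 7 retained days, tf feature vector length 64
first five tf features: [15.5417 10.3848  5.1598  3.1148  3.0462]
```

140 simulated days lose 25 to the >30-min missing-run rule (a 0.2 insertion
probability with run lengths 5–120 min, of which runs longer than 30 min
trigger exclusion); each retained day contributes one 720-point segment, and
the subject's 64 time-frequency features are the day-average of the pooled
spectrogram magnitudes — low-frequency bins dominate because the circadian
profile concentrates power near zero frequency.

The full pipeline (simulate both corpora, preprocess, train the autoencoder,
extract 60 + 64 features, fit 2 × 116 region models, summarize) runs from the
command line:

```bash
actibrain run-all --seed 7 --out run7
```

and writes every intermediate table (segments, features, per-region results,
lobe summaries, feature-set comparison, violin-plot data, run manifest) under
`run7/`. Individual stages are available as `actibrain simulate`,
`preprocess`, `train-ae`, `extract-features`, `fit-regions` and `report`.

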