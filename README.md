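# emgfatigue

Localized muscle-fatigue detection and time-to-fatigue prediction from
surface EMG (sEMG) and elbow-joint kinematics, built as a fully software
pipeline with a synthetic trial generator standing in for the wearable
hardware.

A fatiguing isometric-contraction trial passes through these stages:

1. **`synthetic`** — seeded generator of trial bundles: multichannel sEMG
   whose spectral median frequency declines (and RMS rises) after a
   programmed transition onset, plus a goniometer trace that drifts away
   from the 90° target with growing oscillation.
2. **`preprocessing`** — zero-phase (dual-pass) 5th-order Butterworth
   band-pass of the sEMG, hop-based windowing, rolling angle statistics.
3. **`features`** — per-window composite feature: normalized Welch total
   band power minus normalized instantaneous median frequency; rises after
   the transition to fatigue.
4. **`fuzzy`** — six-rule fuzzy labeller mapping elbow angle and angular
   oscillation onto {NonFatigue, TransitionToFatigue, Fatigue}; provides
   ground truth for training and scoring.
5. **`lda`** — two-class Fisher linear discriminant (y = w·x + w0)
   separating NonFatigue from TransitionToFatigue.
6. **`predictor`** — debounced transition-onset detection, transition
   duration profiling over training trials, and fatigue-time prediction
   (onset + mean training duration).
7. **`pipeline`** / **`cli`** — orchestration, LED-style status stream
   (GREEN/ORANGE/RED), per-subject accuracy and prediction summaries.

## CLI

```bash
# generate a synthetic subject (2 training + 1 testing trial)
emgfatigue simulate --duration 180 --transition 55 --fatigue 150 \
    --seed 1 --out-dir trials/

# train on the two training trials
emgfatigue train --trial trials/synthetic_trial1_training.csv \
    --trial trials/synthetic_trial2_training.csv --out-dir artifacts/

# stream the testing trial: status feed + prediction + accuracy
emgfatigue run --model artifacts/model.json --profile artifacts/profile.json \
    --trial trials/synthetic_trial3_testing.csv --out-dir run/

# multi-subject synthetic evaluation with table-style summaries
emgfatigue evaluate --subjects 5 --seed 1 --out-dir eval/
```

Trials are plain CSV (`time_s, emg_ch1..emg_chN, angle_deg`) with a JSON
sidecar holding the stage timeline and generator config. Models and
profiles serialize to human-readable JSON; run configs to YAML.

## Notes

- The feature's two components (power in units², frequency in Hz) are made
  commensurable before subtraction; modes: causal expanding z-score
  (default, streaming-safe), frozen-baseline z-score, global z-score, or
  raw subtraction.
- The band-pass upper edge is clamped to 0.99× Nyquist when a requested
  edge is unrealizable (e.g. 500 Hz at a 1 kHz sampling rate).
- Ties in fuzzy defuzzification and at the discriminant boundary resolve
  toward the more fatigued class: for a warning device a false alarm is
  cheaper than a miss.
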