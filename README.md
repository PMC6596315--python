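# tonelab

Acoustic analysis and simulation of Mandarin lexical tone (Tone 1 vs.
Tone 4) production and perception, built around a fully synthetic,
seed-reproducible data path so that every analysis stage can be validated
by parameter recovery.

## What it does

**Production side.** Disyllabic utterances (dipping first syllable,
level/rising or falling second syllable) are synthesized from per-speaker
parameter profiles (harmonic pulse-train source, dB-domain intensity
envelopes, log-linear F0 trajectories). The analysis pipeline then:

1. extracts an intensity contour (5-ms hop, 30-ms Hanning RMS),
2. segments the two syllables by peak detection at 20-dB prominence
   (relaxed stepwise when the inter-syllable dip is shallow) and trims
   each syllable at a 20-dB (or 10-dB) cutoff below its intensity peak,
3. tracks F0 by normalized autocorrelation (5-ms hop, 40-ms window,
   amplitude-envelope normalization, octave-glitch removal, median
   smoothing), fits a speaker vocal range (Gaussian on log2-F0 of pooled
   recordings, +-6 st band) and re-tracks each token inside that band with
   two documented fallbacks (voicing threshold 0.45 -> 0.1; band
   expansion to +12/-9 st),
4. computes four descriptors per token: syllable duration ratio,
   intensity peak difference, relative F0 median, and F0 movement
   (last-minus-first 30 ms, semitones), plus 100-point normalized
   contour patterns,
5. fits per-descriptor linear mixed models
   `value ~ contrast * hearing + (1 + contrast | participant)`.

**Perception side.** A 96-token continuum (8 F0 slopes x 6 durations x 2
F0 heights), RMS-equalized, with exact round-trip verification of every
token; simulated 2AFC listeners drawing Bernoulli responses from a
logistic model; a Laplace-approximation logistic mixed model
(`response ~ population * F0drop * log-duration` with per-subject random
intercept + slopes for F0 drop, duration and F0 height) written in-house;
per-subject cue weights (fixed effect + predicted random slope); and
perception-production coupling correlations.

## CLI

```sh
tonelab synth --n-nh 2 --n-ci 2 --reps 3 --seed 1 --out out/audio
tonelab analyze out/audio --out out/descriptors.csv
tonelab continuum --height 220 --sessions 1 --seed 1 --out out/continuum
tonelab simulate-perception --n-nh 35 --n-ci 40 --out out/responses.csv
tonelab fit --descriptors out/descriptors.csv --responses out/responses.csv --out out/fits
tonelab run-all --small --out out/run     # quick end-to-end smoke run
tonelab report out/run
```

## Package layout

| module | contents |
| --- | --- |
| `tonelab.types` | Waveform/Contour/SyllableWindow/VocalRange/descriptor dataclasses |
| `tonelab.synth` | speaker & listener profiles, utterance synthesis, cohorts, response simulation |
| `tonelab.extract` | intensity contour, peak detection, windowing, F0 tracking, vocal range |
| `tonelab.descriptors` | the four production descriptors, normalized patterns |
| `tonelab.continuum` | 96-token grid, token rendering, RMS equalization, round-trip measurement |
| `tonelab.models` | production LME (statsmodels MixedLM), perception GLMM (in-house Laplace), cue weights, coupling |
| `tonelab.pipeline` / `tonelab.cli` / `tonelab.config` / `tonelab.io` | orchestration, CLI, YAML config, WAV I/O |
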