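# eegdenoise

Online, fully automated denoising of **muscle artefacts in single-channel
EEG streams**, with the offline annotator and the evaluation machinery needed
to assess it on data with known ground truth.

Myogenic potentials from jaw, neck or forehead muscles are transient,
broadband (~20–300 Hz, most prominent around 110–140 Hz) and often orders of
magnitude stronger than cortical activity. Offline, multi-channel cleaning
methods (ICA/CCA, FASTER) cannot run in a brain–computer-interface loop;
`eegdenoise` instead processes each channel block-by-block as it arrives:

1. each 1 s window is concatenated to the previous one and decomposed with a
   decimated wavelet filter bank (db4 or sym4), so the left edge escapes the
   cone of influence; the right edge is smooth-padded;
2. the coefficients form a *scaleogram* — a levels × time-slices matrix with
   level `m` normalized by `2^m` — whose columns are slice feature vectors;
3. an **extended isolation forest** (random-hyperplane splits), refit every
   window on a sliding buffer of the last 20 windows' slice vectors, scores
   each new slice by `s = 2^(−E[h]/a(ψ))`; slices with `s > 0.55` are
   anomalous;
4. anomalous slices are attenuated by a Hadamard product with a mitigator
   vector `mtg = 1 − d(a, medoid)/max_dist` derived from the buffer medoid —
   gentle near typical activity, aggressive far from it — applied per scale
   to the raw coefficients, which are then inverted back to the time domain.

The package also provides the offline multi-channel ground-truth annotator
(110–140 Hz Hilbert-envelope z-scores integrated across channels, with a
precision-maximizing threshold sweep validated by a Mann–Whitney test on
30–300 Hz Welch spectra), a per-window SNR / Jensen–Shannon-divergence
evaluation, and a seeded synthetic-EEG generator (1/f background, alpha
rhythm, tapered muscle bursts, optional blinks) with recorded burst truth.

## Worked example

```python
import numpy as np
from eegdenoise import SimConfig, simulate, FrameworkConfig, denoise_stream
from eegdenoise.ground_truth import sweep_threshold
from eegdenoise.evaluation import evaluate_h1, label_windows

sim = simulate(SimConfig(n_channels=4, duration_s=60.0, seed=1))
print(f"injected bursts: {len(sim.true_intervals)}")

result = sweep_threshold(sim.data, 1024.0)
print(f"ideal z-score threshold: {result.ideal_threshold:.1f}, "
      f"annotated intervals: {len(result.final_intervals)}")

cfg = FrameworkConfig(seed=1)          # 1000 ms @ 1024 Hz, db4, ta = 0.55
denoised, records = denoise_stream(sim.data, cfg)
print(f"anomalous slices flagged: {sum(len(r.at) for ch in records for r in ch)}")

labels = label_windows(result.final_intervals, 60, cfg.rtwl_ms)
report = evaluate_h1(sim.data, denoised, labels, cfg.sr_hz, cfg.rtwl_ms)
print(f"JS(A vs Na): original {report.mean_o_a_vs_na:.3f} -> denoised {report.mean_d_a_vs_na:.3f}")
print(f"JS(O vs D):  artefactual {report.mean_a_o_vs_d:.3f} vs clean {report.mean_na_o_vs_d:.3f}")
```

prints

```
injected bursts: 12
ideal z-score threshold: 2.5, annotated intervals: 12
anomalous slices flagged: 4367
JS(A vs Na): original 0.610 -> denoised 0.564
JS(O vs D):  artefactual 0.365 vs clean 0.000
```

The annotator recovers all 12 injected bursts. After denoising, the SNR
distributions of artefactual windows move toward those of clean windows
(mean per-channel Jensen–Shannon divergence 0.610 → 0.564), and denoising
touches almost exclusively the artefactual windows (divergence between
original and denoised SNRs: 0.365 in artefactual vs 0.000 in clean windows).

The same workflow is available from the shell:

```sh
eegdenoise simulate --out rec.f64 --seed 1 --channels 4 --duration 60
eegdenoise denoise rec.f64 --out den.f64 --anomalies at.json
eegdenoise annotate rec.f64 --out events.tsv
eegdenoise evaluate rec.f64 den.f64 --events events.tsv --out h1.json
```

Recordings are read from EDF/BDF (via mne) or from a plain matrix dialect
(raw float64, channels × samples, with a JSON sidecar); annotations are
BIDS-style events TSV/CSV. See `docs/methods.md` for the model, parameter
defaults, numerical choices and known limitations.

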