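# Methods

`eegdenoise` implements a fully automated, block-online denoiser for muscle
artefacts in single-channel EEG, together with the offline annotator and the
evaluation machinery used to assess it. This note records the model, the
defaults, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## The denoising framework

The denoiser is parameterized by the 8-tuple
`<RTWL, Sr, MW, IFS, IFt, Bs, ta, Es>`: window length (ms), sampling rate
(Hz), mother wavelet, isolation-forest sub-sample size and tree count, buffer
capacity (windows), anomaly threshold, and expansion step. The muscle
instantiation defaults to `<1000 ms, 1024 Hz, db4, 512, 100, 20, 0.55, 0>`
(`sym4` and `Es = 5` are the tested alternatives). Each channel is processed
independently, one window at a time:

1. **Windowed DWT.** The current raw window is concatenated to the *previous*
   raw window so its left edge sits mid-signal, outside the cone of
   influence; the right edge (no future data) and the cold-start left edge
   are smooth-padded (linear extrapolation from the edge derivative). The
   padded signal is decomposed with a decimated, periodized orthogonal filter
   bank to depth `M = floor(log2(n / (L - 1)))` (`L` = filter length; `M = 7`
   for 1024-sample windows with db4/sym4). Periodization keeps every level at
   exactly half the length of the level below, so the current window retains
   `n / 2^m` coefficients per level — those whose time centres
   (`j ↦ j·2^m` samples) fall inside it. The full padded coefficient context
   is kept so inversion is exact.
2. **Scaleogram.** Detail rows 1..M plus the approximation row are replicated
   onto a shared axis of `k = n/2` time slices (level `m` replicated
   `2^(m-1)` times). For detection only, row `m` is divided by `2^m` (the
   approximation row by `2^M`) to equalize magnitudes across scales; the
   normalized matrix is never inverted.
3. **Detection.** A FIFO buffer holds the normalized slice vectors of the
   last `Bs` windows (`20 × 512 = 10,240` vectors at the default). For each
   new window an extended isolation forest (random-hyperplane splits; slopes
   standard normal per dimension, intercepts uniform in the node bounding
   box; depth limit `ceil(log2(IFS))`) is refit on the buffer and queried
   with the current window's slices. The anomaly score is
   `s = 2^(−E[h]/a(ψ))` with `a(·)` the average unsuccessful-BST-search path
   length; slices with `s > ta` form the anomalous set `AT`, expanded by
   `Es` neighbours each side (clipped to `[0, k)`).
4. **Mitigation.** The buffer medoid (Euclidean, member minimizing total
   distance, earliest member on ties) represents typical recent activity.
   Each flagged slice `a` receives a mitigator
   `mtg_i = 1 − |a_i − med_i| / max_v |v_i − med_i|`, clipped to `[0, 1]`,
   computed **per scale** on normalized vectors and applied as a Hadamard
   product to the **non-normalized** coefficients. A scalar-ratio variant
   (one Euclidean distance ratio broadcast over scales) is available via
   `mitigator_mode="scalar"`.
5. **Reconstruction.** The mitigated scaleogram is collapsed (first value of
   each replication run), written back into the padded context, inverted,
   and the current window's samples are emitted.

Design points that were genuinely open, and how they were resolved:

- **Per-scale mitigation.** The mitigator is written as a single distance
  ratio but applied as a Hadamard product; the per-dimension form is the
  default because it is what lets one scale be attenuated more than another.
- **Degenerate buffer dimension.** If the buffer never deviates from the
  medoid in some dimension, that dimension carries no evidence and its
  mitigation factor stays 1.
- **Warm-up.** Until the buffer holds `Bs` windows, windows pass through
  bit-exactly; there is no forest to query.
- **Refit cadence.** The forest is refit on the buffer for every window
  (full adaptivity). The buffer stores *pre-denoising* vectors — the stream
  as recorded — and the left-context window is likewise the raw previous
  window (causal recording).
- **Approximation row.** Included in the slice vectors (normalized by
  `2^M`); the inverse transform needs it and the detector should see the
  lowest band.
- **Collapse rule.** When only some replicated copies of a deep coefficient
  are flagged, the collapse keeps the first copy of each run; a flagged slice
  therefore only modifies a deep coefficient when it is the group leader.
- **Anomaly timestamps** are slice indices (2 samples per slice), convertible
  to seconds.

## Performance notes

Tree growing and traversal are numba-compiled (first call per process pays a
one-off compilation cost of a few seconds). The buffer maintains each
member's sum of distances to all other members incrementally across pushes
and evictions, so the exact medoid of 10,240 vectors is an `argmin` rather
than an O(n²) recomputation per window. Full-scale denoising runs at roughly
8 s per channel per 120 s of signal on one CPU core.

## Offline ground-truth annotation

Channels are band-passed to 110–140 Hz (where myogenic activity is most
prominent and cortical power is negligible) with a zero-phase 4th-order
Butterworth, Hilbert-envelope z-scores are summed across channels and divided
by `sqrt(n)`, and the integrated score is low-pass-filtered at 4 Hz.
Supra-threshold runs become intervals; gaps of good data shorter than 0.1 s
are absorbed. Because the z-score threshold is hard to fix a priori, it is
swept from 5.0 to 2.0 in steps of 0.1; at each value the detected intervals
are validated spectrally — an interval is valid when its channel-averaged
Welch PSD bin values over 30–300 Hz are stochastically larger than the whole
recording's (one-tailed Mann–Whitney U, alpha 0.01) — and the earliest
threshold with the strictly best valid/total ratio is kept. Welch uses 0.5 s
Hann segments with 50% overlap; intervals shorter than one segment cannot be
tested and count as invalid. The U-test samples are the PSD frequency-bin
values in the band.

## Evaluation

A window is *artefactual* when it overlaps an annotated interval by at least
one sample. Per-window SNR is defined as
`10·log10(P[1–30 Hz] / P[110–140 Hz])` in dB (Welch, 0.5 s segments): muscle
activity depresses it, denoising should restore it. Per channel, SNR
distributions (histograms on 30 shared bins spanning the pooled range) are
compared with the Jensen–Shannon divergence in base 2 (range [0, 1];
zero-probability bins are smoothed with ε = 1e−12 and renormalized). The
divergence itself (not its square root, the JS distance) is reported. Two
comparisons summarize performance: the A-vs-Na divergence should shrink
after denoising, and the O-vs-D divergence should be much larger in
artefactual than in clean windows.

## Synthetic data: what it emulates, and what it does not

The generator produces per-channel 1/f-shaped Gaussian noise (PSD ∝ 1/f from
1 Hz, steepening to 1/f² above 64 Hz, as real EEG spectra fall faster at high
frequencies) at 10 µV RMS plus a 5 µV random-phase alpha (10 Hz) oscillation.
Muscle bursts are Poisson-placed without overlap (0.2 s minimum gap),
Hann-tapered, 0.4–1.0 s long, at 8× the channel's background RMS, built from
band-limited 20–300 Hz noise with half the power re-shaped into 110–140 Hz;
each burst hits a random subset of at least half the channels, independently
per channel. Optional blinks are half-cosine 100 µV deflections of 0.2–0.7 s
on the two frontal channels (off by default — the instantiation under study
is muscular). Defaults: 8 channels, 120 s, 10 bursts/min (≈20 bursts,
≈12% artefactual samples, honouring the assumption that the buffer is mostly
clean); burst durations sit above the 0.5 s Welch segment so the spectral
validator can certify them. All randomness flows from one seed.

What the generator does **not** emulate: volume conduction and realistic
inter-channel correlation, non-stationary background drifts, electrode pops,
cardiac artefacts, or the heavy-tailed amplitude statistics of real EEG.
Passing the synthetic recovery tests therefore shows that the pipeline's
machinery behaves as designed under its own assumptions, not that the
instantiation attains any particular performance on recorded EEG.

Two behaviours observed on the synthetic streams are worth knowing about.
First, with a tight, artefact-free buffer, roughly the natural score tail
(~1% of slice vectors, genuine 3–5σ excursions) exceeds `ta = 0.55` and
receives mild mitigation; when such a slice happens to lead a deep-level
replication group, a slow-wave coefficient is attenuated and an individual
clean window's power can shift noticeably, while the total power over clean
windows stays within 1%. Second, burst columns already in the buffer inflate
the very dimensions a new burst deviates in, so detection weakens as
contamination grows — the framework's stated buffer-cleanliness assumption
is load-bearing. Hann-taper tails carry almost no artefact energy and are
not expected to be flagged.

## Reduced problem sizes

Unit tests run a reduced geometry (256-sample windows at 256 Hz, 8-window
buffers, 50-tree forests) chosen so every code path — warm-up, eviction,
detection, mitigation, reconstruction — is exercised in seconds; the
study-scale checks (8 × 120 s at the full instantiation, 500-replicate
type-I control of the validator) live in the end-to-end suite.
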