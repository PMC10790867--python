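# Methods

This note documents the models and procedural choices behind `oddbci`: what
the synthetic generator produces and why, the exact conventions of each
analysis stage, and the places where the design was genuinely open.

## 1. Synthetic oddball sessions

The generator (`oddbci.synthetic`) emulates a mobile-EEG oddball session
during a demanding task. It is first-class, tested code — the study
conditions it encodes are the conditions every downstream claim is tested
under.

### Stimulus stream and behavior

- Stimuli: Bernoulli(p_odd = 0.25) odd/standard draws; inter-stimulus
  interval 1.5 s + U(0, 2) s. A session defaults to 565 stimuli
  (≈ 141 odds, ≈ 24 min).
- Odd-trial outcomes: *late* with probability 0.005 (RT > 2 s), otherwise
  *miss* with probability 0.347, otherwise *hit* with RT drawn from a
  normal(789, 100) ms truncated to (0, 2000] ms. Standards trigger a false
  positive with probability 0.010, placed uniformly in (0, 2] s.
- The within-subject RT standard deviation (100 ms) is a free parameter:
  only an across-subject SEM is known for the reference conditions, so a
  typical single-subject spread was chosen.

### Signal model

Each channel (µV, 500 Hz) is a sum of:

1. **1/f background** — per-source spectra shaped as f^(−γ/2) with γ = 1,
   mixed through a random orthonormal matrix (10 µV RMS per channel), plus
   a **shared common-mode** 1/f component at 4× that RMS. The common mode
   plays two roles: it gives neighboring channels the realistic ≥ 0.85
   correlation that reference-derived montages show (and that the
   bad-channel rule assumes), and it cancels exactly under the ear-grid
   bipolar re-reference, mirroring why such derivations are used. A slow
   lognormal amplitude drift (SD 1.5 dB, timescale 10 s) makes the
   background non-stationary, as real EEG is.
2. **Band-limited rhythms** — θ [4–8], α [7–8], β [25–30], γ [30–40] Hz
   components (RMS 3 / 6 / 2 / 1.5 µV), each spatially mixed by its own
   random orthonormal matrix.
3. **Attentional-state modulation** — during each trial (−1…1.5 s around
   the stimulus, with 50 ms ramps) the rhythm amplitudes are scaled by
   per-condition, per-channel dB gains. Defaults: hits θ +1.5 / α −1.0 dB
   (diffuse topography); misses θ −1.5 (frontal-midline), α +2.0
   (posterior-focal), β +1.1, γ +1.5 dB. The direction (misses carry more
   β/γ and α power, less θ) and the β magnitude follow the reference
   findings; the topographies follow the standard frontal-midline-θ /
   posterior-α picture, and making them condition-specific means the two
   states differ in spatial covariance *pattern*, not only in scale —
   which is what gives single-trial covariance classification a
   discriminability comparable to the reported balanced accuracies.
4. **Event-related templates** — per condition and channel, an N1
   (negative Gaussian bump, SD 20 ms, at the configured latency: scalp
   ≈ 106 ms, ear grid ≈ 171 ms for hits) and a P300 (raised-cosine bump
   over 300–500 ms whose window mean equals the configured amplitude,
   e.g. +1.47 µV at Pz for hits, −1.06 µV for misses). Ear-grid templates
   sit on the upper electrodes L1–L4/R1–R4 only, so the bipolar derivation
   recovers them unchanged. Standards get a modest N1 and no P300.
5. **Artifacts** — blinks (300 ms raised-cosine transients, 100 µV,
   front-weighted; 2/min), muscle bursts (> 20 Hz noise at 10× the
   recording's median channel SD, 0.5–1.5 s, on 1–4 channels; 1/min) and
   optional ≥ 5 s flatlines. Ground-truth intervals are returned for
   validation.

All randomness flows through one `numpy.random.Generator`; a seed fixes
schedule, behavior and signal bit-for-bit.

**What the generator does not emulate:** volume-conducted source
topographies (mixing is random, not biophysical), simulator-cab
electromagnetic noise, audio stimulus acoustics, eye movements other than
blinks, and any drift of behavior over time. Passing tests therefore show
that the *analysis chain* behaves correctly under controlled conditions
with realistic amplitude ratios — not that it would produce identical
numbers on any particular real recording.

## 2. Preprocessing conventions

- Resampling by polyphase filtering (`scipy.signal.resample_poly`);
  event times stay in seconds.
- Band-pass: Hamming-window FIR, order 414, designed with `firwin`;
  applied with reflection padding and a shift of order/2 samples, so the
  effective response is zero-phase (component latencies verified unshifted
  to within one sample). [1, 20] Hz for ERP work, [1, 40] Hz for spectra.
- Bad channels: flat ≥ 5 s; best neighbor correlation < 0.85 in more than
  40% of 1 s windows (windowed, so transient artifacts cannot poison a
  whole-recording estimate); high-frequency-to-signal amplitude ratio a
  > 4 robust-z outlier *and* > 0.1 absolutely (the absolute floor prevents
  degenerate z-scores on band-passed data where all ratios are tiny).
  Flagged channels are interpolated: inverse-distance weighting on a unit
  sphere for the scalp montage, adjacent-electrode means on the ear grid
  (spherical geometry is ill-posed on a planar grid). More than half the
  channels flagged aborts the run.
- ASR: 0.5 s windows with 50% overlap and Hann cross-fade. Calibration is
  the quietest ~60 s of 1 s windows by multichannel RMS. Thresholds follow
  the standard formulation: per calibration-PCA component, the windowed
  RMS distribution's robust location + burst_sd × robust scale (MAD-based,
  with a 5% floor to avoid zero-MAD degeneracy); a window component whose
  variance exceeds the threshold projected onto its direction is
  reconstructed from the retained subspace. Directions with near-zero
  calibration variance (e.g., after channel interpolation the data are
  rank-deficient) are never flagged. A recording with > 45% flagged
  windows is marked unusable, mirroring the participant-exclusion rule.
- Epochs are half-open `[start, end)` at 0-based sample indices, onset
  sample included, so an epoch of (−0.2, 1.0) s at 250 Hz has exactly 300
  samples. Baseline correction subtracts the per-channel mean over
  [−200, 0) ms.
- An optional epoch-level rejection (peak-to-peak > 100 µV or kurtosis
  robust-z > 5), disabled by default, stands in for ICA-based component
  rejection: automated component labeling needs a trained network, and ASR
  already removes the burst artifacts that dominate here.

## 3. Features

- N1: most negative sample in [50, 150] ms (scalp) or [120, 220] ms (ear
  grid — its auditory N1 peaks later and no printed window exists for it);
  ties resolve to the earliest latency. P300: mean over [300, 500] ms.
  Pooled derivations: L2+L3 and R2+R3 (ear), Cz and Pz (scalp).
- Welch PSD: floor(0.25 × rate) = 62-sample Hamming segments at 250 Hz,
  no overlap (≈ 4.03 Hz resolution), averaged over segments then trials.
  Band powers average the grid frequencies inside the band; a band
  narrower than one bin (the 7–8 Hz α window) maps to the bin overlapping
  it.
- ERSP: Morlet wavelets via `mne.time_frequency.tfr_array_morlet` with
  c(f) = 3·(f/3 Hz)^0.8 cycles on 40 linearly spaced frequencies in
  [3, 40] Hz, interpolated onto 250 time points in [−442, 938] ms, in dB
  against the condition-pooled mean pre-stimulus power (per channel and
  frequency). The exact cycle-expansion convention and frequency spacing
  behind "expansion 0.8" are not uniquely determined; both are exposed as
  parameters with these defaults. Note the wavelets are long (≈ 0.8 s at
  10 Hz), so power steps smear ~0.3 s into the baseline; calibration
  checks therefore compare post- minus pre-stimulus dB in windows clear of
  the transition.
- Subject-level PSD display normalization (each condition minus the
  across-condition mean spectrum) is provided as a separate helper; it is
  an interpretation of how grand-average spectra are usually displayed.

## 4. Statistics

- d′ uses 1/(2n) clipping with the counts of the respective stimulus
  class; the correction convention was not specified and this is the most
  common one.
- The permutation test is a **group-level paired sign-flip** on
  per-subject condition-mean maps: statistic = across-subject mean
  difference per point; null = independent random sign flips per subject;
  two-sided p with the add-one estimator; BH-FDR at α = 0.05
  (`statsmodels.multipletests`). Group level was chosen because the design
  is within-subject with per-subject averages entering the figures.
  A resolution consequence worth knowing: with N subjects the smallest
  achievable p is 2^−(N−1) (e.g. ≈ 0.0039 at N = 9), so BH over m points
  can only flag an effect cluster of at least ~m·2^−(N−1)/α points, no
  matter how large the effect. Calibration tests size their injected
  windows accordingly.
- Trial-count balancing subsamples every condition to the minimum count,
  without replacement, seeded.

## 5. Classification

- Covariance: Schäfer–Strimmer shrinkage toward diag(S) (the estimator's
  target was not specified; the diagonal/unequal-variance target is its
  common EEG form), with the analytic λ from the variance/misfit ratio,
  clipped to [0, 1].
- Geometry: affine-invariant metric; distances via generalized
  eigenvalues; Fréchet mean by tangent-space fixed-point iteration
  (tolerance 1e-10 on the update norm, ≤ 100 iterations); tangent vectors
  vec the upper triangle with √2 off-diagonal weights, so vector norm =
  geodesic distance to the reference.
- Tomek-link undersampling operates on tangent vectors at the training-set
  mean (the space was unspecified; Euclidean distance in the tangent space
  is the geometry-consistent choice), iterates link removal until balance
  or no links, and finishes with seeded random undersampling. It runs
  inside training folds by default (`balance="pre"` applies it before the
  split for comparability with pipelines that did).
- Analysis channels: the scalp montage drops the three frontopolar
  channels (5 channels → 15 tangent features); the ear grid uses the 8
  bipolar derivations (36 features).
- Descriptor: `covariances_from_epochs` defaults to the plain spatial
  covariance of the −200…1000 ms epoch. The pipeline default adds the
  **ERP-prototype augmentation** (per-class mean waveforms stacked under
  each trial before the covariance). Two details matter there: prototypes
  are recomputed inside each training fold and applied unchanged to that
  fold's test trials (no test-label leakage), and training trials use
  leave-one-out prototypes — a trial contributing to its own class mean
  would acquire a spurious trial-prototype correlation that test trials
  cannot have, which measurably biases the fitted model below chance on
  null data. The augmented descriptor was made the pipeline default
  because with the raw covariance, at realistic signal-to-noise, the
  nearest-centroid classifier slightly outperforms the tangent-space
  classifier on this generator, whereas the augmented descriptor restores
  the tangent-space advantage that evoked-response covariance pipelines
  show; the raw descriptor remains the library default and a flag away.
- Cross-validation: stratified 5-fold, shuffled, seeded; every
  training-derived quantity (reference, scaler, Tomek removals, centroids,
  prototypes) comes from the training fold only. When several classifiers
  are compared, they share the same fold split and balancing draws, so the
  comparison is paired. Logistic regression: L2, C = 1, ≤ 1000 iterations.

## 6. Problem sizes in the checked runs

The acceptance suite and script use 8-subject scalp cohorts of 565 stimuli
(≈ 95 hits / 50 misses per subject entering classification), 500-replicate
null calibrations at 9 subjects × 300 points, and 100–1000-sample oracle
batches for the geometry and estimator checks; these sizes give stable
estimates of every property while keeping a full run in minutes on one
core.

## 7. Known limitations

- The ear-grid montage's bipolar derivations cancel most of the spatially
  shared state modulation this generator produces, leaving its synthetic
  single-trial discriminability near chance; end-to-end classification
  properties are demonstrated on the scalp montage.
- ASR here is the covariance-eigendecomposition variant with fixed
  windowing; it does not implement the Riemannian or windowed-statistics
  refinements of later ASR versions, and bursts shorter than about half a
  processing window may be under-repaired.
- The EDF writer targets the plain-EDF subset this package needs (uniform
  rate, µV, 1 s records, events in a TSV sidecar) and is not a general
  EDF+ implementation.
- Measured N1 amplitudes are biased slightly negative at finite trial
  counts (a min-statistic over a noisy window); the recovery tests use
  bootstrap standard errors, which absorb this at the tested sizes.
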