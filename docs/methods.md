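# Methods

## Signal model

A PR-interval epoch is modelled as the sum of two source-separable parts,

    b_PR(t) = b_HB(t) + b_A(t),

where `b_A` is the atrial activity (P wave and the ramp-like atrial
repolarisation wave, PTa) and `b_HB` the His bundle deflection. The method
rests on two physiological facts: the His deflection is a compact ~100 Hz
event while the atrial components are slow, and the HV interval (His onset
to QRS onset) is nearly constant across beats, so QRS-onset-aligned epochs
place the deflection at a fixed latency.

## Pipeline

Given an aligned epoch stack and a template annotation (T1/T2 markers and
preserve intervals around the deflection on the signal-averaged trace):

1. **Interval-dependent wavelet thresholding.** Each epoch is decomposed
   with `coif5` into five detail levels (symmetric signal extension, the
   MATLAB `wavedec` convention). Detail coefficients are soft-thresholded
   with the fixed-form (universal) threshold `t_j = sigma_j * sqrt(2 ln N_j)`
   except where their time support intersects a preserve interval; a
   level-j coefficient at index k is assigned the support
   `[k*2^j - L_j, k*2^j]` samples with `L_j = (2^j-1)(L-1)+1` the effective
   filter length. Levels 4 and 5 (15.6–62.5 Hz at 1 kHz) carry no His
   content and are zeroed outright; at other sampling rates the zeroed set
   is configurable because the His band lands in different levels. The
   deepest approximation is never touched — the slow ramps it carries are
   the next stage's job. The compiled `ThresholdSpec` is serialisable and
   applied unchanged to every beat.

   `sigma_j` is the robust MAD estimate `median(|d_j|)/0.6745`. By default
   it comes from the template trace itself; the pipeline paths instead pass
   `noise_ref` (the raw epoch matrix) and use the median of per-epoch MADs,
   because the universal threshold is defined against the noise level of
   the signal being denoised and a signal-averaged template understates the
   single-beat noise by ~sqrt(m). Without this, the extracted beats retain
   most of their 150–200 Hz noise and the band-wise SER pattern (His band
   up, P and noise bands down) is lost.

2. **Signal space projection.** The thresholded epochs are over-smoothed
   with a Savitzky–Golay filter, order 3, frame 23 ms (= 23 samples at
   1 kHz; rounded to the nearest odd sample count at other rates). The
   smoother passes cubics exactly and attenuates a 100 Hz component at
   1 kHz to <25%, so the smoothed beats estimate `b_A` alone. Their SVD
   gives an orthonormal atrial basis `U_n`, retained until the cumulative
   squared singular values reach `energy_rule` (default 0.99) and always
   capped at m−1 vectors. Each thresholded epoch is projected onto the
   orthogonal complement, `P_per = I − U_n U_nᵀ`. For epochs up to 4096
   samples the projector is materialised; beyond that the equivalent
   `x − U_n(U_nᵀ x)` form is used. The projector is applied to the
   *thresholded* epoch (the stage order of the extraction chain), not the
   raw one.

## Synthetic study conditions

The generator emulates the evaluation conditions of the method:

| parameter | default | meaning |
| --- | --- | --- |
| `fs` | 1000 Hz | sampling rate (the source recordings are band-limited to 300 Hz, so 1 kHz sampling is the natural desk-scale choice) |
| `epoch_len` | 350 ms | PR window before the QRS onset; covers HV up to 120 ms with a full P wave |
| `p_center`, `p_width`, `p_amp` | 100 ms, 50 ms, 1.0 | Gaussian P bump (sigma = width/3); the P offset at `p_center + p_width` starts the ramp |
| `pta_type` / `pta_ratio` | Type 1 / −1/3 | ramp extreme as a fraction of the P peak: −1/3 (Type 1), +1/2 (Type 2), +0.6 (Type 3, anything > +1/2) |
| `pta_end_frac` | 0.5 | ramp level at the QRS onset relative to its extreme; ≠1 gives the post-His ramp a slope, and multichannel series alternate 0.5/1.5 so its polarity flips across channels |
| `hbs_hv` | 60 ms | His onset to QRS onset |
| `hbs_freq`, `hbs_amp` | 100 Hz, 0.2 | one Hann-windowed sine cycle (10 ms support), downward lobe first; amplitude 1/5 of the P peak keeps the deflection well below the atrial signals, as in measured traces |
| `snr_db` | 20 dB | P-peak over noise RMS; the study sweeps 5–28 dB |

Noise realisations are scaled to the *exact* target RMS
(`p_amp / 10^(snr/20)`), so the realised SNR equals the nominal one for
every epoch; all realisations of a stack share one clean signal and differ
only in noise. The generator does **not** model beat-to-beat variability of
atrial morphology, arrhythmic beats, baseline wander or 1/f sensor noise.
Two consequences matter for interpreting passing tests: (a) results
certify the signal-processing chain, not robustness to physiological
variability; (b) because the shared ramp is captured exactly by the atrial
subspace, the three PTa types perform identically to within Monte-Carlo
error — the relative advantage of small ramps (Type 1) that appears on
measured data needs ramp variability to manifest, so the type-ordering
check asserts ordering only up to 2 standard errors.

## Measurements

* **HV interval** — threshold at `k`× a caller-supplied noise floor
  (default k = 2, floor = pre-P RMS of the raw beat), group supra-threshold
  excursions closer than 10 ms into complexes, take the last complex before
  the QRS onset, and walk its first downward limb back to the preceding
  non-negative sample. The final 25 ms before the QRS onset are excluded
  from the search: reconstruction edge effects concentrate at the epoch
  boundary and physiological HV is ≥ 35 ms. The per-recording estimate is
  the median across beats; single beats at 28 dB scatter by several ms.
* **SER** — `P_ext / (P_raw − P_ext)` with Welch band powers (segment
  length ≤ epoch length) integrated over 5–30 Hz (P), 75–100 Hz (His) and
  150–200 Hz (noise).
* **Correlation** — Pearson r between an extracted beat and the clean
  reference over the preserved window (the window choice is the caller's;
  full-epoch correlation is available by passing no window).
* **Agreement** — Spearman ρ from the rank-difference formula with average
  ranks (exact for tie-free data; with ties it deviates from the
  rank-then-Pearson form), and Bland–Altman bias ± 1.96 sample (n−1) SDs.

## Numerical choices and degenerate inputs

* QRS onsets: 5–40 Hz band-pass, smoothed squared-derivative envelope,
  adaptive threshold at 30% of the rolling 2 s maximum, 200 ms refractory,
  backtrack to 10% of the peak envelope. On simulated series this lands
  within ±1 ms of truth; any detector within ±5 ms is interchangeable.
* An all-zero template yields zero thresholds (IDWT becomes a pure d4/d5
  kill); an all-zero smoothed stack makes the atrial subspace undefined and
  raises rather than guessing a basis.
* Soft thresholding with an infinite threshold is a full kill; preserved
  coefficients are copied verbatim, never recomputed.
* The symmetric-extension wavelet transform of a 350-sample epoch is
  expansive (more coefficients than samples), so
  reconstruction-then-redecomposition does not reproduce the coefficient
  array exactly; one thresholding application provably never increases
  out-of-window d1–d3 energy, but a second application can shift a few
  percent of energy across the window boundary. The stored spec is
  therefore applied exactly once per beat.
* Epochs cut from a series use `qrs_onset_idx = T` (onset just past the row
  end); simulated epochs end *on* the onset (`T − 1`). HV measurements take
  the index explicitly, so both conventions coexist.

## Known limitations

* Preserve intervals are set manually (or from simulation ground truth);
  no automatic template annotation is attempted.
* The method presumes a stable HV interval; it is not suited to rhythms
  with beat-to-beat HV variation, and no ectopic-beat rejection beyond the
  refractory rule is provided.
* Extraction quality degrades below ~15 dB SNR; the correlation ceiling at
  high SNR is ~0.8, reflecting deliberate distortion by the projection.
* EDF files are read (via `mne`) but not written; delimited CSV with a JSON
  header is the native interchange format.
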