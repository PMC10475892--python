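# hisbeat

Beat-by-beat extraction of **His bundle signals (HBS)** from the PR interval
of noninvasive cardiac recordings (magnetocardiography, body surface
potential mapping), by **interval-dependent wavelet thresholding (IDWT)**
followed by **signal space projection (SSP)**.

## The problem

The His bundle produces a ~100 Hz bi/triphasic deflection in the PR segment,
between atrial and ventricular activation. Its timing relative to the QRS
onset — the **HV interval** (normal 35–50 ms, >75 ms signalling conduction
risk) — is normally measured invasively in an electrophysiological study.
In surface recordings the deflection is buried under ramp-like atrial
repolarisation signals and beat-to-beat noise, so it is classically
recovered only by averaging 100–200 beats, losing all per-beat dynamics.

`hisbeat` recovers the deflection in *every* beat. The signal-averaged PR
trace serves as a guide: the user (or the simulator's ground truth) marks the
deflection with T1/T2 markers, and the method then

1. **IDWT** — decomposes each raw epoch with the `coif5` wavelet into five
   detail levels, soft-thresholds every detail coefficient with the
   fixed-form (universal) threshold σ·√(2 ln N) *except* inside the
   preserved time intervals around the deflection, and zeroes the
   very-low-frequency levels d4/d5 outright;
2. **SSP** — over-smooths the thresholded epochs with a Savitzky–Golay
   filter (cubic, 23 ms frame) so only atrial content (P wave + ramps)
   survives, takes an orthonormal basis U\_n of the space these smoothed
   beats span via SVD, and projects each epoch onto the orthogonal
   complement:

   P\_per = I − U\_n U\_nᵀ,  b\_HB(t) = P\_per · b\_PR(t).

A synthetic generator reproduces the structure of a PR epoch (Gaussian
P wave; three canonical atrial-repolarisation ramp types — Type 1: −1/3 of
the P amplitude, Type 2: +1/2, Type 3: > +1/2; a biphasic 100 Hz His
deflection at a chosen HV; additive white Gaussian noise at an SNR
referenced to the P-wave peak), so the whole chain is testable without
recorded data. Quality metrics (SNR, band-limited signal-to-error ratio,
Pearson correlation against the clean reference, per-beat HV) and agreement
statistics (Spearman ρ, Bland–Altman limits of agreement) complete the
evaluation study.

## Worked example

```python
import numpy as np
import hisbeat as hb

cfg = hb.SimConfig(pta_type=hb.PTaType.TYPE1, snr_db=28.0,
                   hbs_hv=60.0, n_epochs=100, seed=1)
stack, truth = hb.simulate_pr_epoch(cfg)

template = hb.template_from_truth(stack, truth)      # T1/T2 around the HBS
spec = hb.build_threshold_spec(template, noise_ref=stack.epochs)
hbs = hb.run_pipeline(stack, spec)                   # IDWT -> SSP, per beat

lo, hi = int(template.t1_ms), int(template.t2_ms)
r = np.mean([hb.pearson_corr(row, truth.clean_hbs, window=(lo, hi))
             for row in hbs.epochs])
hv = np.median([hb.measure_hv(row, stack.qrs_onset_idx, cfg.fs,
                              raw[:40].std())
                for raw, row in zip(stack.epochs, hbs.epochs)])
print(f"mean correlation {r:.3f}, recording HV {hv:.0f} ms")
```

prints

```
mean correlation 0.794, recording HV 59 ms
```

i.e. at 28 dB the per-beat extracted deflections correlate ~0.8 with the
clean reference (distortion by the projection caps this below 1 even at
high SNR) and the median per-beat HV lands within a millisecond of the
simulated 60 ms.

The same workflow is available from the shell:

```sh
hisbeat simulate --pta-type 1 --snr-db 28 --hv-ms 60 --n-epochs 100 \
        --seed 1 --out stack.csv
hisbeat template --stack stack.csv --t1 279 --t2 309 --hbs-onset 289 \
        --out spec.json
hisbeat extract  --stack stack.csv --spec spec.json --out hbs.csv
hisbeat evaluate --raw stack.csv --hbs hbs.csv \
        --truth stack.csv.truth.json --out report.json
hisbeat contour  --hbs hbs.csv --out contour.csv --png contour.png
```

## Layout

| module | contents |
| --- | --- |
| `hisbeat.simulate` | synthetic PR epochs, beat series, ground truth |
| `hisbeat.epochs`   | QRS-onset detection, epoching, averaging, the four objective HBS criteria, stress bins |
| `hisbeat.idwt`     | soft thresholding, threshold-spec compilation and application |
| `hisbeat.ssp`      | Savitzky–Golay over-smoothing, atrial basis, projector, full pipeline |
| `hisbeat.metrics`  | SNR, band SER, correlation, HV measurement, Spearman ρ, Bland–Altman |
| `hisbeat.io` / `hisbeat.cli` | CSV/EDF ingest, contour matrices, JSON reports, the `hisbeat` command |

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
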