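# nvsleep

Analysis of arousal-state-dependent cerebral hemodynamics in head-fixed mice
— from raw multimodal physiological recordings (bilateral intrinsic optical
signal reflectance, cortical and hippocampal stereotrode signals, nuchal EMG,
force sensor, whisker camera) to sleep-state classification, state-resolved
hemodynamic summaries, transition-triggered averages, neurovascular
cross-correlations, and bilateral connectivity metrics.

Head-fixed mice fall asleep readily, and sleep drives cerebral blood-volume
changes that dwarf anything seen in the awake state. Any "resting-state"
analysis that ignores arousal state mixes these regimes. This package
implements the full analysis chain needed to separate them, plus a synthetic
session generator that emulates the statistical structure of such recordings
and provides ground truth for every downstream stage — so the entire pipeline
is testable without animal data.

## The core quantities

* **∆[HbT]** — total-hemoglobin change (µM), a blood-volume proxy, obtained
  from 530 nm isosbestic reflectance by the Beer-Lambert relation
  ∆[HbT] = −ln(1 + ∆R/R) / (ε·X), with ε = 39 036.4 M⁻¹cm⁻¹ and
  X = 0.037 cm by default. Baseline R₀ is the daily mean over manually
  verified awake rest.
* **Band powers** — zero-phase 3rd-order Butterworth bandpass (delta 1–4,
  theta 4–10, alpha 10–13, beta 13–30, gamma 30–100, MUA 300–3000 Hz),
  squared, lowpassed < 10 Hz, resampled to the common 30 Hz analysis rate.
* **Sleep scoring** — 128 bagged decision trees on seven features per 5 s
  bin (cortical delta/beta/gamma, hippocampal theta, EMG log-power, heart
  rate, whisk count), with out-of-bag error and a shuffled-label chance
  baseline; contiguous NREM requires 6 consecutive bins (30 s), contiguous
  REM 12 bins (60 s) after bridging ≤ 10 s gaps.
* **Multitaper spectra** — Slepian tapers (TW, K) with power-of-two FFT
  padding; squared coherence MoC² with the analytic 95 % null level
  1 − 0.05^(1/(dof/2 − 1)).
* **Neurovascular coupling** — normalized cross-correlation over ±5 s lags
  between neural band power and ∆[HbT] per event class; bilateral Pearson r
  and MoC² at 0.1 Hz and 0.01 Hz.
* **Image analysis** — Radon-transform whisker tracking (angle of maximal
  sinogram variance); vessel diameters by FWHM (pial) and thresholding in
  Radon space (penetrating).
* **Statistics** — Gaussian mixed models
  `value ~ 1 + state + (1|subject) + (1|subject:hemisphere)` with Wald tests
  against a reference state.

## Worked example

```python
from nvsleep.synthgen import GeneratorConfig
from nvsleep.pipeline_io import run_pipeline

res = run_pipeline(GeneratorConfig(seed=3), duration_s=1800.0, seed=3)
print(f"held-out accuracy {res['accuracy']:.3f}")
for kind, vals in sorted(res["hbt_by_kind"].items()):
    print(f"{kind:>18s}: {vals.mean():+7.2f} uM  (n={vals.size})")
```

Output from this exact call:

```
held-out accuracy 0.933
             all15:  +19.31 uM  (n=2)
   contiguous_NREM:  +30.79 uM  (n=12)
              rest:   -0.52 uM  (n=13)
       whisk_brief:   +1.70 uM  (n=22)
    whisk_extended:   +4.61 uM  (n=14)
    whisk_moderate:   +2.60 uM  (n=36)
```

The classifier, trained on half of the ground-truth-labeled bins and
evaluated on the alternating half, scores 93 % of 5 s bins correctly.
Awake rest sits at the zero baseline by construction; brief whisking raises
∆[HbT] by a couple of µM; contiguous NREM sleep raises it by ~31 µM —
recovering the generator's planted 32.2 µM NREM offset from the raw
synthetic channels. (A 30-minute session at this seed contains no REM epoch
long enough to qualify as contiguous; hour-long sessions do.)

The same stages are available from the shell:

```sh
nvsleep simulate --seed 3 --duration 1800 --out session.h5
nvsleep analyze  --seed 3 --duration 1800 --out results/
nvsleep report   --outdir results/
```

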