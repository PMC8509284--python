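# renalqmri

Digital kidney phantoms and quantitative T1/T2/ADC parameter mapping for
small-animal renal MRI — built around the imaging workup of chronic kidney
transplant rejection in mice.

## The problem

Chronic allograft rejection drives inflammation and interstitial fibrosis
in the kidney graft. Quantitative MRI can track this non-invasively:

* **T1 and T2 relaxation times** rise with inflammation, edema and
  fibrosis; the **cortico-medullary difference** (CMD = mean ISOM − mean
  cortex) collapses when the whole parenchyma is diseased;
* the **apparent diffusion coefficient (ADC)** becomes spatially patchy —
  regions of restricted diffusion (cellular infiltrate, fibrosis) sit next
  to regions of elevated diffusivity — which whole-kidney **ADC histogram
  metrics** (SD, IQR, entropy) pick up even when the mean ADC is unchanged.

Because animal imaging data from such studies are typically not shareable,
this package provides the entire analysis chain *plus* a digital kidney
phantom whose ground-truth tissue parameters are the published group means,
so every estimator can be validated by parameter recovery.

## What it does

1. **Phantom** (`renalqmri.phantom`, `renalqmri.presets`): a 2D coronal
   kidney slice of concentric elliptical bands — cortex, outer stripe
   (OSOM) and inner stripe (ISOM) of the outer medulla — with per-
   compartment ground-truth T1/T2/ADC. Allograft phantoms overlay a
   spatially correlated two-class ADC mixture (class means base ± δ,
   within-class SD σ) calibrated so the voxel population reproduces the
   published whole-kidney histogram SD *and* IQR.
2. **Synthesis** (`renalqmri.synthesis`): forward simulation of the three
   acquisitions — inversion recovery with 13 TIs (30–8000 ms, TR 18 s),
   a 7-echo train (TE 11–77 ms), and DWI over 7 b-values (0–800 s/mm²) —
   with Rician magnitude noise at σ = S0/SNR (default SNR 40).
3. **Mapping** (`renalqmri.relaxometry`): statsmodels-style model objects.
   `InversionRecoveryT1Model` fits the magnitude model |a − b·e^(−TI/T1)|
   with polarity restoration by candidate-null search (variable projection:
   deterministic grid + golden-section refinement). `MultiEchoT2Model` and
   `MonoExponentialADCModel` use weighted log-linear least squares
   (weights = signal²) with optional nonlinear refinement. `fit()` returns
   a `ParameterMap` with values, validity mask, R² map, per-voxel standard
   errors and a `summary()`.
4. **ROI statistics** (`renalqmri.roi`): compartment means, the CMD, and
   long-format cohort tables.
5. **Histogram** (`renalqmri.histogram`): Gaussian-kernel density
   (Silverman bandwidth, 128-point grid on [0, 3.5]×10⁻³ mm²/s) and the
   descriptors mean, SD, Pearson kurtosis, skewness, normalized KDE
   entropy, and IQR.
6. **Group statistics** (`renalqmri.groupstats`): Shapiro–Wilk screening,
   one-way ANOVA + Tukey HSD, unpaired/paired t-tests, mean ± SEM tables
   with significance stars.
7. **Pipeline** (`renalqmri.study`, CLI `renalqmri`): end-to-end
   simulate → fit → summarize with deterministic per-subject seeding.

## Worked example

```python
import numpy as np
from renalqmri import (Protocol, make_phantom, tissue_parameters,
                       synthesize_subject, fit_adc, fit_t1_ir, region_means,
                       histogram_metrics)
from renalqmri.phantom import region_mask

protocol = Protocol()                       # SNR 40, standard TI/TE/b axes
params = tissue_parameters("allogenic", "w3", protocol=protocol)
phantom = make_phantom(params, shape=(128, 128), seed=42)
series = synthesize_subject(phantom, protocol, seed=42)

t1_map = fit_t1_ir(series["t1"])
print(t1_map.summary())

stats = region_means(t1_map, phantom.label_map, subject_id="allo_w3_00")
print(f"cortex T1 {stats.means['cortex']:.0f} ms, ISOM T1 {stats.means['isom']:.0f} ms, "
      f"CMD {stats.cmd:.0f} ms")

adc_map = fit_adc(series["dwi"])
kidney = region_mask(phantom.label_map, "whole_kidney") & adc_map.mask
h = histogram_metrics(adc_map.values[kidney])
print(f"ADC histogram: mean {h.mean:.2f}, SD {h.sd:.2f}, IQR {h.iqr:.2f}, "
      f"entropy {h.entropy:.2f}, kurtosis {h.kurtosis:.2f}")
```

prints

```
T1_ms parameter map (128x128)
  fitted voxels : 4980 / 16384
  mean / median : 2063 / 2052 ms
  range         : [206.9, 4597] ms
  median R^2    : 0.99885
  median stderr : 65.25 ms
  model: magnitude IR |a - b*exp(-TI/T1)| (variable projection)
  ...
cortex T1 1966 ms, ISOM T1 2293 ms, CMD 327 ms
ADC histogram: mean 1.44, SD 0.33, IQR 0.44, entropy 0.81, kurtosis 2.96
```

The rejecting graft shows the expected signature: cortical T1 near 1966 ms
(a healthy control cortex sits at ~1304 ms), a shrunken CMD, and a wide,
patchy ADC distribution (SD 0.33, IQR 0.44 ×10⁻³ mm²/s) despite an
unremarkable mean ADC.

The same pipeline is scriptable from the shell:

```sh
renalqmri simulate --group allogenic --timepoint w3 --seed 42 --outdir subj/
renalqmri fit --model adc --input subj/series_dwi --output subj/map_adc
renalqmri histogram --map subj/map_adc --labels subj/phantom --out subj/hist.json
renalqmri run-study --outdir study/        # full default cohorts
```

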