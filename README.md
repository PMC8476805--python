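# glycovivo

Quantification of endothelial **glycocalyx (GCX)** integrity from intravital
fluorescence microscopy of skin microvessels (dorsal skinfold chamber
preparation), for researchers studying GCX degradation and recovery in
sepsis-like models.

The package implements three imaging read-outs and their shared statistics:

* **Thickness index (TI)** of the GCX from FITC-WGA lectin images: in a
  40 x 200-px wall ROI aligned with flow, pixels at or above the threshold
  `Th = F·(Imax − Imin) + Imin` (F = 0.7) are counted as the GCX band;
  `TI = count / 200 px`, calibrated to micrometres (0.377 um/px).
* **Leukocyte–endothelium interactions** from 15-s tracks: *adhering*
  (max displacement ≤ 2 um), *rolling* (slower than half the free-flow
  speed) or *flowing*, with counts calibrated to a 100 um x 100 um segment,
  plus the dual-channel 8-s-lag criterion for tight adherence.
* **Vascular permeability index** from TMR-dextran time-lapses: mean
  intensity of 30 x 30-um interstitial ROIs every 30 min for 120 min, minus
  the t = 0 control value.
* **Group statistics**: mean ± SD, one-way ANOVA across scheduled hours and
  Dunnett's many-to-one comparisons against the 0-h control (α = 0.05).

Because the original image archive is not deposited, the package ships a
**synthetic-data generator** (vessel scenes with known band thickness,
labelled tracks, leakage time-lapses, physiological cohorts) so every stage
is verifiable against ground truth; `analysis/` contains numbered drivers
that run each stage and write tables under `results/`.

## Worked example

```python
from glycovivo import (SceneSpec, render_vessel_scene, roi_on_wall,
                       compute_ti)

# a 30-um vessel with a 1.885-um (5-px) GCX band, noise SD 5
frame, truth = render_vessel_scene(SceneSpec(noise_sd=5.0, seed=1))
result = compute_ti(frame, roi_on_wall(truth))
print(f"Th={result.threshold_used:.1f}  count={result.gcx_pixel_count}"
      f"  ti_px={result.ti_px:.2f}  ti_um={result.ti_um:.3f}")
```

prints

```
Th=151.2  count=1000  ti_px=5.00  ti_um=1.885
```

i.e. the threshold lands between lumen and band gray levels, exactly
5 px x 200 columns of band are counted, and the index recovers the true
1.885-um thickness.

The same from the command line:

```bash
glycovivo simulate scene --seed 1 --noise-sd 5 --out scene_dir
glycovivo emulate --seed 1 --out results/emulation
```

`emulate` simulates the full experimental protocol (TI, adhesion counts,
permeability, syndecan-1 / body weight / blood pressure cohorts at their
scheduled hours), quantifies every endpoint with the code above, applies the
ANOVA + Dunnett policy and writes one CSV per table plus a markdown report.
Under the default conditions the report flags the 24-h syndecan-1 elevation
as the only significant syndecan-1 time point, the 24-h rise in rolling
leukocyte counts, and no significant permeability trend.

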