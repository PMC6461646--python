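# nucleomech

Quantification pipelines for the imaging and gel assays used to study
mechanical compression of the nucleus by the actin–MKL1 pathway: when
actin polymerization driven by MKL1/SRF squeezes the nucleus, nuclear
volume drops, the LINC-complex tension sensor reads compression, histone
mobility falls, and DNase I digests chromatin into larger fragments.
`nucleomech` turns the raw readouts of those four assays into numbers:

* **Sensitized-emission FRET** (`nucleomech.fret`) — three-cube FRET with
  bleed-through calibration. Donor leakage *x* and acceptor
  cross-excitation *y* are fitted pixel-wise from single-fluorophore
  samples, and the per-pixel index is

  ```
  FRET index = (F − x·D − y·A) / A
  ```

  computed after background subtraction, illumination-gradient
  correction, pixel-shift registration and 3×3 smoothing, then averaged
  per cell mask.

* **FRAP double normalization** (`nucleomech.frap`) —
  `I_t = (ROI1 − ROI3)/(ROI2 − ROI3)` (background and acquisition
  photobleaching cancel), then `I = (I_t − I_4)/(I_ave − I_4)` anchored at
  the pre-bleach mean and the first post-bleach frame; mobile fraction and
  half-time from a single-exponential fit.

* **Nuclear morphometry** (`nucleomech.morphometry`) — 3D segmentation of
  anisotropic DAPI z-stacks (0.25 µm z-step) with watershed splitting of
  touching nuclei on the physical distance transform; volume in µm³,
  2D circularity `4π·area/perimeter²` (Crofton perimeter), quality flags,
  and two-sample t-tests.

* **Gel densitometry** (`nucleomech.gel_densitometry`) — DNase I lane
  profiles normalized as `I = (I_n − I_b)/I_total`, ladder-calibrated
  fragment-size distributions, and accessibility scores (mass fraction
  below 500 bp).

* **Synthetic ground truth** (`nucleomech.synthetic`) — deterministic
  generators for nuclei stacks, FRET scenes, FRAP traces and gel images
  with known parameters, used to validate every stage by recovery.

## Worked example

Recover the mean nuclear volume of a synthetic population generated at
the wild-type mESC distribution (352 ± 88 µm³):

```python
import numpy as np
from nucleomech import make_nuclei_fields, measure_nuclei_stack

fields = make_nuclei_fields(60, volume_mean=352.0, volume_sd=88.0, seed=4)
volumes = []
for stack, truth in fields:
    volumes += [m.volume for m in measure_nuclei_stack(stack) if not m.flags]
print(f"{len(volumes)} nuclei, mean {np.mean(volumes):.1f} um^3")
```

```
60 nuclei, mean 346.8 um^3
```

60 nuclei are generated across 11 confocal-sized fields (256×256×80
voxels at 0.25 × 0.1 × 0.1 µm), blurred, noised, re-segmented in 3D and
measured; the recovered mean is within 1.5% of the generating 352 µm³.

A FRET scene with a known sensitized-emission fraction:

```python
from nucleomech import BackgroundSpec, make_fret_scene, run_fret_pipeline

scene, truth = make_fret_scene(true_se_fraction=0.15, x=0.25, y=0.10,
                               snr=20.0, seed=11)
cal, result, means = run_fret_pipeline(
    scene["sensor"], scene["donor_only"], scene["acceptor_only"],
    scene["masks"], BackgroundSpec("constant", value=100.0))
print(f"x = {cal.x:.3f}, y = {cal.y:.3f}, "
      f"mean cell index = {np.mean([m for _, m in means]):.3f}")
```

```
x = 0.251, y = 0.100, mean cell index = 0.148
```

The calibration slopes recover the generating x = 0.25 and y = 0.10, and
the mean per-cell index recovers the true sensitized-emission fraction
0.15 within 0.01.

## Command line

```sh
nucleomech volume --stack stack.tif --dz 0.25 --dxy 0.1 --out results/
nucleomech fret calibrate --donor-only d.tif f.tif a.tif \
                          --acceptor-only d2.tif f2.tif a2.tif --out results/
nucleomech frap --traces traces.csv --n-prebleach 3 --out results/
nucleomech gel --image gel.tif --lanes lanes.yaml \
               --ladder 10000,3000,1000,500,100 --out results/
nucleomech sim nuclei --n 20 --volume-mean 207 --volume-sd 58 --seed 1 --out sim/
```

Every command writes its correction parameters to `provenance.jsonl` in
the output directory.

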