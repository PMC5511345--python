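# sheathchase

Simulation and kymograph analysis of contractile **type VI secretion system
(T6SS) sheath** dynamics in live-cell fluorescence time-lapse imaging, built
around the photobleach-chase assay that identifies *where* a growing sheath
polymer adds new subunits.

## The scientific problem

The T6SS sheath (VipA/VipB, imaged as VipA-msfGFP) is a phage-tail-like
polymer that nucleates on a membrane-anchored baseplate, polymerizes along a
straight chord of the cell at a constant speed `v_a` (tens of nm/s),
contracts to roughly half its extended length in under 2 ms, and is then
disassembled. Three assembly mechanisms are conceivable: new subunits could
be added at the end **distal** to the baseplate, inserted **proximally** at
the baseplate, or **intercalated** between existing subunits. A
photobleach-chase experiment distinguishes them: bleach a stripe across a
growing sheath and follow the bleached mark in a kymogram (distance x time
intensity map along the sheath). Each mechanism leaves a distinct signature:

| mechanism     | bleached mark in the kymogram                          |
|---------------|--------------------------------------------------------|
| distal        | fixed distance from the origin, fixed width/intensity  |
| proximal      | moves away from the origin at `v_a`, intensity stable  |
| intercalation | spreads with total length and regains intensity        |

`sheathchase` provides, for users who analyze such movies or want a tested
synthetic benchmark for them:

* a **forward simulator** of sheath life cycles (nucleation, chord-limited
  growth under any of the three mechanisms, sub-frame contraction to a
  configurable fraction, disassembly) with an irreversible line photobleach
  acting on both the polymer and the soluble subunit pool;
* an **optics renderer** (65 nm pixels, 2D Gaussian PSF, Poisson shot noise,
  Gaussian read noise) producing multi-frame TIFF stacks with YAML metadata;
* **kymogram extraction** (bilinear sub-pixel line sampling), origin
  location, sub-bin **front tracking**, OLS **speed estimation** with R²,
  end-of-assembly detection, and **contraction quantification** including
  the `Δℓ / Δt` lower bound on contraction speed from high-frame-rate
  (500 fps) stacks;
* the **photobleach-chase analysis**: event eligibility, bright / bleached /
  dim section classification, section tracking at the assay's four
  timepoints (pre-bleach, first post-bleach frame, 20 s before the end of
  assembly, end of assembly), per-timepoint background normalization, and
  the **mechanism call**;
* **population statistics**: morphology/dynamics fractions, sheath-length
  vs cell-diameter regression, per-cell assembly counts.

## Worked example

Simulate a compliant distal photobleach-chase event (2 s frames for 2 min,
stripe bleach after 30 s) and fit the mechanism:

```python
from sheathchase import BleachChaseModel
from sheathchase.presets import chase_experiment

exp = chase_experiment("distal", seed=11)          # rendered TIFF-like stack
model = BleachChaseModel.from_stack(exp.stack, exp.line)
res = model.fit()
print(res.summary())
```

```
Photobleach-chase fit
=====================
mechanism call         distal
bleached drift             0.12 nm/s  (tolerance 20% of v_a)
bleached width change     0.32%
bleached dI                -1.8 pct points
v_a (pre-bleach)          53.34 nm/s  R2 0.9981
v_a (post-bleach)         55.26 nm/s  R2 0.9992
timepoints (s)         t1=30 t2=32 t3=72 t4=92
```

The bleached mark drifts at 0.12 nm/s — indistinguishable from zero against
the 20%-of-`v_a` tolerance (~11 nm/s) — keeps its width (0.3% change), and
stays at the cytosolic-background intensity level (dI ≈ 0: no fluorescence
recovery), so the call is `distal`: subunits were added at the end away
from the baseplate. The polymerization speed is the OLS slope of the
front-position trace and is the same before and after the bleach
(R² > 0.99), confirming one continuous assembly. `res.table` carries the
per-section centroids, widths and normalized intensities behind these
numbers.

The same objects drive the command line:

```sh
sheathchase simulate --config config.yaml      # stack.tif + truth CSVs
sheathchase kymo    --stack stack.tif --line line.yaml
sheathchase measure --stack stack.tif --line line.yaml
sheathchase chase   --stack stack.tif --line line.yaml   # mechanism report
sheathchase stats   --records cells.csv --events events.csv
```

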