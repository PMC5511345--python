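# Methods

This note documents the models behind `sheathchase`: what the simulator and
renderer assume, how the measurements are defined numerically, which design
choices were genuinely open, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Sheath life-cycle model

A sheath is a 1D stack of subunit rings on a straight chord through the 2D
focal-plane cross-section of a cell (circle for a spheroplast, capsule for
a rod). The anchor (baseplate) is a fixed membrane point; the polymer can
never outgrow the chord available from its anchor, which is what couples
maximal sheath length to cell diameter. Rings are book-kept every 10 nm of
length — far below the 65 nm pixel size, so the pitch value is immaterial
to any rendered observable; it only keeps the bookkeeping exact.

While assembling, ring `i` sits at `i x pitch` from the anchor, and the
three candidate assembly mechanisms reduce to where new entries enter the
brightness array: appended at the far end (**distal**), prepended at the
anchor (**proximal**), or inserted at uniformly random indices
(**intercalation**). Each ring permanently carries the soluble pool's
relative brightness at its incorporation time; this single rule generates
the bright / bleached / dim structure of the chase assay. Phases run
assembling → extended → contracted → disassembling → gone. Contraction is
instantaneous between frames (the real event is sub-frame even at 2 ms
frame intervals): ring positions scale by the contraction fraction —
default 0.5 with optional Gaussian jitter (sd 0.03), emulating the
observed near-half contraction — so summed fluorescence is conserved and
the contracted sheath doubles in linear brightness density. Disassembly is
an exponential brightness decay (default time constant 15 s) after a
configurable delay; the disassembly machinery is not modeled mechanically.

Nucleation is Poisson in time with anchors uniform on the membrane and
chord directions toward a second uniform membrane point; per-sheath speeds
are Gaussian (`v_a_mean`, `v_a_sd`, default 38 ± 5 nm/s for wild-type-like
populations, 55 nm/s for the sparse-sheath chase background). The soluble
pool is infinite by default; a finite subunit budget is supported.

## Photobleach model

The bleach is an irreversible line event. The laser dose falls off as a
Gaussian with perpendicular distance from the line but **saturates** at
100% output power: rings keep
`1 − (1 − polymer_survival) · min(1, S · exp(−d²/2σ²))` of their
brightness. `footprint_fwhm_um` (default 0.8 µm) is the width of the fully
bleached stripe — the dark zone one sees in the images — and σ is derived
from it and the saturation `S` (default 4) so the stripe saturates exactly
across that width with sharpening skirts. A plain Gaussian profile (`S=1`)
leaves the center of the mark 15–25% bright, which contradicts the
defining observation that bleached sections sit at cytosolic-background
intensity; saturation is the physically expected behavior of a full-power
line scan and reproduces it. The soluble pool is scaled by
`pool_survival` (default 0.4, exposed in config — only "partial" pool
bleaching is known); subunits added afterwards are correspondingly dim.

## Optics and noise

Each ring is an isotropic 2D Gaussian emitter (σ = 110 nm, about the
diffraction limit for GFP at NA 1.4; exposed since the true PSF is not
known) of integrated intensity `photons_per_ring x brightness`, splatted
bilinearly and blurred in one pass. Cytosol contributes a uniform photon
rate inside the cell mask proportional to the current pool brightness —
so the background visibly dims when the pool is bleached, as in the real
assay. Poisson shot noise acts on the photon field, then Gaussian read
noise and a constant camera offset. Defaults (60 photons/ring, 20
background photons/px, read noise 2, offset 100) put a single extended
sheath at roughly 5x the per-pixel background sd. Motion blur is not
modeled (contraction is sub-frame by assumption); there is no 3D PSF and
no camera-specific calibration.

## Measurement definitions

**Background** is per-frame: the median (with a 1.4826·MAD scale) of
in-cell pixels outside the sheath mask, the cell found by a three-class
Otsu split of the temporal median image (dark surround / cytosol /
sheath). Per-frame levels matter because the pool bleach dims the cytosol
mid-movie; all thresholds and normalizations use the background of their
own timepoint. Noise thresholds applied to kymogram values are scaled by
the perpendicular (and, for profiles, temporal) averaging width.

**Kymograms** sample the stack along a line with bilinear interpolation at
`floor(L/spacing)+1` evenly spaced points including both endpoints
(reported spacing is the effective `L/(D−1)`), averaged over an odd
perpendicular width (default 3 px). Evenly spaced endpoint-inclusive
sampling makes extraction exactly equivariant to reversing the line. The
**origin** is the line end whose above-background edge appears earliest
and stays static, consistent with a fixed baseplate; kymograms are
oriented so the origin is bin 0.

**Front tracking**: per frame, above-threshold runs are chained from the
origin, bridging dark gaps up to ~1 µm wide — a bleached span pierces the
signal without ending the sheath. The detection threshold is
`background + max(k·sd_eff, 10% of column amplitude)` (k = 3); the
relative floor is needed because at vanishing noise a pure k·sd threshold
lands arbitrarily far down the PSF tail. The tip is refined to sub-bin
precision at the half-amplitude of the tip-side section: the half-height
point of a step edge blurred by a symmetric PSF coincides with the true
edge, independent of the section's absolute brightness (bright or dim).
On noiseless renders this tracks truth to within half a distance bin over
established growth.

**Speed** is the OLS slope of front distance on time (scipy
`linregress`), reported with intercept, R² and standard error. The default
fit window starts once the sheath exceeds four bins (a sub-resolution blob
has no localizable front) and ends at the end of assembly. **End of
assembly** is the onset of the terminal plateau of the 3-frame-median
smoothed front: the first frame from which the median of all later
positions exceeds the current one by no more than half a bin ("clearly
detected growth" operationalized; the raw last-increase rule is too
sensitive to single noisy late steps). Growth reaching the end of the
stack is flagged as censored. **Contractions** are length drops ≥ 25%
between consecutive frames (well between frame-to-frame noise and the
~50% true drop); the high-frame-rate speed bound is `Δℓ/Δt` in nm/ms.

## The chase analysis

**Eligibility** requires measurable front growth before the bleach,
continued growth after it, and a partial bleach. Partiality has two
observable signatures, either of which qualifies: a below-background span
(at least `max(2 sd, 15% of amplitude)` deep, ≥ 2 bins) inside the polymer
extent, or a regression of the measured front at the bleach instant —
polymerization alone can never shrink, so a front drop means the mark
clipped the tip — together with clearly surviving unbleached polymer
elsewhere on the line.

**Classification** averages each distance bin over a short post-bleach
window (8 s), only over frames in which the front has already passed that
bin, and thresholds: bleached ≤ background + max(2 sd, 15% amplitude);
bright ≥ 70% of the pre-bleach on-polymer level; dim in between. The
window is kept short so the classification stays meaningful for moving
marks. PSF blur necessarily creates thin transition runs where bright and
bleached spans meet; these are split between their neighbors, and spans
under 2 bins are dropped. If the absolute rule finds no bleached bins
(early subunit mixing can lift the mark above it), the deepest half-depth
valley of the averaged profile seeds the bleached span instead. The
pre-bleach reference level is the 90th percentile of on-polymer values
(an early short sheath is edge-dominated; a mean understates the plateau
that wide sections reach later).

**Tracking** at the assay timepoints t2 (first post-bleach frame), t3
(20 s before end of assembly; skipped with a warning if assembly ends too
soon) and t4 (end of assembly) is self-calibrating: the bleached span is
the darkest valley of the profile with its edges at half depth toward the
per-side shoulder maxima. Valleys with shoulders on both sides take
priority; a valley running into the extent boundary is accepted as
"tip-merged" with its span closed at the extent — the signature of a mark
riding just behind the polymerizing front. Candidate valleys are
disambiguated by continuity with the previous timepoint (predicted
centroid interval from the measured `v_a`). The polymer extent uses the
running maximum of the front trace, since growth is monotone and a
tip-riding mark depresses the instantaneous front estimate. Bright spans
are tracked as runs above the bright floor nearest the previous centroid.
Intensities are normalized per timepoint: background ↦ 0%, pre-bleach
polymer level ↦ 100% (the 100% anchor is this package's choice; only the
0% end is externally defined). The normalization is exactly invariant to
affine rescaling of camera counts.

**Mechanism call**, a pure function of three evidence numbers — bleached
centroid drift (OLS over t2..t4), relative width change (t4 vs t2), and
normalized intensity change:

* intercalation: width change ≥ 0.3 with intensity rise ≥ 5 points, *or*
  intensity recovery ≥ 20 points alone — strong recovery of the mark is
  impossible under either end-addition mechanism, and late-time mixing can
  erase the width signature entirely;
* distal: |drift| < 20% of `v_a` and |width change| < 0.3;
* proximal: drift ≥ 20% of `v_a` without intensity rise — width is not
  used here because a tip-riding mark is delimited by the moving front,
  which inflates its apparent width;
* otherwise ambiguous.

All thresholds live in `ChaseThresholds` / the `analysis:` config block;
they were calibrated once on simulated events and are deliberately
conservative about the distal↔proximal axis (on 50 noisy events per
mechanism, no distal event is called proximal or vice versa).

## Synthetic study conditions

The presets pin the acquisition protocols: 65 nm pixels throughout; chase
events at 2 s/frame for 2 min with the bleach after 30 s, one seeded
sheath at 55 nm/s crossing a 5 µm spheroplast, bleach line perpendicular
to the sheath 0.75 µm behind the front; speed series at 2 s/frame for
80 s; contraction events at 2 s/frame in ~2.8 µm spheroplasts; high-speed
stacks at 500 frames/s for 5 s with five staggered contractions in an
8 µm spheroplast. Population runs (length–diameter regression, per-cell
assembly counts) simulate 150–400 cells at truth level with one pixel of
measurement noise on lengths rather than rendering hundreds of movies;
the optical measurement path is exercised per-event elsewhere, and the
problem sizes keep the default test run and the acceptance script within
a couple of minutes.

## What passing tests do and do not show

The generator reproduces the study's *designed* structure: straight
chords, a static origin, constant per-sheath speed, a single well-isolated
sheath per analysis line, known bleach time and geometry, stationary
cells. Real movies add sheath crossings and bundling, out-of-focal-plane
tilt (projected lengths underestimate true lengths; no correction is
applied), cell drift, photobleaching during ordinary imaging, autofocus
breathing, and manually drawn lines. Recovery results on these synthetics
therefore validate the measurement and inference machinery — not the
biological conclusion itself, which requires the real data. The
length–diameter R² and per-cell count benchmarks are calibration-recovery
checks: the generator is configured with literature-scale parameters and
the pipeline must measure them back; they are not independent evidence
about cells.

## Known limitations

2D only; no explicit disassembly machinery; no finite-pool speed coupling
(the pool size caps growth but does not slow it); the automatic line
proposal (principal axis of the thresholded maximum projection) is only
suitable for isolated structures; eligibility's tip-clip signature assumes
the bleach time is known from metadata (it is never inferred from the
images); intercalation calls rely partly on intensity recovery, so a
hypothetical mechanism mixing end-addition with subunit exchange would be
reported as intercalation.
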