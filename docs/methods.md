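# Methods

## The latent maturation model

One simulated recording follows a single phagosome from the moment its
pseudopods seal (`t = 0`) on a fixed frame grid (default 2-min interval,
100-min span, 51 frames — matching typical time-lapse protocols for
embryonic corpse clearance). The latent state per frame comprises the
phagosome disc (center, radius), the luminal pH, the engulfed nucleus
disc, per-reporter label pools on the rim and in the lumen, and a list of
vesicles (puncta) with positions, states and label content.

**Vesicle kinetics.** Births form a homogeneous Poisson process
(`puncta_birth_rate`, events/min) placed uniformly over the cytosolic
annulus between the phagosome rim plus a 10-px margin and the embryo
edge. Within each frame, events resolve in birth → dock → fuse order with
per-interval probabilities `1 − exp(−k·Δt)`; a vesicle born in an
interval may dock (and a newly docked one fuse) in the same interval.
Docked vesicles sit on the rim at their docking angle and ride the rim as
it shrinks. The birth margin encodes that undocked vesicles are not
enriched at the surface; without it, chance apposition of cytosolic
puncta contaminates the surface readout of recruitment-defective
scenarios.

**Membrane topology.** On fusion, a double-membrane vesicle delivers half
its label to the rim pool (outer membrane) and half to the lumen pool
(inner membrane released into the lumen); a single-membrane vesicle
delivers everything to the rim. This routing is the discriminating
mechanism between the autophagosome and LAP-vesicle hypotheses, and label
is conserved exactly: at every frame, label ever born equals
puncta-held + rim + lumen label.

**Deterministic programmes.** Luminal pH decays exponentially from
`pH_initial` 7.2 to `pH_final` 5.0 with `pH_tau` 20 min (endosomal →
lysosomal range). After a per-scene shrink onset (24 ± 7 min, uniform
jitter) the phagosome radius halves every `shrink_halftime` = 25 min, so
the measured lifespan (time to half diameter) falls in 42–58 min on the
2-min grid. The nucleus radius halves every `nucleus_decay_halftime` =
60 min, i.e. ~49% of the initial diameter remains at 60 min in the wild
type. Engulfment duration (budding → sealing, default 6 min) is carried
as scene metadata.

**Calibration.** The wild-type rates (`puncta_birth_rate` 0.25/min,
`k_recruit` 0.12/min, `k_fuse` 0.05/min, `label_per_vesicle` 300) were
fixed once so that the median time of first fusion over many seeds is
≈ 16–17 min (published medians for LGG-1⁺/LGG-2⁺ autophagosomes: 14 and
18 min) and all lifespans fall within the published 40–60 min band. The
genotype presets change only the parameter their phenotype implies:
`ced1_like` sets `k_recruit = 0`; `rab7_like` sets `k_fuse = 0`;
`atg7_like` sets the birth rate to 0 (with a moderate residual
acidification defect, pH_final 6.0); `cup5_like` holds pH flat.
Degradation-defective presets (`rab7_like`, `cup5_like`, `ced1_like`)
also disable phagosome shrinkage and nuclear decay, since corpse
degradation requires lysosomal delivery.

## Rendering

Each channel images one structure through one fluorophore. Emission
follows a single-site Henderson–Hasselbalch titration,
`f = floor + (1 − floor)/(1 + 10^(pKa − pH))`, with GFP pKa 6.0,
mNeonGreen 5.1 and mCherry 4.5 (the literature bound "< 4.5" is used as
the conservative worst case); floors default to 0. Every label unit
contributes `brightness × f(local pH)` expected photons spread by an
isotropic Gaussian PSF (σ 1.5 px at 0.1 µm/px; kernels truncated at 6σ so
photon bookkeeping closes to < 1e-6 relative). Rim pools spread over a
3-px annulus and luminal pools uniformly over the disc at luminal pH;
puncta and rim material sit at cytosolic pH 7.2. Expected images are
corrupted by Poisson shot noise, then Gaussian read noise (σ 3), then a
constant offset (10 counts); noise-free renders are bit-reproducible.

Vesicle-reporter channels additionally carry a uniform, un-quenched
"haze" (0.1 label/px² over the embryo disc) modelling out-of-focus
cytosolic reporter light in the real 3-D embryo. It gives the luminal
RInt a positive T0 anchor, exactly as the real measurement relies on
diffuse reporter signal at sealing. Nuclear (chromatin-bound) channels
carry no haze. The default four channels are mCherry::LGG on vesicles, a
GFP+mCherry tandem on the nucleus, and an acid-resistant luminal
phagosome marker for diameter tracking; scenes with a second vesicle
reporter (e.g. RAB-7 co-labelling) add a GFP vesicle channel.

The simulator emits single 2-D planes; the original recordings were
12–16-section z-stacks. Whether the published intensities were measured
on single sections or projections is not recoverable; single planes with
the haze term are this package's stated stand-in, and absolute intensities
are meaningless — only the normalised ratios are interpreted.

## Measurement conventions

Coordinates are 0-based (row, col) = (y, x) with pixel centers at integer
positions; boxes are half-open, and an even-sided box centers with the
named pixel at the upper-left of the central 2×2 block. Polygon areas are
rasterised pixel counts (center-in-polygon, even-odd rule), matching how
intensity is summed; the background ROI defaults to an 8×8 box in the
image corner farthest from the phagosome, outside the embryo disc. The
acidification index deliberately subtracts no background (its defining
formula has none); a corrected variant exists behind a flag, off by
default. FWHM diameters threshold halfway between the 3×3 center mean and
the median of the outermost profile pixels, interpolate crossings
linearly, and average the horizontal and vertical chords.

Fusion onset uses threshold 1.5× with 2-frame persistence — chosen so
that noise-free wild-type scenes trigger on the first-fusion frame (one
fused vesicle raises the center box ≈ 2.2×) while default noise
(≈ 6% RInt sd) sits ≈ 8σ below threshold. Both knobs are config-exposed,
as the published criterion ("obvious signal entry") was visual. Lifespan
takes the first at-or-below-half crossing without interpolation, at the
2-min frame resolution. Censored events carry their series horizon.

Puncta detection is multi-scale LoG (σ 1–3 px) with an absolute response
threshold of 100 counts on the raw image — about 5% of a single vesicle's
peak response — plus non-maximum suppression at the matching radius.
Matching is greedy nearest-neighbour under a 3-px cap (≈ 2× PSF σ; the
published assays judged co-labelling visually, so the radius is an
explicit stand-in), with an exhaustive optimal matcher provided as a
validation oracle.

## Fusion-rate recovery

The birth → dock → fuse chain is linear, so expected pool sizes obey an
exact per-frame recursion. Noise-free luminal RInt curves are inverted to
luminal label (each fusion adds half a vesicle's label), and `k_fuse` is
estimated by Poisson maximum likelihood on the per-frame fusion-count
increments. Cumulative-curve least squares is statistically inefficient
here: late frames dominate the objective yet carry almost no information,
because every vesicle eventually fuses whatever the rate. The recovery
benchmark uses a well-powered scene (birth rate 1.0/min, shrinkage off,
30 seeds per rate); there the estimator is unbiased with 5–8% relative
sd across the 0.02–0.1/min grid.

## Known limitations

- **Rim spill into the center box.** Once the shrinking phagosome radius
  approaches ~10 px, membrane-bound label bleeds into the 4×4 luminal
  box and the luminal readout loses topology specificity (a
  single-membrane scene can show RInt ≫ 1 at late times purely from rim
  spill). Topology-discrimination analyses therefore run with shrinkage
  disabled; degradation analyses use the diameter readouts instead.
- **Offset-dominated A_idx at late times.** With the nucleus below
  ~4 px radius (beyond ~85 min in wild type) the uncorrected GFP/mCherry
  ratio drifts toward the offset ratio and can uptick by ~0.003/frame;
  the index is interpreted out to ~60 min, as in the published assays.
- **Detection near bright rims.** Accumulated rim label forms a bright
  ridge that can yield spurious LoG detections; colocalization counting
  is therefore validated on scenes without luminal/rim pools
  (pre-fusion or fusion-defective), where ground truth arbitrates.
- The constant-image relative-intensity case is undefined (zero anchor)
  and raises rather than returning 1.
- No photobleaching, drift, 3-D optics, deconvolution, or automated
  phagosome segmentation; center tracks and polygons come from ground
  truth (simulation) or annotation files (external data).

Passing tests demonstrate correct measurement arithmetic, conservation,
and discrimination behaviour on this generative model — not performance
on real embryo movies, whose background structure, z-projection effects
and annotation error the generator does not emulate.
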