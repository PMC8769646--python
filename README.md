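# phagotrace

Quantitative time-lapse analysis of phagosome maturation in *C. elegans*
embryos, together with a synthetic microscopy generator that simulates the
underlying vesicle kinetics so every measurement can be validated against
ground truth without real footage.

During programmed cell death, engulfing cells internalise apoptotic corpses
into phagosomes, which then mature: LC3/GABARAP-labelled vesicles (LGG-1/
LGG-2 in the worm) are recruited to the phagosome surface and fuse with it,
the lumen acidifies, and the corpse — including its nucleus — is degraded.
A central question is membrane topology: fusion of a **double-membrane
autophagosome** releases its labelled inner membrane into the phagosomal
lumen, whereas fusion of a **single-membrane (LAP-type) vesicle** leaves
label on the phagosome membrane only. Ratiometric reporters exploit
fluorophore pKa (GFP ≈ 6.0 quenches in acid; mCherry ≤ 4.5 and mNeonGreen
5.1 resist it) to read out luminal entry and acidification.

`phagotrace` implements, as tested reusable code, the measurements used to
make these inferences:

- **Luminal relative intensity** — `RInt(Tn) = (Int_center − Int_bg)_Tn /
  (Int_center − Int_bg)_T0`, summed over a 4×4 px box at the phagosome
  center; 1.0 means no label entry.
- **Surface relative intensity** — unit intensity of the donut between two
  polygons outlining the phagosome, `UI = (Int_outer − Int_inner) /
  (Area_outer − Area_inner)`, background-corrected per unit area and
  normalised to the sealing frame.
- **Acidification index** — `A_idx(Tn) = (Int_GFP/Int_mCherry)_Tn /
  (Int_GFP/Int_mCherry)_T0` over a 3×3 px center box (no background term).
- **Disc diameters** — FWHM chords through the engulfed nucleus or the
  phagosome marker; the **phagosome lifespan** is the time until the
  diameter first halves, and the **nuclear diameter ratio** tracks corpse
  degradation.
- **Event times** — engulfment duration, fusion onset (first sustained
  luminal RInt above threshold) with right-censored "no fusion" calls,
  and censored histograms.
- **Puncta colocalization** — LoG blob detection plus greedy
  nearest-neighbour matching, feeding the class-distribution and
  double-positive percentage formulas (e.g. %RAB-7⁺, % autolysosomes).

The simulator renders multi-channel stacks (vesicle birth → docking →
fusion as per-frame Bernoulli kinetics, Henderson–Hasselbalch pH-dependent
emission, Gaussian PSF, Poisson/Gaussian noise) from genotype presets that
encode the classical mutant phenotypes: `ced1_like` (recruitment-defective),
`rab7_like` (fusion-defective), `atg7_like` (no autophagosome biogenesis),
`cup5_like` (acidification-defective), and `single_membrane_control`.

## Worked example

```python
from phagotrace import (preset_genotype, simulate_scene, render_stack,
                        annotation_from_scene, luminal_relative_intensity,
                        surface_relative_intensity, acidification_index,
                        nuclear_diameter_ratio, fusion_onset,
                        phagosome_lifespan, disc_diameter_timecourse)
from phagotrace.render import Optics

params = preset_genotype("wild_type")
scene = simulate_scene(params, seed=1)            # latent ground truth
optics = Optics(shot_noise=False, read_noise=0.0)  # noise-free render
stack = render_stack(scene, optics=optics, seed=2)
ann = annotation_from_scene(scene)

lumen = luminal_relative_intensity(stack, stack.channel_index("lgg_mcherry"), ann)
onset = fusion_onset(lumen)
life = phagosome_lifespan(disc_diameter_timecourse(
    stack, stack.channel_index("phago_mcherry"), ann))
```

At `t = 60` min this prints:

```
luminal RInt at 60 min:    77.38
surface RInt at 60 min:    119.79
acidification index 60 min: 0.178
nuclear diameter ratio:     0.488
fusion onset:  22 min
lifespan:      50 min
```

Read: mCherry::LGG label flooded the lumen after fusion began at 22 min
(a double-membrane signature — a `single_membrane_control` scene on the
same seed stays at RInt ≈ 1.0), the surface accumulated label, the lumen
acidified (GFP/mCherry ratio fell to 0.18), the corpse nucleus shrank to
49% of its initial diameter by 60 min, and the phagosome halved its
diameter at 50 min.

The same pipeline runs from the shell:

```sh
phagotrace run --preset wild_type --seed 1 --no-noise --out rundir/
phagotrace simulate --preset rab7_like --seed 1 --out scene/
phagotrace quantify --stack scene/stack.ome.tif \
    --annotations scene/annotations.json --channel lgg_mcherry --out tc.csv
phagotrace events --timecourses tc.csv --threshold 1.5 --out events.csv
```

A run directory contains the OME-TIFF stack, ground-truth and annotation
JSON sidecars, `timecourses.csv`, `events.csv`, time-course plots, and the
resolved config + seed for exact replay (noise-free reruns are
byte-identical).

## Layout

- `src/phagotrace/photophysics.py` — pH-dependent emission model
- `src/phagotrace/kinetics.py`, `simulate.py`, `scene.py` — kinetic
  parameters, genotype presets, stochastic simulation, ground truth
- `src/phagotrace/render.py` — PSF/noise rendering into image stacks
- `src/phagotrace/quantify.py` — ROI measurements (boxes, polygons, FWHM)
- `src/phagotrace/events.py` — event times and censored histograms
- `src/phagotrace/puncta.py` — detection and colocalization
- `src/phagotrace/fit.py` — fusion-rate recovery from luminal curves
- `src/phagotrace/io.py`, `pipeline.py`, `cli.py` — OME-TIFF/JSON/CSV I/O,
  end-to-end runs, command line

See `docs/methods.md` for the model, its assumptions, parameter defaults,
and known limitations.
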