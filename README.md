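# pnpmetrics

Quantitative image analysis of surface-ectoderm (SE) mechanics during spinal
neural tube closure.

During mammalian neurulation the neural plate folds and "zippers" shut; the
last opening, the posterior neuropore (PNP), is covered by a single cell
layer of surface ectoderm whose mechanics — regional tension, cell shape,
an F-actin cable at the neural-fold boundary, and mechanosensitive YAP
nuclear translocation — shape the outcome. Measuring any of this from
confocal stacks requires a chain of image-quantification steps, each easy to
get subtly wrong. `pnpmetrics` implements that chain as a tested, reusable
library for developmental biologists and image analysts:

* **Surface extraction** — locate the superficial cell layer in a z-stack
  (argmax of the z-smoothed reference channel, median-filtered) and
  max-project a thin band below it, discarding signal from the deeper
  neuroepithelium ("surface subtraction").
* **Cell morphometry** — watershed segmentation of the membrane channel and
  moment-ellipse descriptors per cell: aspect ratio = long axis *x* / short
  axis *y*, and the angle *z* of the long axis from the rostrocaudal axis,
  folded to [0, 90]°; grouped midline-vs-lateral, per-zone summaries.
* **Nuclear YAP** — morphological nucleus segmentation, the classical
  particle filter (area 2–100 µm², circularity 4πA/P² in 0.6–1, Crofton
  perimeter), per-nucleus YAP/DAPI ratios, spatial gradients (Pearson r with
  a binned heatmap on the reflected half-plane) and nuclear:cytoplasmic
  ratios from a perinuclear ring.
* **Ablation recoil** — landmark tracking by normalised cross-correlation
  with subpixel refinement; recoil = d(first post frame) − mean d(pre
  frames) under the 2-pre + 18-post, ~0.9 s/frame protocol; kymographs;
  block-matching PIV after a difference-of-Gaussians bandpass.
* **Closure-site geometry** — F-actin cable peak/mean line-profile
  statistic, zippering-point curvature by Kåsa circle fit of rim points,
  dorsolateral hinge-point angles from YZ reslices, and zone assignment.
* **Statistics** — the grouping, pairing and unit-of-analysis conventions
  for these measurements (nucleus → embryo aggregation to avoid
  pseudo-replication), delegating the classical tests to scipy/statsmodels.
* **Synthetic scenes** — generators for every input above with stored
  ground truth (programmed cell anisotropy, YAP gradients, exponential
  recoil, cable amplitude, circle radius, hinge angles), so the entire
  pipeline is testable without any microscope data.

See `docs/methods.md` for the models, parameter defaults and numerical
choices.

## Worked example

Generate a synthetic sheet scene (curved SE layer over a deeper confounding
layer, elongated midline cells, a programmed mediolateral YAP gradient), run
the pipeline, and compare against the scene's ground truth:

```python
from pnpmetrics import synth
from pnpmetrics.surface import extract_surface, project_band
from pnpmetrics.cells import segment_cells, fit_all_ellipses, midline_elongation_summary
from pnpmetrics.nuclei import segment_nuclei, filter_particles, measure_nuclei, ratio_gradient

params = synth.SceneParams(seed=1)          # 200x200 um, 0.5 um/px, ~200 cells
stack, truth = synth.make_sheet_scene(params)

depth = extract_surface(stack, "membrane", intensity_floor=1.0)
proj = project_band(stack, depth, band_um=10.0)

labels = segment_cells(proj.channel("membrane"), proj.pixel_size_um)
records = fit_all_ellipses(labels, proj.pixel_size_um)
print(midline_elongation_summary(records, truth.annotation).to_string(index=False))

nuc = filter_particles(segment_nuclei(proj.channel("dapi"), proj.pixel_size_um),
                       proj.pixel_size_um)
recs = measure_nuclei(nuc, proj.channel("yap"), proj.channel("dapi"),
                      truth.annotation, proj.pixel_size_um)
grad = ratio_gradient(recs, "mediolateral")
print(f"nuclei n={grad.n}  mediolateral YAP/DAPI gradient r={grad.r:.3f}  p={grad.p:.2e}")
```

Output:

```
 zone    side  n  median_aspect_ratio  median_orientation_deg
    1 lateral 31             1.118123               38.830012
    1 midline 11             1.963500                3.936985
    2 lateral 37             1.127230               51.556552
    2 midline 17             2.342817                4.652067
    3 lateral 36             1.142211               47.318860
    3 midline 13             2.072912                3.128268
nuclei n=191  mediolateral YAP/DAPI gradient r=-0.957  p=3.39e-103
```

Midline cells recover the programmed elongation (aspect ≈ 2 oriented a few
degrees off the rostrocaudal axis) while lateral cells stay near-isotropic
at random orientations, and the per-nucleus YAP/DAPI ratios fall with
distance from the midline as programmed. An ablation movie runs the same
way:

```python
from pnpmetrics.ablation import track_landmarks, compute_recoil

aparams = synth.SceneParams(seed=1, recoil_A_um=2.0, recoil_tau_s=3.0)
series, atruth = synth.make_ablation_series(aparams)
pos, conf = track_landmarks(series)
res = compute_recoil(pos, series, conf)
print(f"recoil = {res.recoil_um:.3f} um (truth {atruth.first_post_recoil_um:.3f}), "
      f"rate = {res.recoil_rate_um_s:.3f} um/s")
```

```
recoil = 0.509 um (truth 0.518), rate = 0.565 um/s
```

i.e. the tracked landmark separation recovers the simulator's closed-form
first-frame recoil `A(1 − e^(−0.9/τ))` to within the tracking tolerance.

A thin CLI wraps the same functions (`pnpmetrics synth|surface|cells|yap|
geometry|validate ...`); run `pnpmetrics --help` for the subcommands.

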