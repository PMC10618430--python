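# Methods

`pnpmetrics` quantifies surface-ectoderm (SE) mechanics at the closing spinal
neural tube from multi-channel confocal stacks: the SE is a single cell layer
over the much thicker neuroepithelium (NE), and every downstream statistic —
cell shape, nuclear YAP, cable enrichment, ablation recoil — is computed on a
2D projection of just that superficial layer. This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
scenes do and do not establish.

## Surface extraction

For each (y, x) column of the reference channel (normally the membrane
stain), the column profile is Gaussian-smoothed along z with sigma of one
z-step and the surface depth is the argmax. The depth map is then cleaned
with a 2D median filter (default radius 5 px). Columns whose maximum
intensity falls below `intensity_floor` are invalid and excluded; the default
floor is the Otsu threshold of the per-column maxima, which is the right
choice when a substantial part of the field is empty background. When the
tissue fills the field (as in the synthetic sheet scenes) Otsu would split
the unimodal distribution of tissue columns, so a low explicit floor should
be passed instead.

The projection is a max-projection over `z in [surface, surface + band_um]`
with `band_um = 10` by default — the SE is a single cell layer of roughly
that thickness. The argmax criterion assumes the superficial layer is the
brightest structure in the reference channel along each column; a deeper
layer that is brighter *in the reference channel* would capture the depth
map. Projection never invents signal (each projected pixel is bounded by its
column maximum) and the whole stage is deterministic.

## Cell morphometry

Cells are segmented from the membrane channel by marker-based watershed.
Markers are the regional minima of the smoothed image after suppressing
minima shallower than `marker_depth` (default 5% of the smoothed intensity
range, an h-minima transform). We initially used point minima separated by a
minimum distance; regional minima with depth suppression proved markedly more
robust on both noise-free and noisy sheets (exact label counts on the
noise-free Voronoi scene), and is the form we ship. Labels below
`min_cell_area_um2` (default 20) are merged into the background and
edge-touching cells are flagged and excluded from shape statistics, since a
truncated pixel set biases the moment ellipse.

Each cell is summarised by the ellipse with the same second central moments
as its pixel set (axes `4*sqrt(eigenvalues)` of the pixel covariance — the
convention under which a uniformly-filled ellipse reproduces its own axes).
The aspect ratio is major/minor and the orientation is the angle of the long
axis from the rostrocaudal (image row) axis, folded into [0, 90] degrees
because an ellipse axis is axial, not directional. Which polygon-axis
convention the original interactive tools used is not documented; we
standardise on image moments. Orientation accuracy degrades continuously as
aspect approaches 1 — for a circle it is undefined — so records with aspect
below 1.05 are flagged isotropic, and recovery tolerances (2 degrees on
rasters with minor axis of 16 px and up) are only meaningful for cells with
aspect around 1.2 or more.

Group summaries report the median aspect ratio and median orientation per
(zone, midline/lateral) group. Orientations are folded axial values on the
bounded interval [0, 90], where the ordinary median is well-defined; no
circular statistics are needed after folding.

## Nuclear YAP quantification

Nuclei are segmented from the DAPI projection: white top-hat at the nuclear
scale (radius 5 um), Otsu threshold, hole filling, 1-px opening, then a
distance-transform watershed to split touching nuclei. Particles are kept if
area is within 2–100 um^2 and circularity `4*pi*A/P^2` within 0.6–1, both
ranges closed. The perimeter is the 4-direction Crofton estimator:
boundary-pixel counting overestimates P by ~5% and would push genuinely round
nuclei below the 0.6 cut. Crofton itself still rasterises slightly high for
small disks (circularity can exceed 1 marginally), so the value is clamped at
1.0 *for filtering only* — the convention of standard particle analyzers —
while the raw value is kept on the record.

Per nucleus we report mean YAP, mean DAPI, and their ratio (the
staining-density-controlled translocation readout), plus position:
`mediolateral_um` is the unsigned distance to the annotated midline — both
sides reflected together under the bilateral-symmetry assumption — and
`rostrocaudal_um` is the distance from the zippering point, positive
rostral. Gradients are Pearson correlations of the ratio against one axis,
with a binned-mean heatmap for display; fewer than 10 valid nuclei is
refused as under-powered. The nuclear:cytoplasmic ratio uses a perinuclear
ring: the nucleus dilated by `ring_um` (default 2 um — unstated in typical
protocols, so a declared configurable constant) minus *all* nuclear masks,
so neighbouring nuclei never contaminate the cytoplasmic estimate; empty
rings in crowded fields are flagged. All measurements are 2D on the
projection, though nuclei are 3D objects; at one-cell-layer depth the
projection collapses little axial structure.

## Ablation recoil

The acquisition protocol is 2 pre-ablation frames, the cut, then 18
post-ablation frames at ~0.9 s/frame. Recoil is `d_post − d_pre`, where
`d_pre` is the landmark separation averaged over pre-frames and `d_post` the
separation at the first post-ablation frame. Only the initial recoil is the
tension readout — later frames mix viscous relaxation — and a rate
(recoil divided by one frame interval) is reported alongside the
displacement, with axes labelled, since either convention appears in
practice. Borders up to 45 degrees from the rostrocaudal axis (inclusive,
the tie-break) are classed as mediolaterally-cut / rostrocaudal-recoil, and
vice versa. Exclusions (cuts hitting two borders, blebbing damage) are
manual input flags, mirroring how such ablations are screened by eye.

Landmarks are tracked by normalised cross-correlation of a template cut from
the mean pre-frame, within a +/-10 px search window, with parabolic subpixel
refinement; the peak correlation is the per-frame confidence and frames
below 0.5 flag the result. The default template radius is 9 px: on the
simulated recoil scenes this halves the subpixel error compared with a 5 px
template (more texture constrains the correlation peak) and keeps the
worst-case estimator bias on the exponential-recoil simulator near 3%,
comfortably inside the 10% design tolerance. The same matching engine drives
the block-matching PIV (difference-of-Gaussians bandpass, default sigmas
1 and 8 px; 32 px windows, 8 px search). PIV vectors are only emitted for
windows whose full search region fits inside the frame — a clipped search
region cannot represent displacement towards the missing side.

## Closure-site geometry

* **Cable statistic** — a mediolaterally-oriented line of constant physical
  length (default 100 um; fixed per experiment) through the zippering point,
  width-averaged over 3 px, sampled at pixel pitch. The statistic is
  peak/mean of the profile: exactly 1 for a uniform image, invariant to
  intensity rescaling, monotone in cable amplitude. The peak is the profile
  maximum wherever it sits, so a cable offset from the nominal ZP is still
  captured.
* **ZP curvature** — algebraic (Kasa) least-squares circle through
  user-annotated rim points; exact for three points (the circumcircle).
  Radius and 1/radius are both reported with unambiguous labels, because
  "curvature" is used loosely in this literature for a blunter (larger
  radius) zippering point; we expose both rather than resolve intent.
  Collinear points are flagged degenerate and reported as curvature 0.
* **DLHP angle** — for each side, the angle at the annotated hinge vertex
  between two ray points on a YZ reslice, via the inner-product formula;
  the reported measure is the mean of the left and right angles
  (scale-invariant by construction).
* **Zones** — zone from rostrocaudal ranges relative to the ZP; midline
  class when the unsigned mediolateral distance is within the configured
  half-band. Positions outside all zones are unassigned and excluded from
  grouped statistics.

## Statistics

Classical tests (t, paired t, Mann-Whitney, one-way ANOVA with Tukey
post-hoc, Pearson, OLS with F-test) are delegated to scipy and statsmodels;
the module owns grouping, pairing, unit-of-analysis aggregation and output
conventions (mean +/- SD for parametric summaries, quartiles for
non-parametric). The unit of analysis is enforced: nucleus- or
ablation-level rows are aggregated to per-embryo means before embryo-level
tests, because thousands of nuclei from a handful of embryos are not
independent observations and treating them as such (pseudo-replication)
wildly overstates significance. Paired comparisons (e.g. midline vs lateral
within embryo) pair on the embryo identifier. The choice of parametric vs
non-parametric test is the caller's, stated per comparison, as there is no
single normality criterion that fits every measure.

## Synthetic scenes

The generators produce exactly the image features the estimators consume,
with every programmed parameter stored as ground truth; they are first-class
tested code, and their defaults are the study conditions.

* **Sheet scene** — a Voronoi tessellation of a jittered seed lattice;
  inside the midline band the lattice is anisotropic (spacing stretched
  along the rostrocaudal axis by sqrt(aspect), compressed mediolaterally by
  the same factor) so midline cells realise a programmed aspect ratio of 2.5
  at 0 degrees, while lateral seeds are isotropic with jitter giving mild
  random elongation (~1.2). This "stretch, tessellate, unstretch" lattice is
  far simpler than a mechanical vertex model and sufficient for testing
  measurement code — it makes no claim about tissue mechanics. The membrane
  channel is the rasterised border network plus a diffuse cytoplasmic level
  (so every column carries surface signal for depth detection); each cell
  carries one 3 um nucleus with uniform DAPI (100) and a YAP level following
  a programmed spatial gradient. The superficial signal is painted into a
  Gaussian z-band (sigma 1.5 um) centred on a smooth parametric surface
  `z(x) = 5 + 3 sin(x/20)` um; the confounder — a smooth random texture
  standing in for the bright NE — is painted 15 um deeper in all channels,
  at 70% amplitude in the membrane reference channel (consistent with a
  membrane dye labelling the surface layer best). Gaussian read noise
  (sigma 20 on a 200-amplitude scene, SNR 10) and optional Poisson noise are
  applied last.
* **Nucleus table** — the same gradient statistics without the imaging
  round-trip: positions uniform on the reflected half-plane, ratio =
  baseline + slope x coordinate + Gaussian noise (sd 0.9, so a slope of
  −0.01/um over a 100 um half-width implies a population r near −0.3). The
  implied population correlation is stored so sign-recovery claims can be
  conditioned on it. Used for estimator-level checks at large n, where
  rendering 20 full scenes would buy no additional coverage.
* **Ablation series** — a smoothed random texture cut along a mediolateral
  line; the two halves translate rigidly apart so the landmark separation
  follows `d0 + A(1 − exp(−t/tau))` with the first post frame at t = 0.9 s;
  the cut band is darkened post-ablation. SNR is texture-contrast sd over
  read-noise sd (default 5). Landmarks are placed with random subpixel
  offsets so raster phase never aligns across seeds — otherwise
  peak-locking in the subpixel interpolation would masquerade as a
  systematic bias. Simulation grids in tests use A in {0.5, 1, 2} um and
  tau in {1, 3, 10} s.
* **Geometry scene** — a V-shaped Gaussian ridge (amplitude 150 over
  background 50, sigma 2 um, V angle 60 degrees) opening caudally from the
  ZP; rim points exactly on a circle of 25 um; a YZ-reslice with walls
  rendered at programmed hinge angles (70/74 degrees), from which ray
  points can be auto-placed by angular peak-finding around each vertex.

What the scenes do **not** emulate: real membrane texture and varying
staining efficiency, curved/folded (multi-valued) surfaces, cell
rearrangement over time, out-of-plane motion during ablation, anisotropic
PSFs, bleaching. Passing tests therefore demonstrate estimator correctness
under the stated forward models — unbiased recovery of programmed geometry,
gradients and recoil at realistic noise — not segmentation robustness on
arbitrary real images.

## Problem sizes and tolerances

Default scenes are 200 x 200 um at 0.5 um/px (400 x 400 px, ~200 cells,
~29 z-slices); ablation scenes 128 px (256 px for PIV) at 0.25 um/px with
the 2+18-frame protocol. These sizes give every estimator hundreds of
measured objects or windows while keeping a full test run of the suite in
well under a minute per stage. Key tolerances: surface depth within one
z-step at >=95% of columns; >=95% / <=5% band-projection energy separation;
ellipse aspect within 5% and orientation within 2 degrees (minor axis >=16
px, aspect >=1.2); Pearson r identical to the direct formula to 1e-9;
recoil bias below 10% over the A x tau grid at SNR 5 (20 seeds); PIV
translation within 0.2 px; circle radius exact to 1e-6 relative on
noiseless points and within 2% at 0.5 px noise; cable ratio within 2% of
the analytic Gaussian-ridge value.

## Known limitations

* The surface model is single-valued z(x, y); folded topologies are out of
  scope.
* Argmax surface detection requires the superficial layer to dominate the
  reference channel; it has no notion of "first layer from the top".
* Intensity images may be 8- or 16-bit (or float); no maximum value is ever
  assumed, and thresholds are always data-derived or explicit.
* Nuclear measures are 2D projections of 3D objects.
* Recoil is reported as measured displacement/rate only; no viscoelastic
  model is fitted to the relaxation curve.
* The midline/lateral reflection assumes bilateral symmetry; any true
  left-right asymmetry is averaged away.
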