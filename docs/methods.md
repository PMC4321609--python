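# Methods

## Scope and model

The package quantifies spindle size asymmetry (SSA) of single metaphase
cells as a normalized percent difference between the two half-spindles,
either from segmented voxel volumes (Δ_V) or from projected pole areas (Δ),
and provides the geometric theory connecting the two. Both measures are
folded (non-negative): the larger pole is labelled "left" by convention, and
ties keep the input order (the label is arbitrary and the difference is 0).
Signed variants are deliberately not exposed; population-level variation is
modelled with folded-normal distributions accordingly.

A spindle pole is idealized as a solid of revolution: a continuous shape
function *f* on [0, 1] with f(0) = 1 and f(1) = 0, scaled by a diameter *d*
(at the metaphase plate) and a width *w* (plate to centrosome). The two
poles share *f* and the revolution axis and differ only in (d, w). This
captures the observed geometry — two single-lobed, approximately
axisymmetric microtubule asters meeting at the plate — and excludes astral
microtubules, midzone structure and non-axisymmetric deformation.

## Theory module

Volumes and cross-sections come from Pappus' centroid theorem reduced to
two normalized quadratures, I₁ = ∫f du and I₂ = ∫f² du:
A(D) = (dw/2) I₁, r̄ = d²w I₂ / (8 A(D)), V = 2π A(D) r̄ = (π d² w / 4) I₂.
Composite Simpson with 512 intervals is the default; the integrands are
smooth (the spheroid profile has an endpoint square-root singularity in the
first derivative, which costs area accuracy ~1e−5 relative but leaves the
volume exact because I₂ is polynomial). A brute-force oracle
(`voxel_volume_oracle`) counts cubic grid cells inside the revolved region
and is used in tests as an independent check at the 2 % level; it shares no
code with the quadrature route.

Two conventions deserve a note:

- **Radius vs diameter in the spheroid closed form.** The classical
  half-spheroid formulas V = 2πd²w/3 and A = πdw/2 treat d as the equatorial
  *radius*, while the general revolution region r ≤ (d/2)f(x/w) and the cone
  formulas treat d as the *diameter*. `spheroid_closed_form` keeps the
  classical printed form; cross-checks against the Pappus route therefore
  use a region of diameter 2d. Every asymmetry statistic is a ratio and
  independent of this choice.
- **The affine envelope.** For area-ordered poles the exact relation is the
  Möbius map Δ_V/100 = (x + e)/(1 + e·x) with x = Δ/100 and
  e = ε(δ)/100 = (δ−1)/(δ+1). This map is concave for δ > 1 and convex for
  δ < 1, so chord and tangent on [0, 1] give the valid affine envelope
  min(δ, 1/δ)·Δ + ε ≤ Δ_V ≤ max(δ, 1/δ)·Δ + ε. The simpler coefficients
  min/max(δ, 1) sometimes quoted for this envelope fail as a bound for
  moderate Δ (e.g. δ = 1.09, Δ = 33.3 gives Δ_V = 37.11, below
  Δ + ε = 37.64); the implemented pair is provable for all δ, coincides with
  the simpler pair at δ = 1, and preserves the substantive conclusion —
  quasi-linearity with slope near 1 for δ near 1. Property tests assert
  containment over ≥1000 random models with zero violations.

Random shape functions for property suites are shape-preserving cubic
(PCHIP) interpolants through random knots with a 0.03 minimum knot spacing;
monotone decreasing profiles (single-lobed poles) are the primary family and
non-monotone non-negative profiles are sampled as a secondary family. PCHIP
never overshoots the knot range, so non-negativity is structural.

## 3D pipeline (volume3d)

Stages: rectangular ROI crop → per-section thresholding → small-component
removal → pole assignment → voxel-count volumes in μm³ using the anisotropic
voxel dimensions (dz, dy, dx). Design choices:

- **Thresholding.** Default is Otsu per optical section (sections are
  thresholded independently, tolerating axial attenuation), with each
  section's level floored at the whole-stack Otsu threshold. The floor
  matters: a section containing no spindle signal, or only an oblique sliver
  of one pole, would otherwise adapt its threshold to noise and flood the
  mask; the floor also removes a tilt-dependent bias (oblique apex sections
  getting systematically generous thresholds). A fixed global level is
  available as an override.
- **Connectivity.** 26-connectivity for cleaning; pole selection grows the
  seeded region with 8-connectivity within each section unioned across
  neighbouring sections, emulating section-wise wand selection. The default
  minimum fragment size is 5 voxels (configurable).
- **Touching poles.** When thresholding does not separate the poles (no
  intensity gap at the plate), the mask is split by the plane normal to the
  centrosome–centrosome axis (detected from the pericentrin channel, with
  the mask's principal axis as fallback). The plane is anchored at the
  DNA-channel intensity centroid — the condensed chromosomes mark the
  metaphase plate directly — rather than at the mask centroid, which lies
  inside the larger pole for asymmetric spindles and would bias Δ_V toward
  0. The split is also chosen over seeded growth when the mask has no
  substantial second component (second-largest < 10 % of largest), so stray
  surface crumbs cannot masquerade as a pole. Automatic runs record in
  provenance whether the plane split was used.
- **Diameter ratio on images.** δ is a theory quantity; when needed from
  data it would be the maximal mask extent perpendicular to the centrosome
  axis per pole. The pipeline does not report it by default.
- Intensities are accepted at any non-negative scale (8/16-bit or float).

## 2D pipeline (area2d)

Maximum-intensity projection of the tubulin channel; pole domains either as
externally supplied polygon ROIs (simple CSV dialect: label, vertex_index,
x, y; areas by shoelace × pixel area via shapely) or by an automatic
splitter that thresholds the projection, keeps all substantial components
(the plate gap may split the spindle in two), and divides the mask along the
line normal to the projected centrosome axis through the projected
DNA centroid. Auto mode is flagged in provenance. Overlapping ROIs are
rejected rather than clipped, because the two areas must partition the
spindle. ImageJ binary .roi files are not read; the CSV dialect is the
interchange format.

Quality control follows the acquisition criteria for real cells: exactly two
pericentrin puncta of equal size (integrated intensity ratio ≤ 1.2 by
default; the threshold-free half-prominence detection is preceded by light
Gaussian smoothing). The spindle tilt α = atan2(Y, X) in degrees, with X the
in-plane and Y the axial centrosome separation, is recorded per cell;
`angle_vs_ssa` reports the Pearson correlation of α with Δ, which should be
indistinguishable from zero — projection of a tilted spindle shortens both
pole areas about equally, a claim the test suite checks on rendered spindles
at α up to 20°.

## Statistics (ssa_stats)

- **Folded normal.** pdf(x) = [φ((x−μ)/σ) + φ((x+μ)/σ)]/σ on x ≥ 0, with
  μ ≥ 0 for identifiability. Fitting is numerical MLE (L-BFGS-B on (μ, log σ)
  with a μ ≥ 0 box, method-of-moments start via E[X²] = μ² + σ², three
  starts to avoid the μ = 0 ridge). Requires n ≥ 10 and a non-degenerate
  sample. Tests cross-check against an independent library implementation.
- **Permutation test.** Statistic |mean(a) − mean(b)|, two-sided by
  construction; default 10,000 shuffles; p = (1 + #{≥ observed})/(n_perm+1)
  (add-one: never zero, exactly valid under exchangeability). The raw
  proportion #{≥ observed}/n_perm is available via `add_one=False` for
  compatibility with conventions that report k/n_perm. Seeds are mandatory
  and recorded in the result.
- **Regression bands.** OLS (delegated to statsmodels); pointwise 95 % band
  ŷ(x) ± t₀.₉₇₅,ₙ₋₂·SE(ŷ(x)); Working–Hotelling simultaneous band with the
  √(2F₀.₉₅;₂,ₙ₋₂) multiplier appropriate for a two-parameter line, so it
  contains the pointwise band at every x.
- **Stage comparison.** Per-stage folded-normal fits plus permutation tests
  of each stage against a reference stage (first stage by default). Raw
  p-values are the default; Holm adjustment is optional and reported
  alongside, never silently substituted.

## Synthetic data (synthetic)

The renderer emulates the acquisition conditions of the original
experiments: anisotropic voxels (0.045 μm laterally, 0.3 μm axially — within
the 0.2–0.6 μm range used on real cells), anisotropic Gaussian PSF
(σ = 0.08 μm lateral, 0.25 μm axial, a standard confocal approximation),
Gaussian intensity noise at SNR 10 by default (the original study reports no
SNR; tests sweep noise-free and SNR 10), pericentrin puncta at the pole
apexes with a configurable size ratio, a DNA disc at the plate, and a
tubulin-sparse gap at the metaphase plate (fractional dip 0.85, Gaussian
half-width 0.12 μm) whose purpose is the one visible in real images: letting
section-wise selection separate the poles. Voxel centers are offset half a
voxel from the equatorial plane so no voxel column straddles t = 0 exactly
(which would be assigned wholly to one pole and bias Δ_V by ~2 points at
axial sampling). Ground truth is computed analytically from the generating
model, never from the raster; rendering is bit-reproducible given the seed.

The population generator draws per-stage Δ from folded normals — the default
five-stage series (μ = 4, 7, 10, 14, 8; σ = 4, 5, 6, 7, 5; n = 64, 64, 66,
64, 64, totalling 322 cells) rises to a mid-series peak and falls, the
kinetics seen across cortical neurogenesis — plus diameter ratios
N(1.09, 0.12²) (clipped to [0.6, 1.8]) and half-normal tilt angles with an
8° scale. Each sampled (Δ, δ) pair is inverted in closed form into a
spheroid-pole model (area ∝ d·w, so the width ratio is
(100+Δ)/(100−Δ)/δ), from which Δ_V follows analytically.

What the generator does **not** emulate: astral and midzone microtubules,
chromosome morphology beyond a flat DNA disc, depth-dependent attenuation,
photobleaching, spectral bleed-through, and time series. Passing
recovery tests therefore demonstrate correctness of the measurement
pipeline under idealized optics, not robustness to every artefact of real
acquisitions.

## Problem sizes and numerical choices

Property suites use 100–1000 random models (seeds fixed in the tests);
pipeline recovery uses one noise-free render plus the median over three
noisy replicate seeds per condition at the default field of view
(~19 × 121 × 243 voxels); the calibration suite uses 500 null replicates of
a 400-shuffle permutation test and one 322-sample MLE recovery. The
acceptance script simulates 200 equal-diameter models. Quadrature tolerance
targets: volume agreement with closed forms at 1e−6 relative; centroid-ratio
identity at 1e−9 (the shared quadrature factors cancel exactly); oracle
agreement at 2 %; bound containment with 1e−9 slack.

## Known limitations

- The theory assumes both poles share one shape function; differential
  deformation (e.g. one flattened pole) breaks the δ-only reduction, though
  the bounds remain informative for mild violations.
- The plane-split fallback needs either a pericentrin channel (axis) and
  ideally a DNA channel (anchor); lacking both, the principal axis and mask
  centroid are used, which degrades accuracy for strongly asymmetric cells.
- Per-section Otsu assumes each informative section is reasonably bimodal;
  very low SNR (< ~8) degrades volume estimates faster than area estimates.
- The folded-normal MLE is near-unidentifiable for μ/σ ≲ 0.5 (the fold hides
  the location); the fitted μ may legitimately sit at 0 there.
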