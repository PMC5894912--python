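# Methods

## The measurement model

A segmented OCT volume yields a pixel count N: for every traced image
column (one A-scan position within one B-scan) the bleb spans the closed
axial interval [upper_z, lower_z], contributing `lower_z − upper_z + 1`
pixels, so a degenerate column with upper = lower still counts one pixel
(bleb margins taper continuously to zero thickness, and the closed-interval
convention keeps the count additive over disjoint column sets).  The volume
estimate is a pure product,

    V = x_pitch · y_pitch · z_pitch · N      (mm³ ≡ μL),

so every modelling question reduces to the three pitches and the count.

**Axis convention.**  Arrays are indexed `(b_scan y, a_scan x, depth z)`,
all 0-based — the acquisition order of a raster scanner that assembles
B-scans from A-scans.  A 90° scan angle swaps the two lateral axes and
their nominal scan lengths; measured volumes are invariant under the swap
by construction, which the tests assert exactly.

**Lateral calibration.**  Nominal scan lengths are not trusted; instead an
object of known diameter d (a ceramic ball, verified by caliper at
3.17 mm) is imaged, its en-face pixel diameter m is measured, and
`pitch = d / m`.  Repeated measurements give a sample SD s, which the
delta method propagates through the ratio: `sd(pitch) ≈ d·s/m̄²`.  A single
measurement reports sd = 0 with a warning rather than an error, because the
automated phantom pipeline measures once (its repeat variance is zero by
construction).

**Axial calibration.**  `z_pitch = axial_range_air / n_depth / n_medium`.
The scanner's axial range is an optical path length in air (7.4 mm
default); dividing by the number of depth samples gives the optical pitch
and dividing by the refractive index of the imaging medium converts to
geometric depth.  The default n = 1.336 is balanced salt solution, which is
essentially water at 1060 nm.  Both values are explicit parameters: the
formula is the standard OCT optical-to-geometric conversion, and users with
different scanners or media should override the defaults.  The axial pitch
is fixed by the source-laser clock and digitizer, so its uncertainty
contribution defaults to zero (but the budget keeps a configurable slot).

**Semicircle doubling.**  An opaque reflective ball shadows everything
beneath its top surface, so only the upper half can be traced.  The rule:
trace the top surface per column, close every B-scan's area with one fixed
baseline row shared across all B-scans, and double the resulting
semicircular areas.  The baseline defaults to the deepest visible
top-surface row — the estimated equator, which for a sphere is the row of
maximal lateral extent — and is configurable (`baseline_z`), since any
fixed line is admissible as long as doubling is interpreted against it.
The residual error of this rule is one equator slab of voxels, which the
half-sphere brute-force test bounds explicitly.

**Uncertainty.**  For a product of independently estimated factors the
first-order propagation of uncertainty is the root-sum-square of relative
SDs: `(σV/V)² = Σ (σi/xi)²`.  The approximation errs by under 0.5% for
component relative SDs up to 10% (for independent normal factors the exact
relative variance is Π(1+ri²) − 1); the tests verify it against a 10⁶-draw
Monte-Carlo simulation at 2% relative tolerance.

## The statistics battery

Reproducibility across instrument settings and graders is assessed with:

* **paired t** — classical two-sided test; identical conditions return
  t = 0, p = 1, while constant nonzero differences (zero variance, nonzero
  mean) raise a degenerate-data error rather than fabricating an infinite t.
* **ICC(A,1)** — two-way random, absolute agreement, single measure, with
  the McGraw–Wong F-based 95% CI (via pingouin).  Absolute agreement is the
  right flavour: the question is whether two scan settings give the *same
  number of microliters*, not merely correlated ones.  Negative estimates
  are truncated at 0 for reporting (the conventional presentation); the raw
  estimate is retained in the report object.
* **Wilcoxon signed rank** — exact null distribution for n ≤ 25 without
  ties, normal approximation otherwise; validated against full 2ⁿ sign
  enumeration.
* **Wilks' Λ for three repeated conditions** — the two pairwise-difference
  contrasts per subject reduce the problem to a one-sample Hotelling T²
  with p = 2: T² = n·d̄ᵀS⁻¹d̄, Λ = 1/(1 + T²/(n−1)), exact
  F = T²(n−p)/(p(n−1)) on (p, n−p) df.  Type-I error is verified by
  simulation (1000 null replicates, n = 7).
* **coefficient of variation** and a **delivery-device summary** whose
  percent error is signed by the device convention,
  (mean measured − intended)/intended — negative for under-delivery —
  whereas bleb dose comparisons report *loss* percentages,
  (intended − measured)/intended, positive when fluid is missing.  The two
  conventions coexist deliberately; each matches how its quantity is read.

All tests are invariant under volume-unit rescaling, which is asserted
directly.

## The phantom generator

Phantoms emulate the two validation objects with closed-form volumes so
that every pipeline stage has an analytic oracle:

* **ball** — sphere of diameter d tangent to a flat retinal bed
  (reflectivity 0.2) at 75% of the imaging depth; only a one-voxel-thick
  top-surface shell (0.95) is rendered, and with shadowing on every voxel
  strictly below that surface within the footprint is exact background.
  The shadow region carries no additive noise — physically it is
  signal-starved — which makes the shadowing contract deterministic.
* **bleb** — spherical cap of hypo-reflective fluid (0.05) on a bright RPE
  plane (0.9), with a 0.2 mm neurosensory-retina layer (0.85) draped over
  the dome and lying on the RPE outside the footprint.  An optional air
  bubble occupies the top of the bleb as a smaller cap of the same sphere,
  marked by a hyperreflective line at the retina–air interface — so the
  automated trace includes the bubble in the total, as a grader reading the
  retina's lower margin would, and the bubble volume is recorded separately
  in ground truth.  Optional leakage particles (small bright specks above
  the retina) carry a ground-truth volume fraction for surgeon-vs-measured
  comparisons.

Rasterization is by voxel-centre membership, unbiased as pitch shrinks; the
tests require < 5% volume error at characteristic-diameter/pitch ≥ 50 and
monotone improvement with finer pitch.  Noise is additive Gaussian on
intensity (default SD 0.05), clipped to [0, 1].

**What the phantoms do not model:** OCT speckle statistics, refraction and
fan-beam distortion, motion, vendor-specific intensity response, or the
irregular shapes of real blebs.  Passing the phantom battery therefore
demonstrates the correctness of the *geometry and arithmetic* (calibration,
counting, doubling, unit conversion, uncertainty combination) — not the
performance of automated segmentation on clinical images, which is out of
scope; real-data tracing is manual, supplied as boundary CSVs.  At the
default contrast the automated phantom tracer's threshold (0.5) sits 6–9
noise SDs from both tissue and background intensities, so recovered volumes
are deterministic in practice; the quoted recovery errors are dominated by
pixel quantization of the en-face diameter (±1 px on a ~68 px B-scan-axis
diameter ≈ 1.5%) plus rasterization, not by noise.

## Problem sizes and numerical choices

The validation battery runs at the full acquisition geometry — 128 B-scans
× 1000 A-scans × 512 depth samples, 6 mm (and 10 mm) nominal scans — with
20 seeds for the recovery sweep; unit tests use reduced grids (e.g.
64×300×256) where the full geometry adds nothing to the property under
test.  Bleb sizes for the sweep (15, 30, 42 μL) span the observed range of
delivered volumes, with base radii 2.2/2.5/2.764 mm and cap heights solved
numerically (Brent) from the cap volume formula; the largest case is the
~2.7 mm-tall bleb geometry.  Other choices:

* automated tracing threshold 0.5 on [0, 1] intensities; bright bands
  shorter than 4 voxels along depth are erased by a 1-D morphological
  opening before layer identification, so leakage specks cannot masquerade
  as the retina;
* en-face diameter threshold 50% of peak (symmetric edge estimator);
  connected components under 9 px are ignored as noise specks, and exactly
  one blob must remain or an ambiguity error is raised;
* en-face projection defaults to maximum intensity, the right statistic
  for a bright shell on a dim background;
* measured volumes are exact products of Python floats; reported tables
  round volumes to 3 significant figures and percentages to integers.

## Known limitations

* The ball recovery carries a small negative bias (≈ 2% at the default
  geometry) from diameter quantization and the one-voxel surface shell;
  it is well inside the 6% validation envelope but not zero.
* The air-bubble interface line occupies two voxels of the bleb's top,
  biasing bubble-bearing measurements low by roughly the bubble footprint
  × 2 voxels (≈ 1.4% on a 30 μL bleb with a 7.3 μL bubble).
* ICC confidence intervals inherit pingouin's two-decimal rounding of the
  CI bounds.
* The degenerate all-identical-measurement ICC returns a collapsed CI at
  the estimate, since the F-based interval is undefined with zero error
  variance.
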