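# Methods

## Model and measurement geometry

The pipeline quantifies antibody microdistribution on 2-D multichannel
fluorescence sections of xenograft tumors. Three co-registered channels are
assumed: a nuclei stain marking tissue (DAPI-type), the labeled antibody
(Cy5-type), and an intravascular lectin marking perfused ("functional")
vessels (Cy3-type). All geometry is computed in the (row, col) pixel frame;
distances are converted to µm by the pixel size.

Two penetration measurements share one boundary definition:

* **Edge profiles (line mode).** The tumor boundary is the sub-pixel
  0.5-level contour of the binary tumor mask (it runs halfway between
  foreground and background pixel centers). Anchors are spaced uniformly by
  arclength; at each anchor a line is cast along the inward boundary normal
  and the antibody channel is sampled bilinearly every `bin_width`
  (default: one pixel) to `max_depth_edge` (default 80 µm), truncating where
  the line exits the mask. Before sampling, pixels outside the tumor are
  replaced by their nearest in-tumor value so interpolation at the boundary
  does not average in the dark exterior.
* **Vessel profiles (distance-map mode).** Each vessel component claims the
  tumor pixels nearer to it than to any other component (Euclidean; exact
  ties go to the lower label). Its profile is the per-bin mean antibody
  intensity versus distance-to-wall, with the recorded abscissa of each bin
  the mean distance of the pixels it contains (more faithful than the
  geometric bin center when pixel counts grow with distance). Components
  are tagged *peripheral* when their centroid's edge distance is within the
  outer quarter of the edge-distance range, else *central*. A line mode is
  retained for the edge because the protocol it mirrors draws explicit
  perpendicular lines there; for vessels, where line placement would be
  arbitrary, the distance map is the default.

Profiles are aggregated per bin into mean ± sd (sample sd, n−1; sd = 0 is
reported with an n = 1 flag) and summarized two ways: `auc_raw`, the
trapezoidal integral of the mean profile in a.u.·µm, and a normalized `auc`
with intensity scaled to max 1 and distance to the profile span, a unitless
shape index in [0, 1]. Published AUC values for this kind of experiment are
printed on an instrument-specific scale whose normalization is not
recoverable, so no attempt is made to match that scale; `auc_raw` carries
unambiguous units and the normalized index is dimensionless. Group-level
AUC is computed in both orders — per-section AUC then averaged, and pooled
profiles then one AUC — and both are written to `auc.csv`.

Whole-tumor accumulation is Σ antibody intensity over tumor pixels divided
by tumor area (pixel count × pixel_size²), in a.u./µm².

An exponential-plus-baseline model `A·exp(−d/λ) + b` is fitted to mean
profiles by bounded least squares (`scipy.optimize.curve_fit`, trf; start
values from the profile's range and its 1/e crossing). Flat profiles are
rejected as unidentifiable rather than reported with a runaway λ.

## Segmentation

The protocol this pipeline mirrors traced tumor and vessel regions by hand;
here a reproducible automatic surrogate is used, with hand-drawn 8-bit mask
TIFFs accepted as an escape hatch. Tumor: Gaussian smoothing of the nuclei
channel (default σ = 2.6 µm), Otsu (or fixed) threshold, hole filling,
small-object removal (default 2000 µm²), largest connected component (ties
broken by first-pixel order for determinism). Vessels: threshold of the
lectin channel computed within the tumor, by default unsmoothed — vessel
lumina are only a few pixels across and smoothing erodes them; speckle is
handled by the minimum-area filter (default 20 µm²) — then optional
restriction to the tumor mask. An empty vessel result warns rather than
fails; vessel profiling is then unavailable.

**Inward normals.** The 0.5-level contour of a binary mask is a stairstep
polyline whose flat runs grow like √(2R) pixels where the boundary is
flattest, so a short-baseline tangent mis-aims normals by several degrees.
The tangent is therefore taken by central differences over ±10 vertices of
the contour *after* a circular moving-average smoothing of its coordinates
(window 41 vertices ≈ 20 px of arc); on a 185-px-radius circular fixture
the resulting normal rays pass within 1 px of the centroid. The window is
small against the lowest roughness wavelength the generator produces
(harmonics 2–5 of the outline), so real curvature is preserved; both knobs
are exposed in `ProfileParams`. The normal's sign is chosen so a short step
lands inside the mask.

## Synthetic data

`generate_section` emulates one section: a tumor disk perturbed by
low-frequency radial noise (harmonics 2–5, relative amplitude
`boundary_roughness`, default 0.08), vessels as random disks fully inside
the tumor with wall-to-wall separation ≥ 2 vessel radii, and the antibody
field `b + A_e·exp(−d_edge/λ_e) + A_v·exp(−d_vessel/λ_v)` inside the tumor
and 0 outside. Distances use the convention `d = (EDT − 0.5)·pixel_size`,
which places zero on the same sub-pixel boundary that `find_contours`
extracts, so the discrete field equals the closed form at pixel centers and
the profiling code and the generator agree about where the edge is.

Defaults describe a realistic acquisition: 1.3 µm/pixel (a 10× objective
with 2×2 binning), 320×320 px field, tumor radius 150 µm, 8 vessels of
radius 6 µm, amplitudes 1.0 over background 0.05, λ_e = 20 µm,
λ_v = 15 µm, and Poisson–Gaussian noise (signal-dependent shot noise with
gain 0.01 plus additive read noise of the same scale, ≈10:1 peak SNR).
Fidelity fixtures that compare sampled profiles against the *continuous*
closed form use 0.65 µm/pixel (full-resolution 10×) and a circular outline,
because (i) the first bin's discretization error scales with pixel size,
and (ii) only on a circle is the nearest-boundary distance along the normal
ray exactly the arclength — on rough outlines deep samples sit nearer to
some other boundary point, biasing deep bins upward relative to the 1-D
formula. `analytic_profile` is exact only when the other source's amplitude
is zero, so fidelity and λ-recovery studies use single-source sections.

`generate_cohort` emulates the efficacy arm: per animal, V(t) = V₀·exp(r·t)
with V₀ ~ N(200, 20²) mm³ (the enrollment condition), additive measurement
noise (sd 15 mm³), caliper readings every 3 days for 30 days, and a death
recorded at the first measurement exceeding 2000 mm³ (a typical
humane-endpoint limit; with r = 0.08/day the crossing sits near day 29, so
the default cohort mixes events and censorings), otherwise censoring at day
30. Default 10 animals per group with equal growth rates — the null regime
mirroring the no-difference outcome of the study design this emulates.

**What the generator does not emulate:** antigen-binding ("binding-site
barrier") kinetics, interstitial-pressure gradients, vessel tortuosity and
non-circular lumina, DAPI texture/nuclear instance structure, illumination
flat-field error, or section-to-section registration artifacts. Passing
tests therefore demonstrate that the measurement machinery is correct and
calibrated on fields with known structure — not that a particular biological
conclusion transfers to real tissue.

## Statistics

Kaplan–Meier curves use the product-limit estimator (via lifelines), with
deaths processed before censorings at tied times; group survival is
compared with the two-group log-rank test, and scalar endpoints (AUC,
accumulation, volume at a day) with a two-sided Welch *t*-test at α = 0.05
— the conventional defaults for this design; the tests sit behind one
module surface and are swappable. Both estimators are verified in the test
suite against hand-rolled risk-set computations, exactly on all random
small datasets. Error bars everywhere are sample sd (n−1).

Type-I calibration is measured on null cohorts with the death threshold at
infinity, comparing day-30 volumes: under equal rates that endpoint is a
Gaussian-propagated quantity for every animal, so the nominal α is the
exact target, uncontaminated by survivorship truncation of who reaches day
30.

## Numerical choices and degenerate inputs

* Trapezoidal integration for all AUCs (error O(bin_width²); ≈0.02%
  relative on the default 1-px grid against the exponential's closed form).
* Bin grouping in aggregation maps both exact grid distances (i·bw) and
  in-bin mean distances to a stable index via floor(d/bw + 1e-6).
* Constant images are segmentation errors; empty vessel masks are warnings;
  flat profiles are fit errors; tumors thinner than one bin are profiling
  errors; empty record lists and mixed schemas are usage errors.
* Determinism: every stochastic step derives from a single integer seed
  (per-section seeds are hashed from it); identical config + seed gives
  bit-identical TIFFs and identical result tables.

## Problem sizes

The demonstration study uses 2 groups × 3 tumors × 10 sections (the
sampling design of the protocol this pipeline mirrors: 30 profile units per
group) at 256×256 px, 36 edge lines per section; calibration studies use
20 noisy sections per source and 500 replicate null cohorts. These sizes
give stable means and Monte-Carlo error ≈1% on the rejection rate while
keeping a full run in tens of seconds.

## Known limitations

* 2-D only: each 8-µm section is analyzed independently; no 3-D
  reconstruction across serial sections.
* The exponential field is a phenomenological stand-in, not a
  diffusion/binding PK model, so regimen effects can only be *injected*
  (e.g. per-group λ overrides), not predicted.
* Automatic segmentation can sit ~1 px off the antibody support at the
  tissue edge, which mostly affects the 0-µm bin; hand-drawn masks can be
  supplied where edge delineation is critical.
* The normalized AUC is a shape index; it deliberately does not reproduce
  any instrument-specific published AUC scale.
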