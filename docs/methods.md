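# Methods

This note documents the measurement model, its tunable parameters, the
synthetic data the package is validated on, and the numerical choices made
where the procedure was genuinely open.

## Measurement model

Each focal adhesion is treated as a straight elongated object in an aligned
two-channel image with known pixel pitch (default 40 nm, the pitch of
reconstructed SIM images; an optional z-stack is averaged over selected
slices first). The quantity of interest is, per FA end, the distance along
the long axis over which exactly one channel remains above its positivity
threshold beyond the dual-positive core — the *protrusion length* — and the
identity of that channel.

### Segmentation

Candidates come from a difference-of-Gaussians band-pass (defaults
σ_low = 1 px, σ_high = 5 px, chosen to pass 8–12 px wide FA cross-sections;
the source procedure leaves the σ values open) followed by an Otsu threshold
(dark-background convention, 256-bin histogram, foreground strictly above
threshold) on the channel mean, and 8-connected labelling with area bounds
50–5000 px (0.08–8 µm² at 40 nm pitch). The channel that is thresholded is
configurable (`mean`, `green`, `red`); `mean` is the default since the
procedure does not name one. Interactive outline correction is replaced by a
plain-text edits file (`delete` / `split` with a polyline), which keeps runs
reproducible; split components are relabelled deterministically by bounding
box (top row, then left column), the ordering used for all region ids.

### Axis fitting

The initial axis is the intensity-weighted second-moment (ellipse) fit of
the region; regions with eccentricity < 0.05 are flagged isotropic and fall
back to the bounding-box diagonal. The axis is refined by least-squares
fitting baseline + amplitude·Gaussian to the perpendicular green-channel
profile at 1 px spacing along the initial axis (profile length 3× the region
minor extent, bilinear sampling); fits with positive amplitude and centre
shift under half the minor extent are kept, and a total-least-squares line
through the kept centres replaces the axis. Fewer than 3 usable centres
keeps the initial axis (flagged `ridge_fallback`). The green channel is used
for refinement; as a consequence, swapping the channels can move the
rasterized chain by one rounding step, so pipeline-level channel-swap
equality is exact only up to one step (profile- and statistics-level
antisymmetry is exact).

The line is rasterized with Bresenham's algorithm (8-connected) and extended
up to 50 px beyond the region at each end (the search distance is not
specified by the procedure; terminations that exhaust it are flagged). Each
end is cut at the last pixel before the 3×3 box means of *both* channels
fall below 30 % of their respective maxima along the chain; "maximum along
the line" is interpreted as the maximum of the box mean, applied
consistently. Paths shorter than 3 px discard the FA (flagged). The head is
the end whose minimum distance to the cell-enclosing rectangle is smaller;
the rectangle is the bounding box of a supplied mask or polygon, or of an
Otsu mask on the σ = 20 px blurred channel sum. Exact ties break toward the
end with the smaller (row, col).

### Profiles and protrusions

Raw per-pixel profiles are median-filtered with window 5; at the profile
ends the window is truncated (sizes 3, 4) rather than reflected — reflection
would fabricate data beyond the termination point, truncation only shortens
the window. Positivity is `filtered ≥ 0.40 × max(filtered)` per channel and
per FA (non-strict boundary, one consistent convention; the filtered maximum
is used for the threshold). The main stretch is the longest interval with
dual-positive endpoints whose interior runs of non-dual-positive pixels are
each ≤ 4 px; equal-length candidates resolve toward the head. At each end,
the pixel bordering the stretch decides: negative for both channels →
protrusion 0; positive for one → that channel's gap-tolerant (≤ 4 px) run is
followed outward and the protrusion is the path distance from the last
main-stretch pixel to the outermost positive pixel (gap pixels contribute
distance but not identity); positive for both (possible only for externally
supplied intervals) → the stretch first absorbs adjoining dual-positive
pixels. Lengths sum 40 nm straight and √3200 ≈ 56.6 nm diagonal steps,
scaled for other pitches. Protrusion length is the number of steps (not
pixels) from stretch boundary to run end, which makes a zero-pixel
protrusion exactly 0 nm and lengths additive along the path.

### Statistics

Signed values are green → +length, red → −length, none → 0, independently
per end. The reference ("pax/pax"-style same-protein) set's per-end median
is the measurement bias subtracted from every experimental signed value;
per-end estimation is strictly more general than a single shared bias and
collapses to it when the two medians agree. Histograms use 80 nm bins with
one bin centred on zero; a value exactly on a bin boundary is assigned by
round-half-even to the nearest bin centre, which makes the binning of v and
−v exact mirror images (measured lengths are often exact multiples of
40 nm). Mann–Whitney U uses mid-ranks; the two-sided p-value is exact — a
dynamic program over the permutation distribution of the pooled mid-rank
multiset, so ties are handled exactly — whenever n_x·n_y ≤ 400, and
otherwise a normal approximation with tie correction and a 0.5 continuity
correction. Medians are reported as protrusion lengths only when p < α
(default 0.05); no multiple-testing correction is applied. The 2D (head,
tail) histogram uses 80 × 80 nm bins over a symmetric data-driven range and
reports per-bin relative-frequency differences (percentage points); the LUT
maps Δ linearly to 8-bit levels via `round(255·(Δ+3.45)/6.90)` with levels
124–132 white, 0–123 cyan→white and 133–255 white→magenta.

### Edge motility

The t1 cell edge is traced as the largest 0.5-level contour; each edge point
gets the signed Euclidean distance to the t0 edge (+ outside the t0 cell),
smoothed by a circular 15 px moving average along the contour. Points with
|displacement| ≥ 200 nm are *moving* (protrusion and retraction pooled), the
rest *static*. An FA is classified by the majority class within one
smoothing window around its nearest edge point, or *disregarded* beyond
2 µm from the edge. All three numbers are package defaults that
operationalise a qualitative "close to a moving edge" notion; they are
exposed in the configuration and declared, not inferred.

## Synthetic scenes

The generator emulates the features of reconstructed dual-colour SIM data
that the measurement is sensitive to: elongated plateaus (core 25–50 px ×
8–12 px FWHM at 40 nm pitch, i.e. 1–2 µm × 320–480 nm), Gaussian
cross-profile, half-Gaussian (SD 1 px) longitudinal end falloff — a
sub-resolution edge that keeps the 40 % crossing within ~1.5 px of the
nominal end — and per-end single-channel extensions rendered as same-width,
same-intensity continuations of the plateau. Default intensities: background
100, peak 800–1200 (a.u.); default noise: additive Gaussian SD 15,
shot-like SD 0.5·√signal, and per-bright-patch Poisson(2) speckle holes of
diameter 3 px and fractional depth 0.6, punched only inside above-background
regions — the phenomenological stand-in for the correlated noise SIM
reconstruction leaves inside structures. FAs are placed in an annulus near a
12-vertex polygonal cell outline, radially oriented with ±15° jitter and
heads outward, with an enforced ≥ 5 px head-to-frame margin so ground-truth
orientation is unambiguous. Ground-truth protrusion lengths convert axis
pixels to nm with the closed-form step-rule factor
`pitch·(1−q+q√2)/√(1+q²)`, q = |minor|/|major| of the axis direction — the
average step-rule length per Euclidean pixel of an 8-connected chain, exact
for axis-aligned and 45° axes.

What the generator does *not* model: optical PSF and SIM reconstruction
proper, photobleaching, drift, chromatic misalignment, curved or branched
FAs, intensity differences between core and protrusion, and FA-dense fields
with touching adhesions. Passing tests therefore demonstrate correctness of
the measurement and statistics under the stated geometry and noise, not
robustness to every property of real micrographs.

A cheaper profile-level reference simulator
(`simulate_reference_measurements`) generates identical-channel plateau
profiles with independent per-channel noise and measures them with the
standard profile analysis; it supplies the large same-protein null sets used
for bias estimation and type-I-error calibration, where rendering thousands
of full scenes would be wasteful. The time-lapse generator displaces
programmed polygon edges along their outward normals (miter joins) and
rejects collapsed or self-intersecting outlines.

## Numerical choices and degenerate inputs

- Otsu on a constant image, an empty z-selection, an empty reference set,
  double bias correction, and edits referencing unknown region ids raise
  errors; all-zero profile channels, isotropic regions, ridge fallbacks,
  exhausted termination searches and discarded FAs are flagged in the
  per-FA QC field instead of failing the run.
- Exact Mann–Whitney p-values use float counts in the DP, exact for subset
  counts up to 2⁵³ — far beyond the n_x·n_y ≤ 400 exact-branch regime.
- Problem sizes in the validation suite — ~200 synthetic FAs per recovery
  condition, 1000 null repetitions at n = 500 drawn from a 30 000-FA
  simulated pool, exhaustive oracle sweeps to length 14 (dual-positive) and
  length 7 (full four-state pairs) plus 10 000 random longer profiles — were
  chosen to give stable rates at interactive runtimes on a single CPU.

## Known limitations

- FAs are assumed straight; strongly curved adhesions would need a spline
  axis.
- The near-edge/motion thresholds of the motility module are conventions,
  not fitted quantities.
- The measured protrusion carries a small positive bias (~1 px per
  protruding end) from the interaction of the truncated median window with
  the termination point; this is the kind of apparent length the reference
  correction exists to remove, and it cancels in all reference-subtracted
  statistics.
- Colocalization coefficients, FA maturity classification, watershed
  auto-splitting and full time-lapse tracking are out of scope.
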