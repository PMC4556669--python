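# Methods

## The measurement model

The assay quantifies new protein synthesis in a photoconverted axon as the
ratio of green (new, unconverted Kaede) to red (pre-existing, converted
Kaede) fluorescence. The red channel doubles as a structural marker: a
binary mask derived from it confines the green signal to the axon before
SUM projection and division. The ratio is sampled along a retrograde
1-pixel trace from the growth-cone tip (150 px = 32 µm at the default
calibration of 32/150 µm/px), averaged in fifteen 10-pixel bins, and
summarized by a two-level ordinary-least-squares statistic: spatial
gradient per timepoint, then the time slope of those gradients per axon
(the *gradient rate*). Local synthesis at the growth cone makes the
spatial gradient increasingly negative, so the gradient rate separates
axons with and without a functional localization element.

### Masking semantics

The red-to-green mask step is implemented in two modes because binary-mask
"subtraction" is ambiguous in 8/16-bit image arithmetic:

* `restrict` (default): green is retained only inside the red-positive
  mask. This matches the analysis intent — ratios stay finite along the
  axon — and is the mode used everywhere in this package's analyses.
* `literal_subtract`: green minus (mask × max intensity), clamped at 0 —
  the faithful saturating-arithmetic alternative, retained as an opt-in
  fidelity mode. Which mode ran is recorded in the mask metadata and the
  run config hash.

Auto-thresholding (Otsu by default; isodata offered because common
image-analysis defaults resemble it) excludes the dimmest PSF fringes of
the axon from the green SUM but not from the red SUM. On uniform synthetic
axons this produces a *position-independent multiplicative* downward bias
of the ratio (≈10–15 % at the default rendering settings). Because both
regression levels are invariant to multiplying all inputs by a constant,
this bias does not affect the gradient statistics; it does mean absolute
ratio values should not be compared across masking settings.

### Ratio validity

Pixels with red SUM below `min_red` (default 1 count) are undefined, never
0 or ∞; undefined pixels are excluded from bin means, and a bin with no
valid pixel is missing. Regressions need ≥ 3 non-missing bins (spatial) and
≥ 3 timepoints (rate); axons failing that are excluded with a logged reason.

### Statistics

* Spatial gradient: OLS of the 15 bin means against bin centres (5.5 …
  145.5 px; a µm axis is available and only rescales the slope). r² is
  defined as 0 for a constant profile.
* Gradient rate: OLS of spatial gradients against minutes after
  photoconversion (0, 10, …, 90 at defaults; t = 0 included by default,
  configurable).
* Mann-Whitney U: exact two-sided p by enumerating all C(n, n₁) rank
  assignments when the combined sample is ≤ 16 and tie-free (the cutoff
  makes a 6-vs-10 design always exact; the minimal two-sided p there is
  2/8008 ≈ 0.00025); otherwise the tie-corrected normal approximation with
  continuity correction. The exact branch computes the U null distribution
  by the standard counting recurrence, which is equivalent to full
  enumeration.
* Region comparison: one-way ANOVA with Tukey-Kramer HSD over the four
  (condition × region) groups of 90-minute bin means, growth cone = bin 1,
  proximal = bin 15.

## The synthetic-data generator

### What it emulates

One axon segment (initially 42 µm) in the 10-minute / 10-frame acquisition.
Concentrations of green G(s, t) and red R(s, t) Kaede live on the axon's
arc length s with the tip at s = L(t):

    ∂G/∂t = D ∂²G/∂s² − v ∂G/∂s + k_local·1[tip region],

with influx J_soma at the proximal boundary (soma-derived protein entering
the segment) and a closed (zero-flux) tip. Red is modelled as a stable
pool at transport equilibrium: diffusion plus optional photobleaching only,
which keeps R(s, t) non-increasing in time from its uniform post-conversion
state. The initial condition is the post-conversion state G = residual·R₀
(residual 0.05 — conversion "until green is undetectable"), R = R₀ = 1.

The solver is an explicit conservative finite-volume scheme (upwinded
advection, central diffusion) with internal substeps enforcing
D·Δt/Δs² ≤ 0.25 and v·Δt/Δs ≤ 0.5; with closed boundaries and no
reaction, total mass is conserved to machine precision. The tip advances by
extending the grid each frame; new cells copy the tip concentrations (the
growing tip carries its material forward). At the default Δs = 0.25 µm the
solution deviates < 2 % (relative to the field maximum) from a 4× refined
grid. An optional first-order maturation pool (`maturation_min`) delays the
appearance of fluorescent green; by default synthesis yields fluorescent
protein directly, because the assay measures net green appearance, not
folding kinetics.

Kinetic defaults (D = 1 µm²/min, v = 0.05 µm/min, J_soma = 0.02 conc·µm/min,
k_local = 0.01 conc/min in the distal 2 µm, bleach = 0) are **illustrative**:
in vivo values are unknown, and these were chosen once so that a +UTR
growth cone rises to a clearly elevated green/red ratio (~0.5) by 90 min
while −UTR axons stay near the residual level — the qualitative pattern the
assay is designed to detect. D is plausible for a slowly diffusing
tetramer in crowded axoplasm; v sits in the slow axonal-transport range.
Note that even −UTR axons acquire a small negative gradient rate: transport
and diffusion deliver some soma-derived and residual green to the closed
tip. This is a real feature of the control condition (soma-derived
trafficking), roughly 6–7× smaller than the local-synthesis signal at
defaults; the recovery tests therefore check contrast (|−UTR rate| below
0.2× the +UTR magnitude in noise-free runs) rather than an absolute zero.

### Rendering

The 1-D concentrations are painted onto a gently curved planar axon (tube
of radius 0.5 µm, disk of radius 1.5 µm at the tip), spread over 5 z-slices
with binomial weights, blurred with a Gaussian PSF (σ = 0.4 µm), scaled by
a photon gain (300 counts/concentration), Poisson shot noise, Gaussian read
noise (σ = 3 counts), constant background (10 counts), and quantised to 16
bits. A tip-anchored retrograde trace is emitted per frame — the growth
cone advances, so traces are re-supplied per timepoint, exactly as the
pipeline requires. All randomness comes from one seeded generator; cohorts
derive per-axon seeds as master + index, and +UTR axons draw k_local from a
lognormal (CV 0.3) around the default for biological variability.

### What it does not emulate

Real 3-D optics (the z-extent is a thin weight profile — sufficient because
the pipeline consumes SUM projections only), photoconversion optics, motion
or focus drift, registration error, autofluorescence structure, and tracing
error (true traces are exact). Passing recovery tests therefore shows the
*quantification chain* is correct and sensitive at realistic noise; it does
not validate segmentation or tracing against real microscopy artefacts.

## Spot counting

The 3-D counting stage uses multi-scale Laplacian-of-Gaussian blob
detection at cell-nucleus scales (2–6 µm) with the response threshold
expressed as a fraction of the maximum response (default 0.3, making counts
invariant to global intensity scaling), plus greedy non-maximum suppression
at a minimum separation (default 2× the smallest scale). The detector, its
scale range and threshold convention are this package's choices — the
counting is validated on planted-truth fixtures (Gaussian spots of σ = r/√3,
at which scale the detector reports radius r) and makes no claim of
reproducing any particular instrument's counts on real retinas. The
axon-to-soma ratio is plain bookkeeping on manual counts
(100 × n_axons / n_somata per projection, mean ± SEM across projections).

## Zipcode scanner

The bipartite element is GGACT, a spacer, then ACA; the spacer counts
nucleotides strictly between the parts. The default search range 5–15 nt
covers known vertebrate zipcodes (the zebrafish β-actin element has spacer
7); an exact-7 search is `--spacer 7:7`. Scanning is sense-strand only
(3'UTRs are mRNA-sense), U is normalized to T, IUPAC wildcards never match,
and all overlapping hits are reported — filtering is the caller's job.

## Numerical and design choices

* Coordinates 0-based (y, x); bins labelled 1-based in outputs to match
  the field's "pixels 1–10 … 141–150" convention.
* Trace resampling is exact arc-length parameterization of the input
  polyline; results are independent of vertex density. The tip is point 1
  (arc length 0), so 150 unit-spaced points need ≥ 149 px of trace.
* Nearest-neighbour sampling is the default (literal pixel lookup);
  bilinear is available for sub-pixel traces and agrees with nearest at
  integer coordinates.
* SUM projections accumulate in 64-bit to avoid 16-bit overflow.
* A constant volume has no object: auto-thresholding returns an empty
  foreground rather than an all-foreground mask.
* Hyperstack calibration falls back to 32/150 µm/px and 10 min/frame when
  metadata is absent (`strict_calibration=True` raises instead). A TIFF
  resolution tag is trusted only when a physical unit is declared.
* Problem sizes in the test suite (cohorts of 10 + 6 axons on 96×320×5
  frames, 20 replicate seeds for power and counting checks) were chosen as
  the smallest sizes at which the study-design comparisons are meaningful.

## Known limitations

* The simulator is 1-D kinetics + thin-plane rendering; it cannot probe
  z-dependent segmentation effects.
* Absolute ratio values depend on the masking mode and threshold (see
  above); only ratios of ratios / gradients are comparable across settings.
* The exact Mann-Whitney branch requires tie-free data; tied rates fall
  back to the normal approximation even at small n.
* `literal_subtract` faithfully reproduces saturating mask arithmetic and
  therefore destroys the in-axon green signal when the mask marks the axon
  as foreground; it exists for forensic comparison, not analysis.
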