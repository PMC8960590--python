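# Methods

`synaptomap` re-implements, as a tested library, a quantitative
fluorescence-microscopy workflow for mapping excitatory synapses and
tripartite synapses (synapses contacted by perisynaptic astrocytic
processes, PAPs) across spinal-cord laminae, and for quantifying the
nanoscale substructure of postsynaptic densities (PSDs) from paired
confocal / gated-STED imaging.  Because suitable raw image data cannot be
bundled, the package ships a forward model — a synthetic micrograph
generator with exact ground truth — and every stage of the analysis is
validated against what that generator planted.

## The measurement model

A field of view is a single optical section.  Each excitatory synapse is
represented by a PSD at a known position, composed of 1–4 PSD95
nanoclusters (NCs) of nominal diameter 140 nm (the literature range is
roughly 100–150 nm).  A configurable fraction of PSDs carries an apposed
presynaptic punctum (VGLUT2-like, centre offset 200 nm) and an
overlapping PAP punctum (centre offset 100 nm); a PSD with a PAP punctum
is, by definition in this model, a tripartite synapse.

Rendering inverts the analysis chain.  Every fluorophore site (NC centres
in the PSD channel; partner centres in the presynaptic and PAP channels)
becomes an isotropic Gaussian spot whose full width at half maximum is
`max(psf_fwhm, structure_size)`; confocal-like optics default to a
320 nm PSF, STED-like optics to 70 nm.  A constant background is added,
then Poisson shot noise (scaled by `poisson_scale` photons per intensity
unit) and Gaussian read noise; both noise terms can be switched off
independently for noise-free oracle renderings.  Output is quantised to
the 16-bit camera range.  Large saturating discs (3–6 µm) can be injected
to mimic lipofuscin autofluorescence in aged tissue.

Two modelling consequences matter downstream:

* Under confocal optics, NCs spaced ≲ the confocal FWHM fuse into one
  suprathreshold blob — this is what makes a confocal object "the whole
  PSD".  Under STED optics the rendered spot FWHM equals the NC diameter
  (140 nm), so NC pairs are separable by a global threshold only beyond
  about twice that rendered width (≈ 280 nm).  The paired-frame studies
  therefore place NCs at 300 nm spacing; the mapping default is 150 nm
  (NCs packed inside a ~360 nm PSD footprint), where NCs merge under both
  modalities, which is correct at mapping resolution.
* The thresholded area of a Gaussian spot depends strongly on where the
  threshold sits relative to the peak; the equivalent-circular-diameter
  estimate is unbiased exactly at the half-maximum level.  The `sted`
  detection profile therefore thresholds at half the nominal punctum peak
  intensity, and recovered NC diameters land within a few percent of the
  planted 140 nm.

## Scene statistics

PSD placement per lamina is a homogeneous spatial Poisson process at the
region's density (default 20–40 puncta per 100 µm², denser dorsally) with
a hard minimum spacing (default 0.7 µm) so neighbouring PSDs remain
resolvable; counts stay Poisson because placement retries until the drawn
count fits, and placement failure raises an error naming the region.  The
tripartite fraction defaults to a per-region profile spanning 17 %
(lamina VII) to 28 % (laminae I–II), the range reported for astrocytic
contact percentages.  NC counts are drawn from a categorical distribution
over {1, 2, 3, 4}, default (0.45, 0.32, 0.15, 0.08), i.e. 23 % of PSDs in
the 3+ class and a mean near 1.9 NCs per PSD.  NC centres sit on a
randomly rotated regular polygon whose side equals the NC spacing, so the
minimum pairwise distance is guaranteed by construction.  All randomness
flows from a single seed; identical parameters reproduce byte-identical
ground truth and images.

The selective-vulnerability case condition is modelled by deleting a
fraction (default 40 %) of ground-truth tripartite entities — and only
those — before rendering.

## Detection

The detection chain follows the standard FIJI particle-analysis recipe:

1. rolling-ball background subtraction (default radius 50 px).  For radii
   ≥ 16 px the image is downscaled, the ball rolled on the reduced image
   and the background upsampled — the same shortcut ImageJ's Subtract
   Background takes; the background is smooth by construction, so the
   approximation error is a few grey levels;
2. Gaussian smoothing (default σ = 1 px);
3. thresholding: automatic moments-preserving (Tsai) thresholding, or a
   manual threshold.  The moments method computes the below-threshold
   pixel fraction `p0` that preserves the image's first three grey-level
   moments (closed-form two-level solution) and returns the smallest grey
   level whose cumulative histogram reaches `p0`, on native-bit-depth
   histograms.  The automatic criterion assumes a non-negligible
   foreground fraction, as dense mapping data has; on sparse validation
   fields (< 1 % foreground) it lands in the bright tail, which is why the
   ground-truth recovery studies use the manual mode — mirroring actual
   practice, where manual thresholding is the fallback;
4. strict `>` binarisation (threshold-equal pixels are background),
   8-connected component labelling, and min/max area filters (mapping
   defaults 0.04–2.0 µm²) that remove few-pixel specks and
   lipofuscin-scale aggregates.  Border-touching puncta are kept by
   default, since hemisection maps tile whole sections.

## Colocalisation and classification

Colocalisation is object-based: two puncta colocalise if their binary
masks share at least one pixel.  In `triple` mode a PSD overlapping ≥ 1
presynaptic punctum is a synapse; among synapses, PAP overlap decides
tripartite vs non-tripartite (an exact partition).  In `psd_pap` mode
every PSD is a synapse and PAP overlap alone decides the class — the
two-channel variant used when no presynaptic channel is available.  An
`either_partner` flag optionally lets PAP–presynaptic overlap confer
tripartite status; the default requires PSD–PAP overlap.

## Regional mapping

Puncta are assigned to laminae by the atlas label of their centroid pixel
(centroid membership avoids double counting across boundaries).  Regional
summaries report counts, densities per 100 µm², and mean areas, per
synapse class, per subject.  Cohort comparisons use subject-level
regional means: the heat-map statistic is
`(case mean − control mean) / control mean × 100` per region, and the
contact-vs-loss analysis correlates the control percentage of synapses
classified tripartite with the signed percent change in tripartite
density across regions (Pearson).  With signed percent change, a loss
that shrinks as astrocytic coverage grows produces a positive r.

A caveat at small problem sizes: the contact percentage (x) and the
percent change (y) share the control sample, so counting noise induces a
spurious negative correlation component (regression to the mean), and the
realistic contact range (17–28 %) spans only ~8 percentage points of
planted signal.  The bundled correlation study therefore uses contact
fractions spanning 10–50 % and 8-vs-8 cohorts of 512 px fields, which
puts the planted relationship well above the noise floor; real hemisection
maps, with tens of thousands of synapses per subject, do not face this
constraint.

## Nanostructure

In paired, co-registered frames, confocal-resolved objects are whole PSDs
and STED-resolved objects are NCs.  Each NC is assigned to the PSD whose
mask contains its centroid; failing that, to the overlapping PSD with the
largest shared-pixel count (ties: nearer PSD centroid, then lower id);
otherwise it is an orphan.  NC size is the equivalent circular diameter
2·√(area/π).  Synapse subtypes bin PSDs by NC count into {1, 2, 3+};
frequencies are computed over PSDs with ≥ 1 NC, and PSDs with no assigned
NC are reported separately rather than treated as a subtype.

## Statistics

The statistical layer operates on tidy subject × region tables (the
analysis unit is the subject, not the punctum): two-way ANOVA
(genotype × region, type-II sums of squares, statsmodels backend; an
effect with zero sum of squares reports F = 0, p = 1), Šidák or
Tukey-Kramer post-hoc comparisons (Šidák adjusts pooled-variance pairwise
t-tests by 1 − (1 − p)^m; Tukey uses the studentized range on the one-way
mean-square error), Pearson's chi-squared on subtype count tables
(Σ(O−E)²/E, df = (r−1)(c−1)), pooled-variance two-sample t (Welch
optional), Pearson correlation, and Shapiro-Wilk.  Adjusted p-values are
clamped to be no smaller than raw ones.  Calibration tests confirm
type-I error within [0.03, 0.07] at α = 0.05 over 2 000 null simulations
for the t-test, both ANOVA main effects, and chi-squared.

A naming note: the post-hoc option that appears as "Sulak's" in some lab
protocols is interpreted as the Šidák correction (no test of that name
exists); reports printed by the package state this interpretation.

## Problem sizes and what the tests show

Validation runs are scaled to desk size as the package's own choice of
problem size: mapping cohorts use 320 px (≈ 1 000 µm²) fields with ~290
synapses per subject and 5-vs-5 subjects (100 replicate cohorts for the
power study); detection recovery uses 300–500 entities per field;
nanostructure studies use ≈ 2 000 PSDs over 16 paired 1024 px frames at
20 nm/px.  At these sizes the pipeline detects the planted 40 %
tripartite-only loss (genotype effect p < 0.05) in ≥ 90 % of replicate
cohorts while leaving non-tripartite density unflagged, recovers planted
NC-count distributions within multinomial error, and reproduces planted
densities within Poisson error.

What passing does not show: the generator renders isotropic Gaussian
spots on a flat background — real tissue has structured background,
depth-dependent aberrations, antibody labelling stochasticity, chromatic
offsets between channels, and PSDs whose shapes are not NC polygons.
Results here validate the analysis logic (thresholding, segmentation,
overlap classification, aggregation, statistics), not robustness to those
real-data complications.  Mis-registration between paired frames is
explicitly out of scope (frames are assumed co-registered), as are 3-D
optics, photobleaching, and deconvolution.

## Numerical and degenerate-input conventions

Pixels equal to the threshold are background.  Centroids are snapped to
the nearest pixel for region lookup; boundary pixels own their label.
Constant images have no moments threshold (error).  Empty regions report
count 0, density 0 and missing mean area.  Percent differences against a
zero control mean are undefined (NaN), and correlations over constant
inputs raise errors rather than returning NaN silently.  All stochastic
operations derive their streams from explicit seeds via
`numpy.random.SeedSequence`; per-subject seeds are spawned from the run
seed and stay below 2³¹.
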