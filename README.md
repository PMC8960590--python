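# synaptomap

Quantitative mapping of excitatory synapses and tripartite synapses in
fluorescence micrographs of spinal cord, for labs doing synaptome-scale
imaging: punctum detection with the standard FIJI-style chain
(rolling-ball background subtraction, Gaussian smoothing,
moments-preserving or manual thresholding, size-filtered particle
analysis), object-overlap colocalisation that classifies each PSD95
punctum as a tripartite or non-tripartite synapse, laminae-resolved
density and size statistics with percent-of-control heat maps, paired
confocal/g-STED nanocluster-per-PSD quantification, and the accompanying
statistical layer (two-way genotype × region ANOVA, Šidák/Tukey post-hoc,
chi-squared on synapse subtypes, t-tests, Pearson correlation,
Shapiro-Wilk).

Because raw tissue images of this kind are rarely shareable, the package
includes a first-class synthetic-micrograph generator with exact ground
truth: PSDs built from 1–4 PSD95 nanoclusters (~140 nm), optional
presynaptic (VGLUT2-like) and perisynaptic-astrocyte (PAP) partners,
region-dependent densities on a laminae atlas, confocal (320 nm FWHM) vs
STED (70 nm FWHM) point-spread functions, Poisson + read noise, and
lipofuscin-like saturating aggregates.  Every stage of the pipeline is
validated end-to-end against what the generator planted.

## Core definitions

* **Punctum**: 8-connected component of pixels strictly above threshold,
  with area inside `[min_area, max_area]` (defaults 0.04–2.0 µm²).
* **Moments threshold** (Tsai): the grey level t such that binarising at
  t preserves the image's first three grey-level moments; computed from
  the native-bit-depth histogram as the smallest level whose cumulative
  fraction reaches the moment-preserving quantile p₀.
* **Synapse / tripartite synapse**: a PSD punctum overlapping (≥ 1 px of
  binary mask) a presynaptic punctum is a synapse; a synapse whose PSD
  also overlaps a PAP punctum is tripartite.  Tripartite +
  non-tripartite = synapses, exactly.
* **Density**: puncta (or synapses of a class) per 100 µm² of lamina
  area; regions assigned by centroid pixel.
* **Heat-map statistic**: per region,
  (case mean − control mean) / control mean × 100, over subject-level
  regional means.
* **Nanocluster (NC) / subtype**: STED-resolved objects are NCs, assigned
  to the confocal-resolved PSD containing their centroid (else maximal
  mask overlap); synapse subtypes bin PSDs by NC count into {1, 2, 3+}.

## Worked example

Simulate a 5-vs-5 cohort in which the case genotype loses 40 % of its
tripartite synapses (and nothing else), run the full pipeline — render
three channels per subject, detect puncta, classify synapses, aggregate
per lamina — and test the group difference:

```python
import synaptomap as sm
from synaptomap.io import DETECTION_PROFILES
from synaptomap.pipeline import run_mapping_cohort

atlas = sm.build_region_atlas((320, 320), pixel_size_nm=100.0, layout="bands")
params = sm.SceneParams(field_size_px=(320, 320), pixel_size_nm=100.0,
                        aggregate_count=0)
det = {ch: DETECTION_PROFILES["mapping"] for ch in ("psd95", "vglut2", "pap")}

res = run_mapping_cohort(params, atlas, sm.OpticsModel.confocal(), det,
                         n_control=5, n_case=5, tripartite_loss=0.4, seed=42)

for m in ("tripartite_density", "non_tripartite_density"):
    sr = res["anova"][m]["genotype"]
    print(f"{m}: F({sr.df[0]:.0f}, {sr.df[1]:.0f}) = {sr.statistic:.2f}, "
          f"p = {sr.p_value:.4g}")
print(res["heatmaps"]["tripartite_density"][["region", "percent_difference"]]
      .round(1).to_string(index=False))
```

Output:

```
tripartite_density: F(1, 64) = 34.10, p = 1.902e-07
non_tripartite_density: F(1, 64) = 0.09, p = 0.7659
region  percent_difference
  I-II               -39.1
III-IV               -53.8
     V               -55.3
    VI               -37.9
   VII               -89.3
  VIII               -41.2
    IX               -27.8
     X               -50.0
```

The genotype effect on tripartite density is strongly significant while
non-tripartite density shows none — the planted selective loss — and the
heat-map column is negative across laminae, scattered around the planted
−40 % by per-region counting noise.

The same stages are available as a CLI for file-based work
(`synaptomap simulate | detect | coloc | map | nano | stats | run`), with
images as single-plane TIFF (pixel size in metadata), tables as CSV with
provenance headers, and configuration as YAML.

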