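# gastruloid-quant

Quantification pipeline for micropatterned 2D-gastruloid fluorescence
imaging, with a synthetic-scene generator that makes every stage testable
without experimental data.

## The problem

Geometrically confined hESC colonies ("2D gastruloids", 500 µm discs)
self-organize under BMP4 into concentric germ-layer domains: a central
SOX2⁺ ectodermal disc, a BRA⁺ mesodermal ring, and a CDX2⁺
extraembryonic-like edge. Comparing how this pattern shifts between
genotypes requires extracting, from large tiled fluorescence images, a
set of per-colony numbers: nucleus counts and per-cell marker levels,
the width of edge-restricted signaling rings, the area of the central
domain, the fraction of responding nuclei on transwell monolayers, the
spatial reach of secreted inhibitors, receptor placement along the
apicobasal axis, and live-reporter dynamics. This package implements
that measurement chain as a tested library:

- **scenes** — synthetic colonies, fields, sheets, z-stacks and
  time-lapses with exported ground truth (the validation substrate);
- **colony** — tile stitching, background correction, colony detection
  by DAPI thresholding + alpha-shape footprints, exclusion of merged or
  clipped colonies, colony extraction;
- **nuclei** — nucleus seeds from a size-matched Laplacian-of-Gaussian
  filter, seeded watershed segmentation, per-cell median intensities;
- **quant** — DAPI normalization, two-Gaussian/Otsu positivity calling,
  radial profiles, half-max ring widths, centre-vs-edge contrasts,
  positive fractions, secretor-proximity inhibition ranges;
- **domains** — three-class multi-Otsu germ-layer segmentation with
  alpha-shape solidification, domain areas, cohort percent changes;
- **polarity** — ZO-1 apical-surface interpolation and signed
  distance-to-apical distributions (positive = basal);
- **dynamics** — reporter-domain radius traces and single-cell
  nuclear-to-cytoplasmic (N:C) ratio traces with tracking;
- **assays** — TEER per unit area, ΔΔCt fold changes, delegated
  nonparametric group comparisons; **pipeline** — end-to-end
  orchestration from a config.

Key per-cell statistic: the binary marker call. Per nucleus, the median
marker intensity is normalized to the median nuclear DAPI; a
two-Gaussian mixture is fitted to the per-colony distribution of
normalized values and the cut-off between the two populations (the
crossing of the weighted component densities, Otsu's threshold as the
degenerate fallback) classifies each nucleus, strictly-above counting as
positive. Ring widths and inhibition ranges are half-maximum crossings
of binned radial (or distance-to-secretor) profiles, linearly
interpolated between bins.

## Worked example

```python
from gastruloid_quant import scenarios as sc
from gastruloid_quant.scenes import generate_colony_image
from gastruloid_quant.nuclei import segment_colony
from gastruloid_quant.quant import (normalize_to_dapi, fit_binary_threshold,
                                    classify_positive, radial_profile,
                                    ring_width)

spec = sc.edge_ring_spec(seed=1, activation_radius=170.0)  # 250 µm colony
colony, truth = generate_colony_image(spec)
cells, labels = segment_colony(colony)
cells = normalize_to_dapi(cells, "pSMAD1")
fit = fit_binary_threshold(cells["norm_pSMAD1"])
cells = classify_positive(cells, "pSMAD1", fit)
prof = radial_profile(cells, analysis_radius=250.0, bin_width=10.0,
                      value_column="norm_pSMAD1")
print(len(cells), round(ring_width(prof, 250.0)[0], 1))
```

prints `693 80.0` — 693 of this colony's 700 nuclei segmented (within
the ≤3% counting tolerance at this packing) and an 80.0 µm signaling
ring recovered for a scene whose response channel activates at radial
positions ≥ 170 µm (true width 80 µm).

The numbered scripts under `analysis/` run each analysis on its
synthetic scenes and write tables under `results/`: scene gallery,
detection/segmentation accuracy, ring widths, central-domain cohort
changes, transwell fractions and secretor ranges, receptor polarity,
live dynamics, and the derived assays. Each prints what it found, e.g.
`04_domain_areas.py` reports `standard_55pct: -55.9% (radius-ratio
prediction -55.0%)`.

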