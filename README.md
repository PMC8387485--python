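# ensquant

Automated, quantitative analysis of enteric nervous system (ENS) network
structure from confocal microscopy — for gastroenterology and
neurogastroenterology labs that image wholemount gut preparations and want
reproducible, scriptable structural read-outs instead of visual scoring.

The ENS forms a planar meshwork of ganglia connected by fibre bundles.
Disease models (and human enteric neuropathies) can remodel this network
in ways that are invisible to the eye but measurable: coverage, branching,
junction density, interganglionic spacing.  `ensquant` turns calibrated
z-stacks of a pan-neuronal fibre marker (TuJ1) or a soma marker (HuC/D)
into per-field metrics and cohort-level statistics:

* **Network density** — foreground percentage of the segmented projection,
  with the background ("negative space", a proxy for interganglionic
  area) decomposed into connected components and binned by size
  (0–50 / 51–200 / 201–400 / 401–600 / 601–800 / 801–1000 / >1000 px²).
* **Skeleton topology** — the mask is thinned to a 1-px centreline and
  reduced to a graph; junctions are counted by degree (triple ×3,
  quadruple ×4, higher), branches by count and length (weighted step
  metric: 1, √2, √3 per axis/diagonal/3D-diagonal move).  A 3D
  Hessian-ridge mode keeps branches that cross in different z-planes
  separate.
* **Orientation and coherency** — structure-tensor analysis; per-pixel
  orientation θ ∈ (−90°, +90°] and coherency (λ₁−λ₂)/(λ₁+λ₂), summarised
  at field level by the energy-weighted mean tensor.  Both the axial
  circular mean and the artefact-prone naive arithmetic mean are
  reported (vertical fibres register at ±90° and cancel in the naive
  mean).
* **Segmentation** — a WEKA-style trainable random-forest pixel classifier
  over a multiscale filter bank, or a plain Otsu auto-threshold.
* **Soma counts** — threshold → components → size/circularity particle
  filter (default 10 µm²–∞, circularity 0.00–1.00), averaged per animal.
* **Statistics** — Welch's t-test on subject means (t = (x̄₁−x̄₂)/√(s₁²/n₁+s₂²/n₂),
  Welch–Satterthwaite df) and ΔΔCT relative expression
  (fold = 2^(−ΔΔCT), significance tested on ΔCT values).

A synthetic-scene generator (`ensquant.simulate`) produces confocal-like
stacks — ganglion lattices, fibre bundles, sprouting secondary fibres,
soma fields, PSF blur and Poisson/Gaussian noise — with exact ground-truth
masks and graph censuses, so the entire chain is validated end to end
without any proprietary imaging data.

## Worked example

```python
import numpy as np
from ensquant import (AnalysisConfig, NetworkSpec, RenderParams,
                      analyze_field, generate_network_graph, render_stack)

spec = NetworkSpec.control_small()          # 3x3 ganglion lattice, 128x128 field
render = RenderParams(shape=(5, 128, 128))  # 5 optical sections

net = generate_network_graph(spec, seed=0, shape=render.shape)
stack, truth = render_stack(net, render, seed=0)
row = analyze_field(stack, AnalysisConfig(compute_orientation=False))

print(f"measured density   : {row['density_percent']:.1f} %"
      f"   (truth {100 * truth.true_density_fraction:.1f} %)")
print(f"junctions (3x/4x)  : {row['n_triple']} / {row['n_quadruple']}"
      f"   (truth {truth.n_triple} / {truth.n_quadruple})")
print(f"branches, total len: {row['n_branches']}, {row['total_branch_length_px']:.1f} px"
      f"   (truth {truth.n_branches}, {truth.total_branch_length_px:.1f} px)")
```

prints

```
measured density   : 25.9 %   (truth 25.2 %)
junctions (3x/4x)  : 14 / 0   (truth 14 / 0)
branches, total len: 26, 705.2 px   (truth 26, 737.5 px)
```

— the pipeline recovers the generating network's junction and branch
census exactly at this signal-to-noise ratio, and density to within the
smear of the point-spread function.

For cohorts, `generate_cohort` builds a two-group dataset with
subject-level random effects (the animal, not the field, is the
statistical unit) and `run_cohort_pipeline` returns the per-field table,
per-subject means, and a Welch comparison per metric with significance
stars.

## Command line

```bash
ensquant simulate --config cohort.yaml --out data/ --seed 1
ensquant train    --images data/ --annotations labels.csv --out clf.joblib
ensquant analyze  --manifest data/manifest.csv --classifier clf.joblib --out results/
ensquant compare  --per-field results/per_field.csv --out comparison.csv
ensquant qpcr     --table ct_values.csv --control-group wt --out qpcr/
```

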