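# claumap

Quantitative demarcation of the mouse claustrum from combined marker
labelling and retrograde tracing, exercised end-to-end on synthetic
multi-channel confocal slices with known ground truth.

The claustrum is a thin sheet of forebrain neurons with no clear anatomical
border in rodents. A reliable way to locate it is combinatorial: claustrum
projection neurons (labelled by a retrograde tracer injected in cortex)
densely co-express the claustrum-enriched markers Nurr1/Nr4a2 and Nr2f2,
while the cortical marker Tle4 is conspicuously absent from them and instead
labels the structures that encase the claustrum on all sides. `claumap`
implements the image-analysis pipeline behind that strategy:

- **synthgen** — a seeded generator of multi-channel z-stacks (11 planes at
  2 µm over a 20 µm volume, 1024×1024 frames) with an exact cell-level
  ground truth: a dense elliptical zone of retro⁺ cells co-expressing the
  enriched markers at configurable pairwise fractions (defaults
  f(retro, Nurr1) = 0.87, f(retro, Tle4) = 0.01), surrounded by a Tle4⁺
  ring, plus Poisson + Gaussian noise.
- **stack_io** — calibrated TIFF stacks and maximum-intensity projections.
- **detect** — smooth → threshold (Otsu) → label → watershed peak splitting
  → area filter → intensity-weighted centroids in µm.
- **coloc** — greedy nearest-centroid matching across channels
  (colocalized ⇔ centroid distance ≤ 5 µm), Venn counts
  (n_A, n_B, n_{A∩B}) per slice and anteroposterior subdivision
  (anterior +1.80…+0.70 mm, middle +0.70…−0.20 mm, posterior
  −0.20…−1.00 mm from bregma), and the c-Fos activation contrast between
  naive and open-field cohorts.
- **zones** — the enriched zone as the outer contour of the highest KDE
  superlevel set containing ≥ 90 % of a channel's cells; the Tle4-devoid
  zone as the connected low-density region around an anchor; vertex-mean
  polygon centroids; cross-animal overlays aligned on the retro centroid
  with gridded occupancy maps.
- **profiles** — 0.1 mm strip-mean intensity profiles along two orthogonal
  axes (parallel and perpendicular to the external capsule), z-scored and
  realigned to the retrograde peak for cross-section averaging.
- **stats** — pooled-variance unpaired t-tests (df = n₁+n₂−2, e.g. t(13)
  for 5 vs 10 mice) and one-way ANOVA with protected Bonferroni post hoc
  comparisons, with the mouse as statistical unit.
- **pipeline / CLI** — one YAML config drives generate → detect → coloc →
  zones → profiles → stats, with deterministic per-mouse seeding and a
  rendered report (`claumap run`, `claumap report`, …).

## Worked example

```python
import numpy as np
from claumap import synthgen as sg
from claumap.stack_io import max_project
from claumap.detect import detect_cells
from claumap.coloc import coloc_table
from claumap.zones import delineate_enriched_zone, delineate_devoid_zone

cfg = sg.GeneratorConfig(seed=1)                      # study-condition defaults
rng = np.random.default_rng(cfg.seed)
truth = sg.sample_cells(cfg.zone_geometry, cfg.densities, cfg.coloc_fractions,
                        rng, frame_um=cfg.frame_um, channels=cfg.channels)
vol = sg.render_slice(truth, cfg, channels=("retro", "nurr1", "tle4"), rng=rng)

sets = {ch: detect_cells(max_project(vol, ch)) for ch in ("retro", "nurr1", "tle4")}
slice_tab, _ = coloc_table([sets], [("retro", "nurr1"), ("retro", "tle4")])
print(slice_tab[["pair", "n_a", "n_b", "n_ab", "frac_ab_of_a"]])

poly = delineate_enriched_zone(sets["retro"])
dev = delineate_devoid_zone(sets["tle4"], tuple(poly.centroid))
```

prints

```
       pair  n_a  n_b  n_ab  frac_ab_of_a
retro|nurr1   81  232    72      0.888889
 retro|tle4   81  421     1      0.012346
```

i.e. 81 retrograde-labelled cells were detected on this slice, 88.9 % of
them colocalize with a Nurr1⁺ cell (ground truth 0.87) and 1.2 % with a
Tle4⁺ cell (ground truth 0.01). The enriched-zone polygon (34 vertices,
vertex centroid at (510.4, 510.4) µm) contains 90.1 % of the detected retro
cells, and the Tle4-devoid polygon anchored at that centroid contains 0 %
of the Tle4 cells — the claustrum interior.

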