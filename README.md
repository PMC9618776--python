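# embryoquant

Quantification of confinement-driven cell invasion in zebrafish embryo
fluorescence microscopy, as a tested, reusable Python pipeline.

When oncogene-expressing epithelial cells (e.g. mosaic EGFP-KRas^V12 clones in
the embryonic periderm) extrude basally and invade the embryo body, the dense
surrounding tissue confines them: their nuclei deform, some acquire DNA damage,
and a fraction trans-differentiates into mesenchymal phenotypes. Assessing this
requires a family of small, precise image measurements plus nonparametric
statistics. `embryoquant` implements each of them over standard multi-channel
TIFF z-stacks, and ships a synthetic-embryo generator with exact ground truth
so the entire pipeline is testable without microscope data:

- **Nuclear morphometry** — circularity `4πa/p²` of a nucleus mask of area
  `a` and perimeter `p` (1 for circles, <1 otherwise), with a subpixel
  perimeter estimator (naive boundary counting would overestimate a digital
  circle's perimeter by ~27% and wreck the shape factor), plus per-frame
  time series for time-lapse tracking.
- **Cell density** — `density = number of nuclei / area` on a maximum
  intensity projection of a thin substack a fixed depth window below the
  tissue surface (e.g. 19–21 µm for neural tube, 15–20 µm for somites at
  0.5 µm z-steps), with manual centroids or an automatic LoG blob detector.
- **Scoring** — cells are *invaded* when their centroid lies strictly below
  the epithelial boundary surface; marker positivity (N-cadherin,
  phospho-H2A.X) is called as mean cell intensity > background mean + k·SD
  (default k=2); percentages are per embryo: positive invaded cells / all
  non-excluded invaded cells.
- **Internal masses** — connected components of reporter-MIP pixels above
  mean + 4·SD, dropping objects smaller than 0.0025 mm² (single cells);
  optional confirmation that each mass lies below the epithelium; embryo
  lateral area from a boundary-marker MIP or a manual outline polygon.
- **Statistics** — Mann–Whitney U (exact null distribution for small
  tie-free samples, tie-corrected normal approximation otherwise),
  Kruskal–Wallis H with chi-square reference, Holm–Šidák step-down
  adjustment for pairwise families, and `*`/`**`/`***` star annotation at
  0.05 / 0.01 / 0.001.

## Worked example

Generate a surface-like cohort (near-round nuclei, target circularity
0.94 ± 0.05, n = 25) and an invaded-like cohort (deformed, 0.83 ± 0.05,
n = 24), measure every rendered mask, and compare the groups:

```python
import pandas as pd
from embryoquant.synthetic import generate_nucleus_cohort
from embryoquant.morphometry import compute_circularity, summarize_groups
from embryoquant.stats import mann_whitney, significance_stars

rows = []
for loc, mean, n, seed in (("surface", 0.94, 25, 2), ("invaded", 0.83, 24, 3)):
    masks, _ = generate_nucleus_cohort(
        n, circularity_mean=mean, circularity_sd=0.05,
        mean_radius_um=5.5, pixel_size_um=0.5, seed=seed, radius_sd_um=0.5)
    for m in masks:
        a, p, c = compute_circularity(m, 0.5)
        rows.append({"location": loc, "area_um2": a, "circularity": c})
df = pd.DataFrame(rows)
print(summarize_groups(df, "location"))
u, p = mann_whitney(df[df.location == "surface"].circularity,
                    df[df.location == "invaded"].circularity)
print(f"U = {u}, p = {p:.2e}, {significance_stars(p)}")
```

prints

```
  location   n      mean        sd       sem
0  invaded  24  0.830226  0.059388  0.012123
1  surface  25  0.939491  0.040393  0.008079
U = 47.0, p = 4.42e-07, ***
```

i.e. the measurement pipeline recovers the generative cohort means (0.83 and
0.94) from the rasterized masks, and the nonparametric comparison separates
the groups decisively — deformed nuclei are unambiguously distinguishable
from round ones at these cohort sizes.

The same flow is available from the shell:

```sh
embryoquant simulate --out sim/ --seed 1          # stacks + ground truth
embryoquant run-all  --out results/ --seed 1      # simulate, measure, compare
embryoquant masses --stack sim/embryo-00.tif --out masses.csv
```

`run-all` writes `circularity.csv`, `density.csv`, `cells.csv`,
`percentages.csv`, `masses.csv`, `mass_counts.csv`, `comparisons.csv` and
`group_summaries.csv`, each with a commented metadata header recording the
seed and parameters; identical config + seed reproduces the tables byte for
byte.

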