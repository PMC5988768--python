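# psoct — birefringence quantification of indented cartilage with PS-OCT

Polarisation-sensitive optical coherence tomography (PS-OCT) detects two
orthogonal backscattered amplitude channels, A_V and A_H, per pixel.  From a
B-scan pair it reconstructs the reflectivity

    R(z) ∝ A_V(z)² + A_H(z)²

and the phase retardation

    δ(z) = arctan(A_V / A_H) ∈ [0, π/2],

which grows with depth at a rate set by the tissue birefringence Δn and folds
at π/2 (the system's quarter-cycle phase wrap).  In articular cartilage the
birefringence reflects collagen-fibre organisation: bovine cartilage imaged
normal to its surface looks nearly isotropic, but when a flat indenter with a
1 mm channel gap is creep-loaded onto it (~56 % axial strain), the fibres
reorient and strong birefringent banding appears — much more strongly in
healthy tissue (grade G0) than in mildly/moderately degenerate tissue
(G1/G2).  The quantity of interest is the **birefringence coefficient
(BRC)**: the cumulative absolute change of the smoothed retardation profile
divided by the physical tissue depth it spans, in rad/mm.

This package is for researchers who want to study, stress-test or extend
that analysis without access to the original specimens.  It provides:

- `psoct.tissue` — a synthetic tissue-model generator whose grade presets
  are calibrated to the published group statistics (per-grade BRC mean ± SD
  in three imaging configurations: XZ-indented, XZ-non-indented, XY side
  view), including the indentation bulge and asymmetric banding;
- `psoct.optics` — a Jones-calculus forward model producing two-channel
  B-scan pairs (1310 nm, 10 µm axial resolution in air, 20 µm lateral,
  10 mm width) with unit-mean multiplicative speckle, plus a virtual
  Berek-compensator experiment for validating the phase read-out;
- `psoct.reconstruction` — the reflectivity/retardation images above;
- `psoct.pipeline` — the BRC pipeline: 10-A-scan lateral averaging, surface
  detection, maximum-depth thresholding, n = 1.36 depth calibration, running
  average smoothing, cumulative |Δδ|/depth, aggregation over 5 adjacent
  B-scans;
- `psoct.stats` — per-configuration one-way ANOVA across G0/G1/G2, Tukey
  HSD, normality/variance-homogeneity reporting and a summary-table replica;
- `psoct.study` / `psoct.cli` — end-to-end study replication and a CLI
  (`psoct simulate | reconstruct | brc | stats | replicate-study`).

## Worked example

```python
from psoct.io import RunConfig
from psoct.study import run_replicate_study

outcome = run_replicate_study(RunConfig(output_dir="study_out", seed=1))
print(outcome.report.to_text())
```

prints (seed 1):

```
Summary of results for phase analysis (retardation gradient, rad/mm)
              XZ - Indented XZ - Non-indented         XY
G0                3.1 ± 0.4         1.3 ± 0.6  5.2 ± 0.7
G1                1.8 ± 0.3         1.2 ± 0.3  4.9 ± 1.0
G2                1.6 ± 0.5         1.4 ± 0.5  5.6 ± 2.1
Anova P-value        <0.001             0.695      0.581
G0 vs. G1               ***                ns         ns
G0 vs. G2               ***                ns         ns
G1 vs. G2                ns                ns         ns
```

Each cell is the recovered group mean ± between-sample SD of the BRC over
the simulated specimens (10 G0, 8 G1, 8 G2).  The indented configuration
separates healthy from degenerate cartilage (ANOVA p < 0.001; G0 differs
from both G1 and G2, which do not differ from each other), while the
non-indented and side-view configurations show no grade effect — the
published structure of the study.  `study_out/` receives the per-sample
records (`samples.csv`), the summary table, and the echoed run config; pass
`write_volumes=True` to persist every simulated B-scan as a two-page float
TIFF with a JSON sidecar.

The same run from a shell:

```sh
psoct replicate-study --out-dir study_out --seed 1
```

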