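# nucleodrop

Shape physics and morphometrics of the endothelial nucleus under flow.

Endothelial monolayers smoothen when exposed to shear stress, and their
nuclei appear to flatten. The *nuclear drop model* explains such shape
changes without invoking nuclear elasticity: the nucleus behaves as a
pressurized drop bounded by a nearly inextensible lamina, so every shape it
adopts conserves its volume V and its lamina surface area A. A rounded
nucleus stores the excess area A − A_sphere(V) as wrinkles; a spreading cell
unfolds them, and once the lamina is taut the shape is fixed by geometry
alone. This package provides, for anyone analyzing such data or testing the
model:

- a **constrained surface-energy solver**: cell cortex and nuclear surface as
  triangle meshes, minimizing

      E_tot = E_cell + E_nuc + γ(A_nuc/A_nuc,0 − 1)² + β_nuc(V_nuc/V_nuc,0 − 1)²
              + β_cell(V_cell/V_cell,0 − 1)²

  with the cortex area as the driving term, centroidal-Voronoi mesh
  regularization, a stiffness schedule raised until all residuals < 10⁻³,
  reflecting-boundary contact (substrate, cortex-nucleus, rigid micropost),
  and quasi-static micropost indentation;
- an **image-quantification pipeline** for confocal z-stacks: bulk nuclear
  segmentation, sub-pixel lamina tracing, elliptical Fourier analysis (15
  harmonics) and the EFC smoothness ratio, nuclear height / surface area /
  volume, monolayer height maps and roughness, YAP nuclear-to-cytoplasmic
  ratios, focal-adhesion density with size and circularity gates, pMLC
  intensity per area, and detachment traces;
- **synthetic-data generators** with exact ground truth (wrinkled nuclei at
  prescribed volume and excess area, confocal-like renders with PSF and
  Poisson-Gaussian noise, monolayers with tall-cell fractions, YAP and
  focal-adhesion scenes, detachment time series);
- a seeded two-sample **permutation test** for roughness contrasts.

## Worked example

The monolayer-smoothing readout, end to end on synthetic data
(`python analysis/05_roughness_stats.py`):

```
roughness SD: tall-cell 1.064 +/- 0.202 um vs flat 0.000 +/- 0.000 um
permutation test: diff 1.064 um, p = 0.0002
Mann-Whitney U (reference): p = 0.0008599
```

Eight monolayers with 20% tall cells and eight flat ones are rendered to
3D stacks, each stack is binarized and reduced to an apical-height map, and
the per-image roughness SD (µm) is compared across conditions: tall cells
raise the monolayer roughness to ~1 µm, and the seeded permutation test on
8+8 images rejects equality (p = 2×10⁻⁴, the add-one minimum at 9,999
permutations being 10⁻⁴).

Measuring nuclei from rendered lamin stacks
(`python analysis/04_measure_morphometrics.py`):

```
taut: measured 14.13 EFC mean
wrinkled: measured 2.81 EFC mean
EFC ordering (smooth > wrinkled): 14.13 > 2.81 -> True
YAP N/C recovery at 10% noise: max error 1.0%
FA detection: 20/20 spots within the gates
```

A taut nucleus (0% excess area) and a wrinkled one (37% excess) of equal
volume are rendered with realistic noise; the 3-plane mean EFC ratio —
first-harmonic semiaxes over the sum of harmonics 2–15, higher = smoother —
correctly ranks the smooth nucleus far above the wrinkled one, YAP
nuclear/cytoplasmic ratios are recovered within 1% at 10% noise, and all 20
synthetic focal adhesions pass the 0.5–15 µm² / circularity 0.1–1.0 gates.

The drop-model solves live in `analysis/02_solve_drop_shapes.py` (free-drop
isoperimetric control and the monolayer-cell prediction at cell volume
2800 µm³, nuclear volume 800 µm³, lamina area 37% in excess of the
equal-volume sphere) and
`analysis/03_indent_micropost.py` (a 1-µm-diameter post driven 2 µm into the
nuclear rim and withdrawn, with shape recovery quantified by Hausdorff
distance). A YAML-configured pipeline with a digest manifest is available as
a CLI:

```bash
nucleodrop run --config examples/demo.yaml --out results/demo --seed 11
nucleodrop synth nucleus --out results/nucleus --seed 1
nucleodrop stats --csv results/roughness/roughness_per_image.csv
```

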