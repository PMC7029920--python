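# morphonorm

3D geometric morphometrics of shape plasticity, built for a classic
question in invasion biology posed by *Drosophila suzukii*: does a
trait that matters for the invasion — the serrated ovipositor that lets
females pierce ripening fruit — respond plastically to developmental
temperature, and do invasive populations respond more than native ones?

The package is for morphometricians and evolutionary biologists who work
with dense 3D semilandmark phenotypes. It implements the full analysis
chain as a tested Python library:

- **Template-based phenotyping** — a reference configuration (5 fixed
  landmarks, 130 curve semilandmarks on three curves, 394 surface
  semilandmarks; 529 points) is transferred to each specimen mesh by a 3D
  thin-plate spline (kernel U(r) = −r) and exact nearest-point projection
  onto the triangle soup.
- **Sliding semilandmarks** — curve points slide along their tangent,
  surface points in their tangent plane, minimizing total bending energy
  Σ<sub>c</sub> xᵀ<sub>c</sub> B x<sub>c</sub> against the Procrustes
  consensus (B the bending-energy matrix), with object symmetry respected
  and the energy trace asserted non-increasing.
- **Superimposition** — generalized Procrustes analysis in the partial
  form (unit centroid size, CS = √Σᵢ‖xᵢ−x̄‖²), object-symmetry
  decomposition into symmetric/asymmetric components by
  reflection-relabelling, tangent-space projection.
- **Statistics** — between-group PCA; the 10 000-permutation test on
  pairwise Procrustes distances among group means; Procrustes ANOVA with
  residual-randomization permutation (RRPP) and effect sizes
  Z = (log F − mean log F*)/sd(log F*); phenotypic trajectory analysis of
  reaction norms (path length, direction angle in [0°, 180°], trajectory
  shape distance); allometric regression of shape on log CS with a
  slope-homogeneity test; the modified signed-likelihood-ratio test for
  equality of coefficients of variation; Mahalanobis distances between
  temperature groups on a common number of principal components; and a
  permutation comparison of thermal plasticity between two structures
  (ovipositor vs wing).
- **Synthesis** — a generator producing the whole two-structure study
  (3 populations × 3 temperatures, group sizes 20/11/13, 19/20/23,
  14/6/13) with known ground truth, so every stage is testable.

## Worked example

Run the full synthetic study from one config (library call shown; the
CLI equivalent is `morphonorm run config.yaml`):

```python
from morphonorm.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=1, outdir="run1", figures=False)
summary = run_pipeline(cfg)["summary"]
print(summary["shape_anova"]["terms"]["temperature"])
print(summary["trajectory"]["path_lengths"])
print(summary["plasticity"]["mahalanobis"])
```

With seed 1 this prints (abridged):

```
temperature: Z = 6.07, p = 0.001          # thermal plasticity of shape
path lengths: Paris 0.097, Sapporo 0.088, Dayton 0.085
Mahalanobis 16–28 °C: ovipositor 8.35, wing 13.17
```

Read: developmental temperature shifts ovipositor shape strongly
(Z ≈ 6), the three populations' reaction norms have nearly equal path
lengths (no plasticity divergence among populations — all pairwise
trajectory tests come back non-significant), and the wing is clearly the
more thermally plastic structure (larger between-temperature Mahalanobis
distance at the same 26 principal components; the permutation comparison
gives p ≈ 0.001). The bundle also contains the 9 × 9 group-mean
distance/p matrices, the centroid-size ANOVA (temperature df = 2,
interaction df = 4, residual df = 130), CV tables, repeatability
MS ratios, bgPC reaction-norm and size figures, and exaggerated
deformation meshes for visualization.

## Layout

```
src/morphonorm/
  io.py              meshes (PLY/OBJ), landmark CSV/TPS dialects, factor tables
  synthesis.py       synthetic valve-pair + wing generator with known truth
  superimposition.py GPA, centroid size, object symmetry, Procrustes distance
  templating.py      TPS, bending energy, template projection, sliding
  shapestats.py      the statistical battery
  pipeline.py        end-to-end orchestration and reporting
  cli.py             morphonorm simulate | gpa | phenotype | analyze | run
docs/methods.md      model, assumptions, parameter choices, limitations
```
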