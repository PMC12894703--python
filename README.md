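# twistcloud

Spatial analysis and curation of oriented particles from cryo-electron
tomography (cryo-ET), built on twist-vector neighborhood descriptors.

Subtomogram averaging and particle picking produce *particle lists*:
positions **p**ᵢ and orientations ωᵢ ∈ SO(3) of macromolecular complexes in
tomograms. Treating each particle as a rigid motion (ωᵢ, **p**ᵢ) ∈ SE(3),
the relative pose of a neighbor seen from a query particle is

    (ω, p) = (ω₁ᵀ ω₂, ω₁ᵀ (p₂ − p₁)),

i.e. the scene is moved so the query sits at the origin in its canonical
orientation. Its *twist vector* (log(ω)∨, **p**) ∈ 𝔰𝔢(3) encodes the
neighbor's relative rotation (axis × angle) and relative position; its
norms are the angular distance d(ω₁, ω₂) = ‖log(ω₁ᵀω₂)∨‖ and the Euclidean
inter-particle distance. Because relative poses are invariant under any
common rigid motion of the scene, every feature derived from twist vectors
is rotationally invariant.

On this basis the package provides, for structural biologists curating and
mining particle lists:

- **Twist descriptors** on spherical supports (single- or cross-list),
  persisted as tables, reducible by geometric supports (sphere, cylinder,
  ellipsoid, cone, torus, binary masks) and record filters.
- **Object affiliation and cleaning** by proximity clustering (connected
  components of the pair graph), e.g. assigning subunits to nuclear-pore
  rings or microtubules while discarding false positives, with F1 = 2TP /
  (2TP + FP + FN) evaluation against ground truth.
- **Symmetry-aware angular scores** σ_V = 1 − δ_V/m_V, where δ_V is the
  spherical Hausdorff distance between rotated vertex sets of the
  symmetry's geometric representative (regular n-gon for Cn, platonic
  solids), removing the rotation-matrix ambiguity of symmetric particles;
  plus a Cn symmetry scan with Mann–Whitney rank-sum comparisons.
- **Lattice analysis**: shell decomposition, first-shell link statistics
  (central angles, Euler characteristic, link type) and pentamer-defect
  labeling on hexagonal lattices via PCA + 2-means.
- **Pattern mining**: nucleosome-stack classification with one-sided
  cylindrical supports, dinucleosome detection with conical supports,
  dominant rotation-axis histograms and k-means on twist features, and
  SHOT-style cone-occupancy footprints for cross-list (e.g. ribosome
  entry/exit) analyses.
- **Synthetic generators** for planar/spherical lattices, Cn rings and
  chromatin-like scenes, with a calibrated positional/orientational noise
  model, so every pipeline is testable at desk scale.

Particle lists are read and written in Relion STAR, TOM/AV3 motive-list
(EM binary and CSV), Dynamo table, and the package's native `twist_csv`
dialect (rotation matrices, no Euler ambiguity).

## Worked example

Generate a chromatin-like scene at the reference composition (6 helical
arrangements of 12 nucleosomes, 350 stacked pairs, 340 trinucleosomes,
3200 mononucleosomes) and classify stacked nucleosomes with a one-sided
cylindrical support along each particle's intrinsic +y axis and an
angular-distance window around the 15° stack twist:

```python
from twistcloud.synthetic import ChromatinSpec, generate_chromatin
from twistcloud.pipelines import stack_classifier, dinucleosome_finder

particles, truth = generate_chromatin(ChromatinSpec(), seed=42)
labels, fractions = stack_classifier(particles)
print(fractions)
```

```
{'helix': 83.33333333333334, 'stack': 100.0, 'tri': 66.66666666666666, 'mono': 0.0}
```

100% of stacked-pair particles are recovered; trinucleosomes report 66.7%
because exactly two of their three nucleosomes form a stacked pair; helices
report 83.3% because each 12-particle helix contains one deliberately
widened pair (10/12) whose twist falls outside the angular window.
Mononucleosomes are essentially never labeled stacked.

Dinucleosome-like (linker-connected) pairs are mined with double-cone
supports along the DNA entry/exit axis, clustering per-pair Euclidean
distance, angular distance and rotation-axis alignment with seeded
15-means:

```python
records, report = dinucleosome_finder(particles, seed=43)
best = report["pct_helix"].idxmax()
print(report.loc[best, ["median_euclidean", "pct_helix", "pct_tri"]])
```

```
median_euclidean     24.960461
pct_helix           100.000000
pct_tri             100.000000
```

A single cluster, centered at the ~24.5 nm linker distance, contains every
helix- and trinucleosome-labeled particle.

The same pipelines are scriptable from the shell:

```sh
twistcloud simulate chromatin --seed 42 --out scene.csv
twistcloud stacks --input scene.csv --out labels.csv
twistcloud score-symmetry --input lattice.csv --radius 20.5 --n-min 2 --n-max 10
```

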