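# somaspat

3D spatial statistics for neuronal soma distributions: is an observed
arrangement of cell bodies clustered, regular, or just unevenly dense?

`somaspat` implements the analysis chain used to characterize the mouse
forebrain cholinergic system — five subcortical structures (CPu, NB, GP,
NA, S) across both hemispheres — from soma centroid coordinates in µm:

* **Region geometry** — convex hulls and alpha complexes from point
  clouds, analytic ellipsoid fixtures, voxel masks, and axonal-bundle
  *exclusion zones* inside which no somata may fall.
* **Ripley's K in 3D**, deliberately uncorrected for edge effects, with
  Monte Carlo envelopes of complete spatial randomness (CSR) simulated in
  the same region at the same n — so the edge bias cancels in testing —
  optionally honoring exclusion zones, plus the paired-t curve comparison:

  K(r) = |V| · Σᵢ Σⱼ≠ᵢ 1[D(i,j) ≤ r] / n²

* **Inhomogeneous K** with Gaussian-kernel intensity estimation (Silverman
  bandwidth, boundary-corrected, leave-one-out at data points) and the
  99-realization Monte Carlo rank test against conditional
  inhomogeneous-Poisson nulls:

  K_inhom(r) = Σᵢ Σⱼ≠ᵢ 1[D(i,j) ≤ r] / (λᵢ λⱼ)

  This separates true clustering from density gradients — the package's
  headline inference: a smooth anterior–posterior gradient makes the
  homogeneous K cry "clustering" while K_inhom correctly does not reject.
* **Density homogeneity** — per-structure density tables, hemispheric
  asymmetry summaries, and the quadrat F-test
  F = v₂(2n₁+1) / (v₁(2n₂+1)), df = (2n₁+1, 2n₂+1) for equality of point
  density between two windows.
* **Nearest neighbors** — exact k-NN distance profiles against CSR bands,
  the symmetrized nearest-neighbor graph whose connected components define
  cluster sizes (minimum size 2), and cluster-histogram robustness to
  coordinate noise.
* **Voronoi volumetrics** — region-clipped 3D cell volumes (conserving the
  structural volume) and interior-only summaries.
* **Synthetic data** — ellipsoid region fixtures and CSR / gradient /
  Thomas-cluster / bundle generators reproducing the study conditions
  (13,989 somata; 557 more in one hemisphere; ~26.8% of CPu volume
  excluded by bundles), so the whole pipeline is testable without
  microscopy data.

## Worked example

```sh
python analysis/02_density_summaries.py
```

```
total somata: 13989
  L: 6716 cells / 24.19 mm^3 = 277.64 mm^-3
  R: 7273 cells / 23.92 mm^3 = 304.06 mm^-3
hemispheric count difference: 557 (3.98% of total)
hemispheric density difference: 26.42 mm^-3
CPu share of all somata: 61.1%
```

One hemisphere holds 557 more cholinergic neurons (3.98% of the total) in
a slightly smaller volume, i.e. packs them ~26 mm⁻³ denser; the
caudate-putamen alone carries 61% of all labeled cells.

```sh
python analysis/04_homogeneity_tests.py --seed 17
```

```
anterior_vs_posterior    CPu          L 1.26 4469 3537 1.380165e-13
anterior_vs_posterior     NB          L 1.18 1225 1037 2.704754e-03
anterior_vs_posterior     GP          L 0.96  303  315 6.331621e-01
...
anterior/posterior inhomogeneity detected in: ['CPu', 'NB']
```

(columns: comparison, region, hemisphere, F, df₁, df₂, one-sided p)

The F-test finds the anterior halves of CPu and NB significantly denser
than their posterior halves (the built-in density gradients), while the
CSR structures are homogeneous.  `analysis/03_ripley_envelopes.py` then
shows the homogeneous K flagging exactly those gradient structures as
"clustered", and `analysis/05_inhomogeneous_k.py` shows the rank test
*not* rejecting once the gradient is absorbed into the intensity — the
package's central contrast.

The numbered scripts under `analysis/` run the full sequence: simulate →
density summaries → K envelopes → homogeneity → K_inhom → neighbors/
clusters → Voronoi → calibration; each writes TSV/JSON under `results/`.
`analysis/09_replicate_supplementary.py` recomputes per-structure counts,
mean 1-NN distances and mean somal diameters from a user-supplied deposited
coordinate database (XLSX/CSV).

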