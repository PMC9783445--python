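# osteophylo

Phylogenetic comparative analysis of limb-bone microanatomy, built for the
question of how often — and how far — mammals that took up a subterranean
lifestyle remodelled the inner structure of their humerus.  The package
covers the whole analysis chain:

- **Voxel microanatomy** — bone volume fraction (BV/TV) in a volume of
  interest, mean trabecular thickness (Tb.Th) by the largest-inscribed-
  sphere definition, and whole-diaphysis global compactness from per-slice
  periosteal contours.
- **Timetree handling** — Newick I/O, divergence recalibration, and fossil
  tip grafting under alternative placement rules (stem-fraction and
  node-pushing), on non-ultrametric trees whose fossil tips end above the
  present.
- **Comparative statistics** — generalized least squares with
  ML/REML-optimized Pagel's λ and tip-height variance weights,
  phylogenetic ANCOVA, Nagelkerke pseudo-R², body-mass imputation from
  humeral cross-sectional area, and size-correction residuals.
- **Convergence testing** — the univariate C1 statistic on an
  acquisition-collapsed tree with a Brownian-motion simulation null.
- **Synthetic data** — Yule timetrees with independent "subterranean"
  regime paintings, BM/multi-optimum-OU trait evolution, and voxel
  phantoms of known bone fraction and strut thickness, so the entire
  pipeline is testable without any downloads.

## The statistics at the core

For a trait vector **y** with design **X** on a timetree, the GLS model is

```
y = Xβ + ε,   ε ~ N(0, σ² W(λ)),
W(λ)ᵢⱼ = λ · tᵢⱼ (i ≠ j),   W(λ)ᵢᵢ = tᵢᵢ,
```

where `tᵢⱼ` is the shared root-to-MRCA path length and `tᵢᵢ` the tip
height.  λ ∈ [0, 1] interpolates between a star phylogeny and Brownian
motion, and is optimized by profiling the (restricted) likelihood.
Leaving the diagonal at tip heights makes unequal tip variances — fossil
tips end early, having accumulated less Brownian variance — the GLS
weights.

The convergence index for focal tips *i*, *j* is

```
C1 = 1 − Σ Dtip / Σ Dmax
```

summed over all focal pairs, where `Dtip = |yᵢ − yⱼ|` and `Dmax` is the
largest distance between any two ancestral states (tips included) on the
two lineages back to their MRCA, with ancestral states reconstructed by
maximum likelihood under BM.  C1 = 1 means complete convergence from
maximally disparate ancestors; C1 ≈ 0 means the tips are as far apart as
their lineages ever were.  Significance comes from re-estimating the BM
rate on the collapsed tree, simulating BM datasets, and counting how often
the simulated C1 reaches the observed one.

## Worked example

```python
from osteophylo.reporting import run_pipeline

cfg = {
    "seed": 7,
    "n_sim": 500,
    "synth": {"n_tips": 155, "n_shifts": 11},   # 11 independent origins
    "exclude": ["acq_01_talpid_like"],          # re-run C1 without the extreme clade
    "trait_columns": ["bvtv"],
}
run_pipeline(cfg, out_dir="example_out")
```

`example_out/run.log` then reads:

```
osteophylo 0.1.0
seed 7
synthetic dataset: 155 tips, 11 acquisitions
variant base: 155 tips
[base] body-mass allometry: slope 1.4968, pseudo-R2 0.9911
[base] phyloANCOVA bvtv: group p = 1.798e-01, lambda = 0.807
[base] C1 bvtv: 0.2892 (p = 0.3493, 11 acquisitions)
wrote phenogram.csv, summary.csv
```

Reading it: the body-mass allometry recovered the generating power-law
slope (1.5); λ ≈ 0.8 says the size-corrected trait retains strong
phylogenetic signal; C1 ≈ 0.29 over the 11 acquisitions quantifies how
much of the lineages' historical disparity has been closed by convergent
evolution, and its p-value is the fraction of pure-BM simulations that
reach that value by chance.  `c1_base.json` additionally holds the
per-pair Dtip/Dmax decomposition and the re-run excluding the talpid-like
clade.

The same stages are scriptable from the shell (`osteophylo synth`,
`osteophylo quantify`, `osteophylo converge`, `osteophylo run`).

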