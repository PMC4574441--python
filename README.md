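# nucpos

Morphology-corrected analysis of 3D gene positioning relative to nuclear
heterochromatin.

## The problem

In mouse nuclei, two heterochromatin compartments are candidate "silencing
neighborhoods": the pericentric chromocenters (DAPI-dense bodies in the
nuclear interior) and the facultative heterochromatin lining the nuclear
periphery. Whether a gene's distance to these compartments tracks its
activity is confounded by morphology — nuclei flatten, grow and fuse their
chromocenters during myogenic differentiation (or under ectopic MeCP2
expression), so raw micrometre distances are not comparable between
conditions.

`nucpos` implements the measurement-and-statistics chain used to address
this with 3D-FISH data, for anyone who scores locus positions in confocal
z-stacks and wants shape-independent statistics:

1. **Geometry** — segment the nucleus (edge of the DAPI signal) and
   chromocenters (high-intensity DAPI, threshold mean + k·SD), detect FISH
   spots, and measure shortest 3D distances on the anisotropic voxel grid
   (default 0.08 × 0.08 × 0.2 µm) via exact Euclidean distance transforms.
2. **Per-nucleus Monte Carlo normalization** — simulate 10,000 random
   points uniform over each nucleus's volume, measure their distances, and
   re-express each observed distance *d* as its mid-rank empirical-CDF value
   within that nucleus's own background:

   *d̂* = ( #{*b* < *d*} + ½·#{*b* = *d*} ) / *n*  ∈ [0, 1].

   A randomly placed locus then has *d̂* ~ U(0, 1) regardless of nuclear
   shape or size.
3. **Randomness test** — bin *d̂* in 0.25 steps; under the null every bin
   holds 25%, and divergence is scored by χ² = Σ(Oᵢ−Eᵢ)²/Eᵢ with 3 degrees
   of freedom.
4. **Expression profiling** — from a log2 normalized probe × sample matrix
   (RMA-like, 5 replicates per condition): single-pass Nalimov outlier
   removal (p = 0.001), antilog fold changes, t-tests and ANOVA, selection
   at p ≤ 4 × 10⁻⁶, probe→gene collapse by maximal |log2FC|, and aggregation
   to BAC probes (overlap-weighted) and 2/5-Mbp neighborhoods.
5. **Genomic context** — RIDGE/anti-RIDGE features of gene-centered
   windows: CpG islands (≥ 500 bp, GC ≥ 0.5, observed/expected CpG ≥ 0.6),
   GC fraction, gene counts, SINE and LINE coverage.
6. **Correlation** — Pearson's R with Fisher-z 95% confidence intervals
   relating repositioning (ΔD = mean *d̂* in condition B − condition A) to
   expression change, and positions to genomic features.

A first-class synthetic-data generator produces nuclei (myoblast-like:
many small chromocenters; myotube-like: few large ones), loci with
controllable positional bias, replicate expression matrices with planted
fold changes and outliers, and a small genome with RIDGE/anti-RIDGE
structure — so the whole pipeline is testable end to end without any
downloads.

## Worked example

```python
import numpy as np
from nucpos.synthetic import SyntheticConfig, make_nucleus
from nucpos.mcnorm import sample_background, normalize_distance
from nucpos.geometry import measure_distances, sample_uniform_points, measure_distances_batch
from nucpos.stats import randomness_test

cfg = SyntheticConfig(rng_seed=1)
rng = np.random.default_rng(1)
nucleus, _ = make_nucleus("demo", cfg.with_preset("MT"), rng, render=False)
print(f"nucleus: {nucleus.volume_um3:.0f} um^3, {nucleus.n_chromocenters} chromocenters")

background = sample_background(nucleus, n=10_000, rng=rng)
rec = measure_distances((6.0, 5.0, 2.5), nucleus, locus_id="myLocus")
print(f"raw distances: periphery {rec.d_periphery:.2f} um, "
      f"chromocenter {rec.d_chromocenter:.2f} um")
print(f"normalized: periphery {normalize_distance(rec.d_periphery, background.d_periphery):.3f}, "
      f"chromocenter {normalize_distance(rec.d_chromocenter, background.d_chromocenter):.3f}")

points = sample_uniform_points(nucleus, 4000, rng)
d_per, _ = measure_distances_batch(points, nucleus)
res = randomness_test(normalize_distance(d_per, background.d_periphery))
print(f"uniform loci: chi2 = {res.chi2:.2f} (df {res.df}), p = {res.p_value:.2f} -> {res.verdict}")
```

prints

```
nucleus: 266 um^3, 6 chromocenters
raw distances: periphery 2.00 um, chromocenter 0.88 um
normalized: periphery 0.975, chromocenter 0.482
uniform loci: chi2 = 3.54 (df 3), p = 0.32 -> random
```

The locus is 2 µm from the periphery in raw units, yet farther from the
periphery than 97.5% of random points in *this* nucleus — the morphology
correction is the point. Uniformly placed loci are correctly called random.

The same chain runs end to end from the command line; with a planted
correlation of ρ = 0.8 between repositioning and expression change:

```bash
cat > config.yaml <<EOF
rng_seed: 1
synthetic:
  n_genes: 12
  n_nuclei: 20
  planted_rho: 0.8
  genome_length: 9000000
  block_size: 1500000
EOF
nucpos all --config config.yaml --outdir run
```

`run/correlation_repositioning.csv` then contains (gene scale):

```
scale              system  compartment      r  ci_low  ci_high  p_value  n
 gene myoblast_vs_myotube    periphery  0.733   0.275    0.920    0.007 12
 gene myoblast_vs_myotube chromocenter -0.723  -0.917   -0.256    0.008 12
```

The planted outward-on-up-regulation movement is recovered at the periphery
(R = 0.73); the mirrored chromocenter anti-correlation follows from
geometry (points pushed to the periphery move away from interior
chromocenters). `run/` also holds the randomness verdicts, the volcano
table, the window-feature table and the position-vs-RIDGE-feature
correlations, plus a manifest with seeds and SHA-256 hashes of every
artifact.

## Layout

| module | contents |
| --- | --- |
| `nucpos.geometry` | nucleus/chromocenter segmentation, spot detection, anisotropic distances |
| `nucpos.mcnorm` | Monte Carlo backgrounds, mid-rank ECDF normalization, ΔD |
| `nucpos.stats` | χ² randomness test, Pearson R with Fisher CIs, report assembly |
| `nucpos.expression` | Nalimov filter, fold changes, gene collapse, BAC/window aggregation |
| `nucpos.genome` | CpG islands, GC, gene density, SINE/LINE coverage, window features |
| `nucpos.synthetic` | the in-silico data generator (nuclei, loci, expression, genome) |
| `nucpos.pipeline` / `nucpos.cli` | seeded stage orchestration and the `nucpos` command |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
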