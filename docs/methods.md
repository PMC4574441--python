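# Methods

This note documents the models, the defaults and the numerical choices made
in `nucpos`, and what the synthetic-data tests do and do not establish.

## Distance measurement

Stacks are ZYX arrays on an anisotropic grid; the default voxel is
0.08 × 0.08 × 0.2 µm (xy × z), typical of a 63×/1.4 NA confocal z-stack.
Physical coordinates are always xyz in micrometres; voxel (iz, iy, ix) spans
`[i·s, (i+1)·s)` per axis with its centre at `(i+0.5)·s`.

Both compartment distances are computed with exact anisotropic Euclidean
distance transforms (`scipy.ndimage.distance_transform_edt` with the voxel
size as sampling): distance to the nearest out-of-mask voxel for the
periphery, distance to the nearest chromocenter voxel (zero inside) for
constitutive heterochromatin. Distances at arbitrary points are read from
the transform by trilinear interpolation, which agrees exactly with the
grid values at voxel centres and keeps sub-voxel variation between points
sharing a voxel. Accuracy is voxel-surface based: the error against
continuous geometry is bounded by half a voxel diagonal (~0.12 µm at the
default voxel). On masks small enough to enumerate, the transform matches a
brute-force minimum over all boundary voxels to < 10⁻⁶ µm (tested).

Conventions:

* A locus inside a chromocenter scores d = 0, not a negative signed depth.
* A nucleus without chromocenters yields a *missing* chromocenter distance,
  never 0.
* Segmentation: Gaussian smoothing, global Otsu, 3D hole filling, largest
  connected component (ties: first label in scan order). Chromocenters:
  intensity > mean + k·SD within the nuclear mask, default k = 2 — the
  source imagery defines chromocenters only qualitatively ("high-intensity
  DAPI"), so k is an explicit, logged parameter; an alternative channel
  (MeCP2-like immunofluorescence) can replace DAPI for thresholding.
* Label masks may be supplied directly, bypassing segmentation entirely.

## Per-nucleus Monte Carlo normalization

Each nucleus gets a background of n = 10,000 points uniform over its in-mask
volume (uniform voxel choice + in-voxel jitter; all voxels share one volume
on a regular grid). An observed distance d maps to its mid-rank empirical
CDF value within the background,

    d_norm = (#{b < d} + 0.5 · #{b = d}) / n .

The percentile form is deliberate: it is the only normalization for which
"25% of loci per 0.25-wide bin" is the *exact* null for random placement,
which the chi-square design requires. Ratio-to-mean normalizations do not
have this property. Mid-rank tie handling keeps the mean of the
background's own normalized values at exactly 0.5 and avoids saturation at
0/1; the transform is invariant to any monotone rescaling of raw distances.
One background serves all loci of its nucleus; backgrounds are seeded and
their seeds recorded in the run manifest. Nuclei lacking chromocenters
contribute periphery values only.

## Randomness test

Normalized distances are binned at 0.25 into four bins (last bin
right-closed); χ² = Σ(Oᵢ−Eᵢ)²/Eᵢ with Eᵢ = n/4 and 3 degrees of freedom.
The verdict threshold is α = 0.05 — chosen by analogy with the significance
level used for the correlations, since no explicit α accompanies the
chi-square design. Samples below n = 8 trigger a logged validity warning
(expected counts < 2). Under the uniform null the type-I error matches α
(tested by simulation).

## Pearson correlation reports

R is the product-moment coefficient; p-values are two-sided via
t = R·√((n−2)/(1−R²)) with n−2 df; intervals are Fisher-z at confidence
0.95 (SE = 1/√(n−3)). Zero variance raises an error rather than returning
R = 0. A one-sided interval mode (bound pinned at ±1 on the side of the
sign) exists for reproducing reports printed in that style; the default is
two-sided. Expression change enters correlations as signed log2 fold
change. No multiple-testing correction is applied to the per-cell reports
(matching per-cell reporting practice); a Benjamini–Hochberg column is
emitted as clearly-labeled supplementary output.

ΔD sign convention: ΔD = mean(d_norm in condition B) − mean(condition A), so
positive ΔD means farther from the compartment in B, and a positive R
between ΔD and log2FC is the "silencing compartment" direction
(up-regulated genes move away from heterochromatin).

## Expression profiling

Inputs are log2-scale normalized probe × sample matrices with ≥ 2 (default
5) replicates per condition. Per probe and condition a single-pass Nalimov
test removes at most the single most extreme replicate:

    q = |x* − x̄| / s · √(n/(n−1)),   reject if q > q_crit(n, α=0.001).

Critical values use the closed form `q_crit = √(n−1)·t/√(n−2+t²)` with
t = t(1−α/2, n−2), which reproduces the classical printed tables to their
three decimals (e.g., 1.757 / 1.918 / 1.982 for n = 5 at α = 0.05 / 0.01 /
0.001) and extends to any n; the printed values are frozen as a test
oracle. Single-pass removal is intentional: with five replicates, iterated
removal risks emptying groups.

A structural caveat worth knowing: the statistic is bounded by √(n−1)
(= 2.0 at n = 5), and the α = 0.001 critical value (1.982) sits ~1% below
that ceiling. Consequently a 5-SD outlier among noisy replicates clears the
threshold only rarely (~6% in simulation); reliable detection at this α and
n requires gross corruption (tens of noise SDs). The synthetic generator
therefore plants outliers of 50 noise-SD by default — large enough that the
stage must flag them — while the magnitude remains a parameter constrained
to ≥ 5 SD.

Fold changes are ratios of antilog (2^x) replicate means after filtering;
t-tests and the across-conditions ANOVA run on the log scale
(variance-stabilized). This asymmetry — effect size on the natural scale,
inference on the log scale — is deliberate and documented here because the
source protocol does not state the t-test scale. Probes collapse to genes
by maximal |log2FC| (ties: smaller p, then lexicographic probe id);
selection applies p ≤ 4 × 10⁻⁶ to the pairwise t-test. BAC aggregation
weights each overlapping gene's value by the overlapping fraction of the
*gene* length and averages; neighborhood aggregation averages values of
genes overlapping `[center − w, center + w)` with w = 1 or 2.5 Mbp around
the gene midpoint (rounded down). Coordinates are 0-based half-open
internally.

## Genomic context

CpG islands follow the three-threshold definition — length ≥ 500 bp,
GC ≥ 0.5, observed/expected CpG ≥ 0.6 with the Gardiner-Garden & Frommer
form obs/exp = N_CpG·L/(N_C·N_G) — implemented as the classic sliding
500-bp scan (step 1), merge of overlapping/adjacent qualifying windows, and
symmetric one-base trimming of each merged region until it qualifies as a
whole or drops below 500 bp. Windows containing N never qualify; GC content
excludes N from the denominator. The caller is validated against an
exhaustive naive-scan oracle on small sequences, and a BED-input mode
(supplied island track) exists for workflows that take islands from a
genome browser. Repeat coverage is merged-union overlap length / window
length, invariant to splitting intervals; gene counts use ≥ 1 bp overlap in
half-open coordinates after collapsing transcripts to gene spans.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analysis assumes:

* **Nuclei** — ellipsoids (default semiaxes 5 × 5 × 2.5 µm, ±10% per-nucleus
  jitter: the morphological variation the normalization must absorb) with
  chromocenter spheres placed fully inside, pairwise disjoint.
  Myoblast-like preset: 10–16 chromocenters of 0.4–0.7 µm; myotube-like:
  3–6 of 0.8–1.1 µm — the fewer-and-larger contrast of differentiation
  (and of high MeCP2 expressers), at counts and sizes that pack feasibly
  into the flat ellipsoid. DAPI-like renders add Gaussian noise; ground
  truth masks are always available.
* **Loci** — uniform over in-mask volume, or beta-biased on the normalized
  periphery-distance scale via inverse-ECDF lookup against the nucleus's
  own uniform candidate sample, guaranteeing self-consistency with the
  normalization stage (up to O(1/√m) empirical-CDF noise).
* **Expression** — 4 conditions × 5 replicates, log2 Gaussian replicate
  noise (SD 0.1), planted log2 fold changes applied to the second condition
  of each pair, and single-replicate outliers at rate 0.02 (default
  magnitude 50 noise-SD, see the Nalimov ceiling above).
* **Genome** — alternating 3-Mbp RIDGE-like blocks (GC 0.60, planted
  CpG-island cores, SINE-dense, gene-dense) and anti-RIDGE blocks (GC 0.37,
  LINE-dense, gene-poor) on one chromosome; iid backgrounds are explicitly
  CpG-depleted (most CG dinucleotides broken), since raw iid DNA has
  obs/exp ≈ 1 and would qualify wholesale as an island. Assay genes sit at
  block centers with ~180-kbp BACs (150–210 kbp) covering them.
* **Planted coupling** — per-gene (ΔD, log2FC) drawn jointly Gaussian at a
  requested correlation ρ, realized as beta-biased placements with mean
  0.5 ∓ ΔD/2 in the two conditions over a shared nucleus pool.

Not emulated: chromatin texture, optical PSF and spectral bleed-through,
chromosome territories, replication timing, probe hybridization chemistry,
transcript-level annotation complexity, inter-chromosomal layout. Passing
tests therefore demonstrate that the *measurement and statistics chain* is
correct and unbiased under its own assumptions — not that segmentation or
spot detection would be robust on real microscope data, nor that the
genomic feature contrasts have real-genome effect sizes.

## Problem sizes and determinism

The standard checks run at: 50 nuclei per panel, 80 loci per nucleus
(≥ 4,000 total), 10,000 background points per nucleus, 100 verdict
replicates; parameter-recovery runs use 200 genes, 25 nuclei per condition,
30 loci per gene, 5 replicates per condition. These sizes give per-bin
standard errors of ~0.7 percentage points and Fisher CIs of ±~0.05 around
ρ = 0.8 — tight enough for the assertions while staying desk-scale.

All randomness flows from a single root seed through
`numpy.random.default_rng`; pipeline stages derive per-stage seeds by
hashing (seed, stage-name), and identical seeds give byte-identical
artifacts (tested). Stable sorts and explicit tie-breaks (first maximal
label, smaller p then lexicographic id) remove order ambiguity.

## Known limitations

* Distances are voxel-surface based; sub-voxel accuracy is bounded by half
  a voxel diagonal, and anisotropy makes the z-contribution the dominant
  error term.
* Spot detection uses a single robust threshold and local maxima; it is not
  a deconvolving Gaussian fitter and will merge spots closer than ~2
  in-plane voxel radii.
* The Nalimov stage at α = 0.001 with five replicates is near-powerless
  against moderate outliers (ceiling effect above); this mirrors the
  published protocol rather than improving on it.
* Beta-biased placement matches the requested law only up to the
  inverse-ECDF lookup resolution (candidate sample of 4,000 per nucleus).
* The chi-square randomness test assumes loci are independent across nuclei
  of a condition; clustered probes within a nucleus would violate this.
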