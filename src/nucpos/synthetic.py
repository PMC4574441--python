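"""Fully in-silico inputs with the statistical structure the analysis assumes.

The generator emulates the two experimental systems on which the analysis is
exercised: a myogenic differentiation system (myoblast-like nuclei with many
small chromocenters vs myotube-like nuclei with fewer, larger ones) and an
ectopic-MeCP2-like system (low vs high expresser presets with the same
chromocenter contrast).  It produces

* anisotropic DAPI-like image stacks plus ground-truth nuclear and
  chromocenter label masks,
* FISH-like spot tables with controllable positional bias on the normalized
  distance scale,
* a 4-condition x 5-replicate log2 expression matrix with planted fold
  changes and planted single-replicate outliers,
* a small genome with alternating RIDGE-like blocks (GC-rich, CpG-island
  bearing, SINE-dense, gene-dense) and anti-RIDGE blocks (AT-rich,
  LINE-dense, gene-poor) with gene/repeat/BAC annotations,
* a planted gene-level correlation between repositioning and expression
  change for end-to-end parameter-recovery runs.

Everything is reproducible byte-for-byte from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .geometry import (
    ChromocenterPlacementError,
    NucleusModel,
    sample_uniform_points,
    write_stack,
)
from .mcnorm import BackgroundDistribution, sample_background

logger = logging.getLogger(__name__)

#: chromocenter presets: myoblast-like nuclei carry many small chromocenters,
#: myotube-like nuclei few large ones (differentiation fuses them)
PRESETS = {
    "MB": {"chromocenter_count_range": (10, 16), "chromocenter_radius_range": (0.4, 0.7)},
    "MT": {"chromocenter_count_range": (3, 6), "chromocenter_radius_range": (0.8, 1.1)},
}

#: which preset each default condition uses
CONDITION_PRESETS = {
    "myoblast": "MB",
    "myotube": "MT",
    "mecp2_low": "MB",
    "mecp2_high": "MT",
}


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic datasets.

    Defaults mirror the experimental design the analysis targets: 0.08 x
    0.08 x 0.2 um voxels, four conditions with five replicate arrays each,
    about 50 analyzed nuclei per condition, a 10,000-point background per
    nucleus, and 14 assayed genes.
    """

    rng_seed: int = 0
    n_nuclei: int = 50
    nucleus_semiaxes: tuple[float, float, float] = (5.0, 5.0, 2.5)
    semiaxis_jitter: float = 0.10
    voxel_size: tuple[float, float, float] = (0.08, 0.08, 0.2)
    chromocenter_count_range: tuple[int, int] = PRESETS["MB"]["chromocenter_count_range"]
    chromocenter_radius_range: tuple[float, float] = PRESETS["MB"]["chromocenter_radius_range"]
    locus_bias: str | tuple = "uniform"
    n_genes: int = 14
    n_probes_per_gene: int = 3
    conditions: tuple[str, ...] = ("myoblast", "myotube", "mecp2_low", "mecp2_high")
    condition_pairs: tuple[tuple[str, str], ...] = (
        ("myoblast", "myotube"),
        ("mecp2_low", "mecp2_high"),
    )
    replicates_per_condition: int = 5
    noise_sd: float = 0.1
    planted_log2fc: dict = field(default_factory=dict)
    outlier_rate: float = 0.02
    # single-replicate shift in units of noise_sd; the spec of the study design
    # requires >= 5; the default of 50 makes the shift detectable by the
    # Nalimov stage at p = 0.001 despite the statistic's sqrt(n-1) ceiling
    # (see docs/methods.md)
    outlier_magnitude_sd: float = 50.0
    genome_length: int = 18_000_000
    block_size: int = 3_000_000
    planted_rho: float = 0.0
    n_background: int = 10_000
    image_noise_sd: float = 6.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be strictly positive")
        if any(a <= 0 for a in self.nucleus_semiaxes):
            raise ValueError("nucleus semiaxes must be strictly positive")
        if self.replicates_per_condition < 2:
            raise ValueError("need at least 2 replicates per condition")
        if not -1.0 <= self.planted_rho <= 1.0:
            raise ValueError("planted_rho must lie in [-1, 1]")
        lo, hi = self.chromocenter_count_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid chromocenter_count_range")
        if self.outlier_magnitude_sd < 5.0:
            raise ValueError("outlier magnitude must be at least 5 noise SDs")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be a fraction")

    def with_preset(self, preset: str) -> "SyntheticConfig":
        """Copy of the config with an MB-like or MT-like chromocenter preset."""
        return dataclasses.replace(self, **PRESETS[preset])


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------


def _ellipsoid_mask(semiaxes_xyz, voxel_size, pad_um=0.4):
    """Boolean ellipsoid on the anisotropic grid; returns (mask, center_xyz_um)."""
    ax, ay, az = semiaxes_xyz
    sx, sy, sz = voxel_size
    nx = int(np.ceil(2 * (ax + pad_um) / sx))
    ny = int(np.ceil(2 * (ay + pad_um) / sy))
    nz = int(np.ceil(2 * (az + pad_um) / sz))
    cx, cy, cz = nx * sx / 2, ny * sy / 2, nz * sz / 2
    zc = (np.arange(nz) + 0.5) * sz
    yc = (np.arange(ny) + 0.5) * sy
    xc = (np.arange(nx) + 0.5) * sx
    zz = ((zc - cz) / az) ** 2
    yy = ((yc - cy) / ay) ** 2
    xx = ((xc - cx) / ax) ** 2
    mask = zz[:, None, None] + yy[None, :, None] + xx[None, None, :] <= 1.0
    return mask, (cx, cy, cz)


def _sample_in_ellipsoid(semiaxes, center, rng):
    """One point uniform in an ellipsoid (unit-ball sample scaled per axis)."""
    while True:
        p = rng.uniform(-1.0, 1.0, size=3)
        if p @ p <= 1.0:
            return center + p * np.asarray(semiaxes)


def make_nucleus(
    nucleus_id: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    condition: str | None = None,
    render: bool = True,
):
    """Build one synthetic nucleus: masks, chromocenters and a DAPI-like stack.

    Semiaxes are jittered per nucleus (morphological variation is exactly what
    the per-nucleus normalization must absorb).  Chromocenter spheres are
    placed fully inside the nuclear ellipsoid, pairwise disjoint, by rejection
    with bounded retries.  Returns ``(NucleusModel, stack_or_None)``.
    """
    j = config.semiaxis_jitter
    semiaxes = np.asarray(config.nucleus_semiaxes) * (1.0 + rng.uniform(-j, j, size=3))
    mask, center = _ellipsoid_mask(semiaxes, config.voxel_size)

    lo, hi = config.chromocenter_count_range
    n_cc = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    r_lo, r_hi = config.chromocenter_radius_range
    sx, sy, sz = config.voxel_size
    nz, ny, nx = mask.shape

    def _ball_voxels(c, radius):
        x0, y0, z0 = c
        ix = np.arange(max(0, int((x0 - radius) / sx)), min(nx, int((x0 + radius) / sx) + 2))
        iy = np.arange(max(0, int((y0 - radius) / sy)), min(ny, int((y0 + radius) / sy) + 2))
        iz = np.arange(max(0, int((z0 - radius) / sz)), min(nz, int((z0 + radius) / sz) + 2))
        dx2 = ((ix + 0.5) * sx - x0) ** 2
        dy2 = ((iy + 0.5) * sy - y0) ** 2
        dz2 = ((iz + 0.5) * sz - z0) ** 2
        ball = dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :] <= radius**2
        return np.ix_(iz, iy, ix), ball

    cc_labels = np.zeros(mask.shape, dtype=np.int32)
    placed: list[tuple[np.ndarray, float]] = []
    # placing the largest spheres first markedly raises the packing success rate
    radii = np.sort(rng.uniform(r_lo, r_hi, size=n_cc))[::-1]
    for radius in radii:
        inner = semiaxes - radius
        if (inner <= 0).any():
            raise ChromocenterPlacementError(
                f"nucleus {nucleus_id}: chromocenter radius {radius:.2f} um exceeds a semiaxis"
            )
        # one-voxel-plus gap so disjoint spheres stay disconnected on the grid
        gap = 2.0 * max(config.voxel_size)
        for attempt in range(500):
            c = _sample_in_ellipsoid(inner, np.asarray(center), rng)
            if not all(np.linalg.norm(c - c2) > radius + r2 + gap for c2, r2 in placed):
                continue
            # voxel-exact containment check: the flat ellipsoid's rim curves
            # tighter than a large sphere, so placement inside the shrunken
            # ellipsoid alone does not guarantee the sphere stays inside
            idx, ball = _ball_voxels(c, radius)
            if mask[idx][ball].all():
                cc_labels[idx] = np.where(ball, len(placed) + 1, cc_labels[idx])
                placed.append((c, radius))
                break
        else:
            raise ChromocenterPlacementError(
                f"nucleus {nucleus_id}: could not place chromocenter {len(placed) + 1}"
                f" of {n_cc} after 500 attempts"
            )

    nucleus = NucleusModel(
        nucleus_id=nucleus_id,
        mask=mask,
        chromocenters=cc_labels,
        voxel_size=config.voxel_size,
        condition=condition,
    )
    stack = None
    if render:
        stack = np.zeros(mask.shape, dtype=np.float32)
        stack[mask] = 100.0
        stack[cc_labels > 0] = 220.0
        if config.image_noise_sd > 0:
            stack += rng.normal(0.0, config.image_noise_sd, size=mask.shape).astype(np.float32)
    return nucleus, stack


def generate_nuclei(
    config: SyntheticConfig,
    n: int | None = None,
    preset: str | None = None,
    condition: str | None = None,
    rng: np.random.Generator | None = None,
    render: bool = True,
):
    """Generate a collection of nuclei (and DAPI-like stacks) for one condition."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if preset is not None:
        config = config.with_preset(preset)
    n = n if n is not None else config.n_nuclei
    prefix = condition or preset or "nucleus"
    out = []
    for i in range(n):
        out.append(
            make_nucleus(f"{prefix}_{i:03d}", config, rng, condition=condition, render=render)
        )
    return out


# ---------------------------------------------------------------------------
# loci
# ---------------------------------------------------------------------------


class PeripheryRankSampler:
    """Per-nucleus inverse-ECDF sampler over periphery-distance ranks.

    Holds a uniform candidate sample of the nucleus ordered by periphery
    distance; drawing at quantile u returns a point whose normalized
    periphery distance is ~u by construction.  Built once per nucleus and
    reused across genes.
    """

    def __init__(self, nucleus: NucleusModel, rng: np.random.Generator, m: int = 4000):
        from .geometry import measure_distances_batch

        points = sample_uniform_points(nucleus, m, rng)
        d_per, _ = measure_distances_batch(points, nucleus)
        order = np.argsort(d_per, kind="stable")
        self.points_sorted = points[order]
        self.m = m

    def at_quantiles(self, u: np.ndarray) -> np.ndarray:
        idx = np.minimum((np.asarray(u) * self.m).astype(int), self.m - 1)
        return self.points_sorted[idx]


def place_loci(
    nucleus: NucleusModel,
    bias="uniform",
    n: int = 1,
    rng: np.random.Generator | None = None,
    rng_seed: int | None = None,
    gene_id: str = "",
    n_candidates: int = 4000,
    sampler: "PeripheryRankSampler | None" = None,
) -> pd.DataFrame:
    """Place n loci in a nucleus, uniformly or with a beta positional bias.

    ``bias='uniform'`` draws loci uniformly over the in-mask volume.  A
    ``('beta', a, b)`` bias draws the target quantile u ~ Beta(a, b) and picks
    the candidate point whose periphery-distance rank within the nucleus's own
    uniform background sample matches u (inverse-ECDF lookup), so the
    normalized periphery distance of the loci follows the requested law by
    construction.
    """
    if n <= 0:
        raise ValueError("n must be a positive count")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    if bias == "uniform":
        pts = sample_uniform_points(nucleus, n, rng)
    else:
        kind, a, b = bias
        if kind != "beta":
            raise ValueError(f"unknown bias spec {bias!r}")
        if sampler is None:
            sampler = PeripheryRankSampler(nucleus, rng, m=n_candidates)
        pts = sampler.at_quantiles(rng.beta(a, b, size=n))
    return pd.DataFrame(
        {
            "locus_id": [f"{nucleus.nucleus_id}:{gene_id or 'locus'}:{i}" for i in range(n)],
            "gene_id": gene_id,
            "nucleus_id": nucleus.nucleus_id,
            "condition": nucleus.condition or "",
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "z_um": pts[:, 2],
        }
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(config: SyntheticConfig, rng: np.random.Generator | None = None):
    """Log2-scale probe x sample matrix with planted fold changes and outliers.

    Each gene gets a baseline log2 level; probes of a gene scatter around it.
    ``planted_log2fc[gene]`` is added to the second condition of every
    condition pair.  Replicates get Gaussian noise (``noise_sd`` log2 units);
    with probability ``outlier_rate`` per probe and condition one replicate is
    shifted by ``outlier_magnitude_sd * noise_sd`` (random sign).

    Returns ``(ExpressionMatrix, outlier_truth)`` where ``outlier_truth``
    lists every injected outlier (probe_id, condition, replicate).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    genes = [f"gene_{i:03d}" for i in range(config.n_genes)]
    treatment = {pair[1] for pair in config.condition_pairs}
    probe_rows, value_rows, outlier_rows = [], [], []
    sample_names = [
        f"{cond}_r{r}"
        for cond in config.conditions
        for r in range(config.replicates_per_condition)
    ]
    sample_conditions = pd.Series(
        {name: name.rsplit("_r", 1)[0] for name in sample_names}
    )
    for gene in genes:
        base = rng.normal(7.0, 1.0)
        fc = float(config.planted_log2fc.get(gene, 0.0))
        for p in range(config.n_probes_per_gene):
            probe_id = f"{gene}_p{p}"
            probe_rows.append({"probe_id": probe_id, "gene_id": gene})
            level = base + rng.normal(0.0, 0.3)
            values = {}
            for cond in config.conditions:
                mean = level + (fc if cond in treatment else 0.0)
                reps = mean + rng.normal(0.0, config.noise_sd, config.replicates_per_condition)
                if config.outlier_rate > 0 and rng.random() < config.outlier_rate:
                    r = int(rng.integers(0, config.replicates_per_condition))
                    shift = config.outlier_magnitude_sd * config.noise_sd * rng.choice([-1.0, 1.0])
                    reps[r] += shift
                    outlier_rows.append(
                        {"probe_id": probe_id, "condition": cond, "replicate": r, "shift": shift}
                    )
                for r in range(config.replicates_per_condition):
                    values[f"{cond}_r{r}"] = reps[r]
            value_rows.append(pd.Series(values, name=probe_id))
    matrix = pd.DataFrame(value_rows)[sample_names]
    probe_map = pd.DataFrame(probe_rows)
    truth = pd.DataFrame(outlier_rows, columns=["probe_id", "condition", "replicate", "shift"])
    return ExpressionMatrix(matrix, sample_conditions, probe_map), truth


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeAnnotation:
    """A synthetic single-chromosome genome with RIDGE/anti-RIDGE structure."""

    chrom: str
    sequence: str
    genes: pd.DataFrame
    repeats: pd.DataFrame
    bacs: pd.DataFrame
    blocks: pd.DataFrame
    assay_genes: list


def _random_sequence(length: int, gc: float, rng, cpg_depletion: float = 0.85) -> np.ndarray:
    """IID sequence at a target GC with CpG dinucleotides suppressed.

    Random iid DNA has an observed/expected CpG ratio near 1, unlike real
    vertebrate DNA (CpG-depleted outside islands); mutating the G of most CG
    dinucleotides to A restores that depletion so island calling stays
    meaningful.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(BASES, size=length, p=p)
    if cpg_depletion > 0:
        cg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
        hit = cg[rng.random(cg.size) < cpg_depletion]
        seq[hit + 1] = ord("A")
    return seq


def _cpg_island_sequence(length: int, rng) -> np.ndarray:
    """CpG-rich island core: CG dinucleotide repeats with light random admixture."""
    seq = np.tile(np.frombuffer(b"CG", dtype=np.uint8), length // 2 + 1)[:length].copy()
    mix = rng.random(length) < 0.15
    seq[mix] = rng.choice(BASES, size=int(mix.sum()))
    return seq


def generate_genome_annotation(config: SyntheticConfig, rng: np.random.Generator | None = None):
    """Synthetic genome with alternating RIDGE / anti-RIDGE blocks plus BED annotation.

    RIDGE blocks: GC-rich, CpG-island bearing, SINE-dense, gene-dense.
    anti-RIDGE blocks: AT-rich, LINE-dense, gene-poor, island-free.
    Assay genes (the ones carrying expression and FISH data) sit at block
    centers; a ~180-kbp BAC covers each.  Alphabet is A/C/G/T only.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if config.genome_length < 2 * config.block_size:
        raise ValueError(
            f"genome_length {config.genome_length} cannot host two blocks of {config.block_size}"
        )
    n_blocks = config.genome_length // config.block_size
    chrom = "chr1"
    parts, block_rows, gene_rows, repeat_rows = [], [], [], []
    islands_per_ridge_block = 40
    gene_density = {"RIDGE": 12, "anti-RIDGE": 3}  # per Mbp
    sine_cov = {"RIDGE": 0.25, "anti-RIDGE": 0.05}
    line_cov = {"RIDGE": 0.05, "anti-RIDGE": 0.30}
    gc = {"RIDGE": 0.60, "anti-RIDGE": 0.37}

    for b in range(n_blocks):
        kind = "RIDGE" if b % 2 == 0 else "anti-RIDGE"
        start = b * config.block_size
        seq = _random_sequence(config.block_size, gc[kind], rng)
        n_islands = islands_per_ridge_block if kind == "RIDGE" else 0
        for _ in range(n_islands):
            ilen = int(rng.integers(600, 1200))
            pos = int(rng.integers(0, config.block_size - ilen))
            seq[pos:pos + ilen] = _cpg_island_sequence(ilen, rng)
        parts.append(seq)
        block_rows.append(
            {"chrom": chrom, "start": start, "end": start + config.block_size,
             "kind": kind, "n_planted_islands": n_islands}
        )
        # background genes
        n_genes_blk = int(gene_density[kind] * config.block_size / 1e6)
        for g in range(n_genes_blk):
            length = int(rng.integers(20_000, 80_000))
            pos = int(rng.integers(0, config.block_size - length))
            gene_rows.append(
                {"chrom": chrom, "start": start + pos, "end": start + pos + length,
                 "name": f"blk{b}_g{g}", "feature_class": "gene", "block_kind": kind}
            )
        # repeats
        for cls, cov, rep_len in (("SINE", sine_cov[kind], 200), ("LINE", line_cov[kind], 3000)):
            n_rep = int(cov * config.block_size / rep_len)
            for _ in range(n_rep):
                pos = int(rng.integers(0, config.block_size - rep_len))
                repeat_rows.append(
                    {"chrom": chrom, "start": start + pos, "end": start + pos + rep_len,
                     "name": cls, "feature_class": cls}
                )

    # assay genes at block centers, cycling over blocks
    assay_rows, bac_rows = [], []
    for i in range(config.n_genes):
        b = i % n_blocks
        kind = "RIDGE" if b % 2 == 0 else "anti-RIDGE"
        length = 30_000
        center = b * config.block_size + config.block_size // 2
        jitter = int(rng.integers(-config.block_size // 8, config.block_size // 8))
        g_start = center + jitter - length // 2
        gene_id = f"gene_{i:03d}"
        assay_rows.append(
            {"chrom": chrom, "start": g_start, "end": g_start + length,
             "name": gene_id, "feature_class": "gene", "block_kind": kind}
        )
        bac_len = int(rng.integers(150_000, 210_001))
        offset = int(rng.integers(0, max(1, bac_len - length)))
        bac_rows.append(
            {"chrom": chrom, "start": g_start - offset, "end": g_start - offset + bac_len,
             "name": f"BAC_{gene_id}"}
        )

    genes = pd.DataFrame(gene_rows + assay_rows).sort_values(["start", "name"]).reset_index(drop=True)
    sequence = b"".join(p.tobytes() for p in parts).decode("ascii")
    return GenomeAnnotation(
        chrom=chrom,
        sequence=sequence,
        genes=genes,
        repeats=pd.DataFrame(repeat_rows),
        bacs=pd.DataFrame(bac_rows),
        blocks=pd.DataFrame(block_rows),
        assay_genes=[r["name"] for r in assay_rows],
    )


# ---------------------------------------------------------------------------
# planted repositioning-expression correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelatedDataset:
    """End-to-end dataset with a planted Δposition-log2FC correlation."""

    nuclei: dict
    backgrounds: dict
    loci: pd.DataFrame
    expression: ExpressionMatrix
    truth: pd.DataFrame
    condition_pair: tuple[str, str]


def generate_correlated_dataset(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    n_nuclei_pool: int = 25,
    loci_per_gene: int = 30,
    delta_scale: float = 0.22,
    log2fc_scale: float = 1.2,
    beta_concentration: float = 30.0,
) -> CorrelatedDataset:
    """Plant a correlation ``planted_rho`` between ΔD (periphery) and log2 fold change.

    Per-gene true repositioning and expression change are drawn jointly
    Gaussian with the requested correlation; positions are realized with beta
    biases targeting mean normalized periphery distances ``0.5 -/+ ΔD/2`` in
    the two conditions of the first condition pair, over a shared pool of
    nuclei per condition.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    rho = config.planted_rho
    cond_a, cond_b = config.condition_pairs[0]
    genes = [f"gene_{i:03d}" for i in range(config.n_genes)]

    z1 = rng.normal(size=config.n_genes)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal(size=config.n_genes)
    delta_true = np.clip(delta_scale * z1, -0.6, 0.6)
    log2fc_true = log2fc_scale * z2

    cfg_expr = dataclasses.replace(
        config, planted_log2fc=dict(zip(genes, log2fc_true)), outlier_rate=0.0
    )
    expression, _ = generate_expression(cfg_expr, rng)

    nuclei: dict[str, NucleusModel] = {}
    backgrounds: dict[str, BackgroundDistribution] = {}
    samplers: dict[str, PeripheryRankSampler] = {}
    pools: dict[str, list[str]] = {}
    for cond in (cond_a, cond_b):
        preset = CONDITION_PRESETS.get(cond, "MB")
        pool = generate_nuclei(
            config.with_preset(preset), n=n_nuclei_pool, condition=cond, rng=rng, render=False
        )
        pools[cond] = []
        for nucleus, _ in pool:
            nuclei[nucleus.nucleus_id] = nucleus
            backgrounds[nucleus.nucleus_id] = sample_background(
                nucleus, n=config.n_background, rng=rng
            )
            samplers[nucleus.nucleus_id] = PeripheryRankSampler(nucleus, rng)
            pools[cond].append(nucleus.nucleus_id)

    loci_rows = []
    kappa = beta_concentration
    for gene, delta in zip(genes, delta_true):
        for cond, sign in ((cond_a, -1.0), (cond_b, +1.0)):
            mu = float(np.clip(0.5 + sign * delta / 2.0, 0.02, 0.98))
            picks = rng.choice(pools[cond], size=loci_per_gene)
            u = rng.beta(mu * kappa, (1.0 - mu) * kappa, size=loci_per_gene)
            for k, nucleus_id in enumerate(picks):
                x, y, z = samplers[nucleus_id].at_quantiles(np.array([u[k]]))[0]
                loci_rows.append(
                    {"locus_id": f"{nucleus_id}:{gene}:{k}", "gene_id": gene,
                     "nucleus_id": nucleus_id, "condition": cond,
                     "x_um": x, "y_um": y, "z_um": z}
                )
    loci = pd.DataFrame(loci_rows)
    truth = pd.DataFrame(
        {"gene_id": genes, "delta_true": delta_true, "log2fc_true": log2fc_true}
    )
    return CorrelatedDataset(
        nuclei=nuclei, backgrounds=backgrounds, loci=loci,
        expression=expression, truth=truth, condition_pair=(cond_a, cond_b),
    )


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------


def save_dataset(
    outdir,
    config: SyntheticConfig,
    nuclei_stacks,
    loci: pd.DataFrame,
    expression: ExpressionMatrix | None = None,
    outlier_truth: pd.DataFrame | None = None,
    genome: GenomeAnnotation | None = None,
    ground_truth: pd.DataFrame | None = None,
) -> dict:
    """Write every artifact to disk and return the manifest (also saved as JSON).

    Emits per-nucleus DAPI-like stacks and label masks (multi-page TIFF, ZYX),
    a spot CSV, the expression matrix + sample sheet + probe map CSVs, the
    genome FASTA and gene/repeat/BAC BEDs, and ground-truth tables.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"rng_seed": config.rng_seed, "files": {}}

    img_dir = outdir / "images"
    img_dir.mkdir(exist_ok=True)
    stacks, masks = [], []
    for nucleus, stack in nuclei_stacks:
        base = img_dir / nucleus.nucleus_id
        if stack is not None:
            write_stack(f"{base}_dapi.tif", stack)
            stacks.append(f"{base}_dapi.tif")
        write_stack(f"{base}_mask.tif", nucleus.mask.astype(np.uint8))
        write_stack(f"{base}_chromocenters.tif", nucleus.chromocenters.astype(np.int32))
        masks.append(f"{base}_mask.tif")
    manifest["files"]["stacks"] = stacks
    manifest["files"]["masks"] = masks

    loci_path = outdir / "spots.csv"
    loci.to_csv(loci_path, index=False)
    manifest["files"]["spots"] = str(loci_path)

    if expression is not None:
        expr_path = outdir / "expression.csv"
        expression.values.to_csv(expr_path, index_label="probe_id")
        expression.sample_conditions.rename("condition").to_csv(
            outdir / "samples.csv", index_label="sample"
        )
        if expression.probe_map is not None:
            expression.probe_map.to_csv(outdir / "probes.csv", index=False)
        manifest["files"]["expression"] = str(expr_path)
    if outlier_truth is not None:
        outlier_truth.to_csv(outdir / "outlier_truth.csv", index=False)
        manifest["files"]["outlier_truth"] = str(outdir / "outlier_truth.csv")
    if genome is not None:
        fasta_path = outdir / "genome.fa"
        SeqIO.write(
            [SeqRecord(Seq(genome.sequence), id=genome.chrom, description="")],
            str(fasta_path), "fasta",
        )
        genome.genes.to_csv(outdir / "genes.bed", sep="\t", header=False, index=False,
                            columns=["chrom", "start", "end", "name", "feature_class"])
        genome.repeats.to_csv(outdir / "repeats.bed", sep="\t", header=False, index=False,
                              columns=["chrom", "start", "end", "name", "feature_class"])
        genome.bacs.to_csv(outdir / "bacs.bed", sep="\t", header=False, index=False,
                           columns=["chrom", "start", "end", "name"])
        genome.blocks.to_csv(outdir / "blocks_truth.csv", index=False)
        manifest["files"]["genome"] = str(fasta_path)
        for key in ("genes", "repeats", "bacs"):
            manifest["files"][key] = str(outdir / f"{key}.bed")
    if ground_truth is not None:
        ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
        manifest["files"]["ground_truth"] = str(outdir / "ground_truth.csv")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["files"]["manifest"] = str(manifest_path)
    return manifest
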