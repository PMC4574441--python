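"""End-to-end orchestration: seeded stages from simulation to correlation reports.

Every stage reads and writes plain CSV/JSON/TIFF artifacts inside one output
directory and appends to a run manifest, so the pipeline is re-entrant from
any stage given the prior artifacts.  All randomness flows from one root seed
expanded per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (
    DEFAULT_NALIMOV_ALPHA,
    DEFAULT_SELECTION_P,
    ExpressionMatrix,
    bac_expression,
    collapse_to_gene,
    fold_change,
    neighborhood_expression,
    select_significant,
    volcano_table,
)
from .genome import features_for_genes, read_bed
from .mcnorm import DEFAULT_N_BACKGROUND, delta_position, normalize_loci, sample_background
from .stats import (
    DEFAULT_ALPHA,
    correlate_position_features,
    correlate_repositioning,
    randomness_test,
    results_to_frame,
)
from .synthetic import (
    SyntheticConfig,
    generate_correlated_dataset,
    generate_expression,
    generate_genome_annotation,
    save_dataset,
)

logger = logging.getLogger(__name__)

COMPARTMENTS = ("periphery", "chromocenter")
SCALES = ("gene", "BAC", "2Mbp", "5Mbp")


@dataclass
class RunConfig:
    """Structured run configuration; defaults match the analysis parameters.

    Round-trips losslessly through YAML (:meth:`to_yaml` / :meth:`from_yaml`).
    """

    rng_seed: int = 0
    n_background_points: int = DEFAULT_N_BACKGROUND
    alpha: float = DEFAULT_ALPHA
    selection_p: float = DEFAULT_SELECTION_P
    nalimov_alpha: float = DEFAULT_NALIMOV_ALPHA
    half_widths: tuple[int, int] = (1_000_000, 2_500_000)
    chromocenter_k: float = 2.0
    save_images: bool = False
    synthetic: dict = field(default_factory=dict)

    def synthetic_config(self) -> SyntheticConfig:
        kw = dict(self.synthetic)
        kw.setdefault("rng_seed", self.rng_seed)
        kw.setdefault("n_background", self.n_background_points)
        if "planted_log2fc" in kw and kw["planted_log2fc"] is None:
            kw.pop("planted_log2fc")
        for key in ("nucleus_semiaxes", "voxel_size"):
            if key in kw:
                kw[key] = tuple(kw[key])
        for key in ("chromocenter_count_range", "chromocenter_radius_range"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "conditions" in kw:
            kw["conditions"] = tuple(kw["conditions"])
        if "condition_pairs" in kw:
            kw["condition_pairs"] = tuple(tuple(p) for p in kw["condition_pairs"])
        return SyntheticConfig(**kw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["half_widths"] = list(self.half_widths)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "half_widths" in data:
            data["half_widths"] = tuple(data["half_widths"])
        return cls(**data)


class RunManifest:
    """Append-only record of stage outputs, seeds and content hashes."""

    def __init__(self, outdir: Path, config: RunConfig):
        self.path = Path(outdir) / "run_manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            cfg = dataclasses.asdict(config)
            cfg["half_widths"] = list(config.half_widths)
            self.data = {"version": __version__, "config": cfg, "stages": {}, "warnings": []}

    def record(self, stage: str, files: dict, seed: int | None = None) -> None:
        hashes = {}
        for key, p in files.items():
            p = Path(p)
            if p.exists():
                hashes[key] = {
                    "path": str(p),
                    "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
                }
        self.data["stages"][stage] = {"seed": seed, "outputs": hashes}
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _stage_seed(root_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) deterministically from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, outdir) -> dict:
    """Generate the full synthetic dataset and write its artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = _stage_seed(config.rng_seed, "simulate")
    syn = dataclasses.replace(config.synthetic_config(), rng_seed=seed)
    rng = np.random.default_rng(seed)

    dataset = generate_correlated_dataset(syn, rng=rng, n_nuclei_pool=syn.n_nuclei)
    expr_full, outlier_truth = generate_expression(syn, np.random.default_rng(seed + 1))
    genome = generate_genome_annotation(syn, np.random.default_rng(seed + 2))

    # label masks are always written; DAPI-like renders only on request
    # (the measurement path accepts masks directly, bypassing segmentation)
    nuclei_stacks = [(n, None) for n in dataset.nuclei.values()]
    if config.save_images:
        rng_img = np.random.default_rng(seed + 3)
        nuclei_stacks = [
            (n, (100.0 * n.mask + 120.0 * (n.chromocenters > 0)
                 + rng_img.normal(0.0, syn.image_noise_sd, n.mask.shape)).astype(np.float32))
            for n in dataset.nuclei.values()
        ]
    manifest_files = save_dataset(
        outdir / "dataset",
        syn,
        nuclei_stacks,
        dataset.loci,
        expression=dataset.expression,
        outlier_truth=outlier_truth,
        genome=genome,
        ground_truth=dataset.truth,
    )
    # the independently-seeded matrix with planted outliers feeds the volcano stage
    expr_full.values.to_csv(outdir / "dataset" / "expression_outliers.csv", index_label="probe_id")

    normalized = normalize_loci(dataset.loci, dataset.nuclei, dataset.backgrounds)
    normalized.to_csv(outdir / "normalized.csv", index=False)

    manifest = RunManifest(outdir, config)
    manifest.record(
        "simulate",
        {"normalized": outdir / "normalized.csv", "manifest": manifest_files["files"]["manifest"]},
        seed=seed,
    )
    return {
        "dataset": dataset,
        "genome": genome,
        "expression_outliers": (expr_full, outlier_truth),
        "normalized": normalized,
    }


def _load_nuclei_from_masks(config: RunConfig, outdir: Path) -> dict:
    """Rebuild NucleusModel objects from the label-mask TIFFs of a dataset dir."""
    from .geometry import NucleusModel, read_stack

    img_dir = Path(outdir) / "dataset" / "images"
    spots = pd.read_csv(Path(outdir) / "dataset" / "spots.csv")
    conditions = spots.drop_duplicates("nucleus_id").set_index("nucleus_id")["condition"]
    syn = config.synthetic_config()
    nuclei = {}
    for mask_path in sorted(img_dir.glob("*_mask.tif")):
        nucleus_id = mask_path.name[: -len("_mask.tif")]
        mask = read_stack(mask_path).astype(bool)
        cc = read_stack(img_dir / f"{nucleus_id}_chromocenters.tif")
        nuclei[nucleus_id] = NucleusModel(
            nucleus_id=nucleus_id, mask=mask, chromocenters=cc,
            voxel_size=syn.voxel_size,
            condition=conditions.get(nucleus_id),
        )
    if not nuclei:
        raise FileNotFoundError(f"no *_mask.tif label masks under {img_dir}")
    return nuclei


def stage_segment(config: RunConfig, outdir) -> dict:
    """Segment nuclei and chromocenters from DAPI-like stacks (image input path)."""
    from .geometry import read_stack, segment_chromocenters, segment_nucleus, write_stack

    outdir = Path(outdir)
    img_dir = outdir / "dataset" / "images"
    seg_dir = outdir / "segmented"
    seg_dir.mkdir(parents=True, exist_ok=True)
    syn = config.synthetic_config()
    stacks = sorted(img_dir.glob("*_dapi.tif"))
    if not stacks:
        raise FileNotFoundError(f"no *_dapi.tif stacks under {img_dir}")
    nuclei = {}
    for path in stacks:
        nucleus_id = path.name[: -len("_dapi.tif")]
        stack = read_stack(path)
        nucleus = segment_nucleus(stack, voxel_size=syn.voxel_size, nucleus_id=nucleus_id)
        nucleus.chromocenters = segment_chromocenters(stack, nucleus, k=config.chromocenter_k)
        write_stack(seg_dir / f"{nucleus_id}_mask.tif", nucleus.mask.astype(np.uint8))
        write_stack(seg_dir / f"{nucleus_id}_chromocenters.tif", nucleus.chromocenters)
        nuclei[nucleus_id] = nucleus
    RunManifest(outdir, config).record(
        "segment", {"segmented_dir": seg_dir / f"{sorted(nuclei)[0]}_mask.tif"}
    )
    return nuclei


def stage_measure(config: RunConfig, outdir) -> pd.DataFrame:
    """Raw shortest distances (um) for every spot, from label masks + spot table."""
    from .geometry import measure_distances_batch

    outdir = Path(outdir)
    nuclei = _load_nuclei_from_masks(config, outdir)
    spots = pd.read_csv(outdir / "dataset" / "spots.csv")
    frames = []
    for nucleus_id, group in spots.groupby("nucleus_id", sort=True):
        d_per, d_cc = measure_distances_batch(
            group[["x_um", "y_um", "z_um"]].to_numpy(), nuclei[nucleus_id]
        )
        part = group[["locus_id", "gene_id", "nucleus_id", "condition"]].copy()
        part["d_per_um"] = d_per
        part["d_cc_um"] = d_cc
        frames.append(part)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(outdir / "distances.csv", index=False)
    RunManifest(outdir, config).record("measure", {"distances": outdir / "distances.csv"})
    return out


def stage_normalize(config: RunConfig, outdir) -> pd.DataFrame:
    """Per-nucleus Monte Carlo backgrounds + mid-rank normalization from artifacts."""
    outdir = Path(outdir)
    seed = _stage_seed(config.rng_seed, "normalize")
    rng = np.random.default_rng(seed)
    nuclei = _load_nuclei_from_masks(config, outdir)
    backgrounds = {
        nucleus_id: sample_background(n, n=config.n_background_points, rng=rng)
        for nucleus_id, n in sorted(nuclei.items())
    }
    spots = pd.read_csv(outdir / "dataset" / "spots.csv")
    normalized = normalize_loci(spots, nuclei, backgrounds)
    normalized.to_csv(outdir / "normalized.csv", index=False)
    RunManifest(outdir, config).record(
        "normalize", {"normalized": outdir / "normalized.csv"}, seed=seed
    )
    return normalized


def stage_test_random(config: RunConfig, outdir, normalized: pd.DataFrame | None = None) -> pd.DataFrame:
    """Chi-square randomness verdicts per gene x condition x compartment."""
    outdir = Path(outdir)
    if normalized is None:
        normalized = pd.read_csv(outdir / "normalized.csv")
    rows = []
    for compartment, col in (("periphery", "norm_per"), ("chromocenter", "norm_cc")):
        df = normalized.dropna(subset=[col])
        for (gene, condition), group in df.groupby(["gene_id", "condition"], sort=True):
            res = randomness_test(
                group[col], alpha=config.alpha,
                gene_id=gene, condition=condition, compartment=compartment,
            )
            rows.append(
                {"gene_id": gene, "condition": condition, "compartment": compartment,
                 "n": res.n, "chi2": res.chi2, "df": res.df, "p_value": res.p_value,
                 "verdict": res.verdict,
                 **{f"bin{i}": int(c) for i, c in enumerate(res.observed)}}
            )
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "randomness.csv", index=False)
    RunManifest(outdir, config).record("test-random", {"randomness": outdir / "randomness.csv"})
    return out


def stage_expression(
    config: RunConfig, outdir, matrix: ExpressionMatrix | None = None
) -> dict[str, pd.DataFrame]:
    """Fold changes, gene collapse, significance selection and volcano tables per pair."""
    outdir = Path(outdir)
    if matrix is None:
        values = pd.read_csv(outdir / "dataset" / "expression.csv", index_col="probe_id")
        samples = pd.read_csv(outdir / "dataset" / "samples.csv", index_col="sample")["condition"]
        probes = pd.read_csv(outdir / "dataset" / "probes.csv")
        matrix = ExpressionMatrix(values, samples, probes)
    syn = config.synthetic_config()
    results = {}
    for cond_a, cond_b in syn.condition_pairs:
        records = fold_change(matrix, cond_a, cond_b, nalimov_alpha=config.nalimov_alpha)
        records = select_significant(records, p_threshold=config.selection_p)
        genes = collapse_to_gene(records, matrix.probe_map)
        pair = f"{cond_a}_vs_{cond_b}"
        records.to_csv(outdir / f"expression_{pair}.csv")
        genes.to_csv(outdir / f"expression_genes_{pair}.csv")
        volcano_table(genes).to_csv(outdir / f"volcano_{pair}.csv")
        results[pair] = genes
    RunManifest(outdir, config).record(
        "expression",
        {f"genes_{p}": outdir / f"expression_genes_{p}.csv" for p in results},
    )
    return results


def stage_context(config: RunConfig, outdir, genome=None) -> dict[int, pd.DataFrame]:
    """RIDGE/anti-RIDGE window features for the assayed genes at both window widths."""
    outdir = Path(outdir)
    if genome is not None:
        sequences = {genome.chrom: genome.sequence}
        genes, repeats = genome.genes, genome.repeats
        assay = genome.assay_genes
    else:
        from pyfaidx import Fasta

        fasta = Fasta(str(outdir / "dataset" / "genome.fa"))
        sequences = {name: str(fasta[name][:]) for name in fasta.keys()}
        genes = read_bed(outdir / "dataset" / "genes.bed")
        repeats = read_bed(outdir / "dataset" / "repeats.bed")
        assay = sorted(pd.read_csv(outdir / "dataset" / "probes.csv")["gene_id"].unique())
    outputs = {}
    for half_width in config.half_widths:
        feats = features_for_genes(assay, half_width, sequences, genes, repeats)
        path = outdir / f"window_features_{2 * half_width // 1_000_000}Mbp.csv"
        feats.to_csv(path, index=False)
        outputs[half_width] = feats
    RunManifest(outdir, config).record(
        "context",
        {f"{2 * hw // 1_000_000}Mbp": outdir / f"window_features_{2 * hw // 1_000_000}Mbp.csv"
         for hw in config.half_widths},
    )
    return outputs


def _scale_expression(genes: pd.DataFrame, gene_coords: pd.DataFrame, bacs: pd.DataFrame,
                      scale: str, half_widths) -> pd.DataFrame:
    """Per-gene signed log2 expression change aggregated at the requested scale."""
    records = gene_coords.join(genes[["fold_change"]], how="inner")
    records = records.rename(columns={"fold_change": "value"})
    if scale == "gene":
        agg = records["value"]
    elif scale == "BAC":
        vals = {}
        bac_idx = bacs.set_index("name")
        for gene_id in records.index:
            key = f"BAC_{gene_id}"
            if key not in bac_idx.index:
                continue
            b = bac_idx.loc[key]
            v, _ = bac_expression(records, (b["chrom"], int(b["start"]), int(b["end"])))
            vals[gene_id] = v
        agg = pd.Series(vals)
    else:
        hw = half_widths[0] if scale == "2Mbp" else half_widths[1]
        agg = pd.Series(
            {g: neighborhood_expression(records, g, hw) for g in records.index}
        )
    out = np.log2(agg.dropna())
    return out.rename("log2fc").rename_axis("gene_id").reset_index()


def stage_correlate(
    config: RunConfig,
    outdir,
    normalized: pd.DataFrame | None = None,
    expression_by_pair: dict[str, pd.DataFrame] | None = None,
    features: dict[int, pd.DataFrame] | None = None,
    genome=None,
) -> dict[str, pd.DataFrame]:
    """Pearson reports: repositioning vs expression (4 scales x 2 compartments x
    systems) and position vs RIDGE features (5 features x 2 compartments x
    conditions)."""
    outdir = Path(outdir)
    if normalized is None:
        normalized = pd.read_csv(outdir / "normalized.csv")
    syn = config.synthetic_config()
    if expression_by_pair is None:
        expression_by_pair = {
            f"{a}_vs_{b}": pd.read_csv(outdir / f"expression_genes_{a}_vs_{b}.csv",
                                       index_col="gene_id")
            for a, b in syn.condition_pairs
        }
    if genome is not None:
        gene_coords = genome.genes.set_index("name")[["chrom", "start", "end"]]
        bacs = genome.bacs
    else:
        genes_bed = read_bed(outdir / "dataset" / "genes.bed")
        gene_coords = genes_bed.set_index("name")[["chrom", "start", "end"]]
        bacs = read_bed(outdir / "dataset" / "bacs.bed")
    if features is None:
        features = {
            hw: pd.read_csv(outdir / f"window_features_{2 * hw // 1_000_000}Mbp.csv")
            for hw in config.half_widths
        }

    # Repositioning vs expression change
    repositioning = []
    available = set(normalized["condition"].unique())
    for cond_a, cond_b in syn.condition_pairs:
        if not {cond_a, cond_b} <= available:
            logger.info("no position data for pair %s/%s; skipped", cond_a, cond_b)
            continue
        system = f"{cond_a}_vs_{cond_b}"
        genes = expression_by_pair[system]
        dpos = pd.concat(
            [delta_position(normalized, cond_a, cond_b, compartment=c) for c in COMPARTMENTS],
            ignore_index=True,
        )
        for scale in SCALES:
            dexpr = _scale_expression(genes, gene_coords, bacs, scale, config.half_widths)
            repositioning.extend(
                correlate_repositioning(dpos, dexpr, scale=scale, system=system)
            )
    table1 = results_to_frame(repositioning)
    table1.to_csv(outdir / "correlation_repositioning.csv", index=False)

    # Position vs genomic context (2-Mbp core neighborhood)
    feats = features[config.half_widths[0]].rename(columns={"gene_id": "gene_id"})
    context_results = []
    for condition, group in normalized.groupby("condition", sort=True):
        pos_frames = []
        for compartment, col in (("periphery", "norm_per"), ("chromocenter", "norm_cc")):
            means = group.dropna(subset=[col]).groupby("gene_id")[col].mean()
            pos_frames.append(
                pd.DataFrame({"gene_id": means.index, "compartment": compartment,
                              "mean_norm": means.to_numpy()})
            )
        positions = pd.concat(pos_frames, ignore_index=True)
        context_results.extend(
            correlate_position_features(positions, feats, condition=condition)
        )
    table2 = results_to_frame(context_results)
    table2.to_csv(outdir / "correlation_context.csv", index=False)

    RunManifest(outdir, config).record(
        "correlate",
        {"repositioning": outdir / "correlation_repositioning.csv",
         "context": outdir / "correlation_context.csv"},
    )
    return {"repositioning": table1, "context": table2}


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage on a seeded synthetic dataset and emit all reports."""
    outdir = Path(outdir)
    sim = stage_simulate(config, outdir)
    randomness = stage_test_random(config, outdir, normalized=sim["normalized"])
    expr = stage_expression(config, outdir, matrix=sim["dataset"].expression)
    feats = stage_context(config, outdir, genome=sim["genome"])
    tables = stage_correlate(
        config, outdir,
        normalized=sim["normalized"],
        expression_by_pair=expr,
        features=feats,
        genome=sim["genome"],
    )
    return {"simulate": sim, "randomness": randomness, "expression": expr,
            "features": feats, **tables}
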