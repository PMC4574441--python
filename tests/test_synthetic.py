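"""Synthetic-data generator: geometry, bias, expression plants, genome, artifacts."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats as sps

from nucpos.geometry import ChromocenterPlacementError, measure_distances_batch
from nucpos.mcnorm import normalize_distance, sample_background
from nucpos.synthetic import (
    SyntheticConfig,
    generate_expression,
    generate_genome_annotation,
    generate_nuclei,
    make_nucleus,
    place_loci,
    save_dataset,
)

from conftest import make_sphere_nucleus


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"replicates_per_condition": 1},
            {"planted_rho": 1.5},
            {"voxel_size": (0.08, -0.08, 0.2)},
            {"outlier_magnitude_sd": 2.0},
            {"chromocenter_count_range": (5, 2)},
            {"outlier_rate": 1.2},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestGenerateNuclei:
    def test_zero_chromocenter_range_gives_empty_masks(self):
        cfg = SyntheticConfig(rng_seed=2, chromocenter_count_range=(0, 0))
        nucleus, _ = make_nucleus("n0", cfg, np.random.default_rng(2), render=False)
        assert nucleus.n_chromocenters == 0
        assert not (nucleus.chromocenters > 0).any()

    def test_mb_preset_more_and_smaller_than_mt(self):
        cfg = SyntheticConfig(rng_seed=6)
        rng = np.random.default_rng(6)
        stats = {}
        for preset in ("MB", "MT"):
            counts, radii = [], []
            for nucleus, _ in generate_nuclei(cfg, n=4, preset=preset, rng=rng, render=False):
                counts.append(nucleus.n_chromocenters)
                sizes = ndimage.sum_labels(
                    np.ones_like(nucleus.chromocenters), nucleus.chromocenters,
                    index=np.arange(1, nucleus.n_chromocenters + 1),
                )
                vol = sizes * np.prod(nucleus.voxel_size)
                radii.extend((3 * vol / (4 * np.pi)) ** (1 / 3))
            stats[preset] = (np.mean(counts), np.mean(radii))
        assert stats["MB"][0] > stats["MT"][0]   # more chromocenters
        assert stats["MB"][1] < stats["MT"][1]   # smaller radius

    def test_mask_volume_matches_analytic_ellipsoid(self):
        cfg = SyntheticConfig(rng_seed=0, semiaxis_jitter=0.0,
                              nucleus_semiaxes=(5.0, 5.0, 2.5))
        nucleus, _ = make_nucleus("v", cfg, np.random.default_rng(0), render=False)
        analytic = 4 / 3 * np.pi * 5.0 * 5.0 * 2.5
        assert abs(nucleus.volume_um3 - analytic) / analytic < 0.05

    def test_chromocenters_inside_mask_and_disjoint(self):
        cfg = SyntheticConfig(rng_seed=3)
        nucleus, _ = make_nucleus("d", cfg.with_preset("MT"), np.random.default_rng(3),
                                  render=False)
        assert ((nucleus.chromocenters > 0) <= nucleus.mask).all()
        # labels are distinct spheres: count equals number of connected components
        _, n = ndimage.label(nucleus.chromocenters > 0)
        assert n == nucleus.n_chromocenters

    def test_infeasible_placement_names_nucleus(self):
        cfg = SyntheticConfig(rng_seed=1, chromocenter_count_range=(1, 1),
                              chromocenter_radius_range=(2.6, 2.6))
        with pytest.raises(ChromocenterPlacementError, match="cramped"):
            make_nucleus("cramped", cfg, np.random.default_rng(1), render=False)


class TestPlaceLoci:
    def test_nonpositive_count_rejected(self, sphere_nucleus):
        with pytest.raises(ValueError):
            place_loci(sphere_nucleus, n=0, rng_seed=0)

    def test_single_locus_inside_mask(self, sphere_nucleus):
        df = place_loci(sphere_nucleus, n=1, rng_seed=5)
        assert len(df) == 1
        pts = df[["x_um", "y_um", "z_um"]].to_numpy()
        measure_distances_batch(pts, sphere_nucleus)  # raises if outside

    def test_uniform_bias_passes_uniformity_check(self, sphere_nucleus):
        """PIT property: uniform loci have U(0,1) normalized periphery distance."""
        bg = sample_background(sphere_nucleus, n=10_000, rng_seed=9)
        df = place_loci(sphere_nucleus, bias="uniform", n=10_000, rng_seed=10)
        d_per, _ = measure_distances_batch(df[["x_um", "y_um", "z_um"]].to_numpy(),
                                           sphere_nucleus)
        u = normalize_distance(d_per, bg.d_periphery)
        assert sps.kstest(u, "uniform").pvalue > 0.01

    def test_beta_bias_shifts_mean_inward(self, sphere_nucleus):
        bg = sample_background(sphere_nucleus, n=5_000, rng_seed=11)
        df = place_loci(sphere_nucleus, bias=("beta", 5, 1), n=2_000, rng_seed=12)
        d_per, _ = measure_distances_batch(df[["x_um", "y_um", "z_um"]].to_numpy(),
                                           sphere_nucleus)
        u = normalize_distance(d_per, bg.d_periphery)
        assert u.mean() > 0.5  # beta(5,1) mean is 5/6

    def test_beta_bias_recovers_requested_law(self, sphere_nucleus):
        """Normalized ranks track the requested beta law up to inverse-ECDF noise.

        The lookup goes through a finite candidate sample, so the empirical
        CDF deviates from the target by O(1/sqrt(m)); the check bounds the KS
        distance accordingly and pins the first two moments.
        """
        bg = sample_background(sphere_nucleus, n=5_000, rng_seed=13)
        df = place_loci(sphere_nucleus, bias=("beta", 2, 2), n=5_000, rng_seed=14)
        d_per, _ = measure_distances_batch(df[["x_um", "y_um", "z_um"]].to_numpy(),
                                           sphere_nucleus)
        u = normalize_distance(d_per, bg.d_periphery)
        assert sps.kstest(u, sps.beta(2, 2).cdf).statistic < 0.05
        assert u.mean() == pytest.approx(0.5, abs=0.02)
        assert u.std() == pytest.approx(np.sqrt(1 / 20), abs=0.02)

    def test_unknown_bias_rejected(self, sphere_nucleus):
        with pytest.raises(ValueError):
            place_loci(sphere_nucleus, bias=("gamma", 1, 1), n=5, rng_seed=0)


class TestGenerateExpression:
    def test_no_plants_zero_noise_all_unity(self):
        cfg = SyntheticConfig(rng_seed=1, n_genes=4, noise_sd=0.0, outlier_rate=0.0)
        matrix, truth = generate_expression(cfg)
        assert truth.empty
        for cond_a, cond_b in cfg.condition_pairs:
            a = matrix.replicates(cond_a).mean(axis=1)
            b = matrix.replicates(cond_b).mean(axis=1)
            np.testing.assert_allclose(2.0 ** (b - a), 1.0, rtol=1e-12)

    def test_outlier_truth_records_match_matrix(self):
        cfg = SyntheticConfig(rng_seed=5, n_genes=20, outlier_rate=0.3)
        matrix, truth = generate_expression(cfg)
        assert not truth.empty
        for _, row in truth.iterrows():
            reps = matrix.replicates(row["condition"]).loc[row["probe_id"]]
            others = reps.drop(reps.index[int(row["replicate"])])
            # the shifted replicate is far outside the remaining scatter
            assert abs(reps.iloc[int(row["replicate"])] - others.mean()) > 10 * cfg.noise_sd

    def test_replicate_count_enforced(self):
        with pytest.raises(ValueError):
            SyntheticConfig(replicates_per_condition=1)


class TestGenerateGenome:
    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="host"):
            generate_genome_annotation(SyntheticConfig(genome_length=1_000_000,
                                                       block_size=3_000_000))

    def test_bac_lengths_within_band(self):
        cfg = SyntheticConfig(rng_seed=2, genome_length=6_000_000, block_size=1_500_000,
                              n_genes=6)
        genome = generate_genome_annotation(cfg)
        lengths = genome.bacs["end"] - genome.bacs["start"]
        assert lengths.between(150_000, 250_000).all()

    def test_alphabet_is_acgt_only(self):
        cfg = SyntheticConfig(rng_seed=2, genome_length=6_000_000, block_size=3_000_000,
                              n_genes=2)
        genome = generate_genome_annotation(cfg)
        assert set(genome.sequence[:100_000]) <= set("ACGT")

    def test_ridge_gc_exceeds_anti_ridge_gc(self):
        from nucpos.genome import gc_content

        cfg = SyntheticConfig(rng_seed=8, genome_length=6_000_000, block_size=1_500_000,
                              n_genes=2)
        genome = generate_genome_annotation(cfg)
        ridge = genome.blocks.iloc[0]
        anti = genome.blocks.iloc[1]
        assert gc_content(genome.sequence[ridge["start"]:ridge["end"]]) > gc_content(
            genome.sequence[anti["start"]:anti["end"]]
        )


class TestDeterminismAndArtifacts:
    def test_fixed_seed_byte_identical_artifacts(self, tmp_path):
        cfg = SyntheticConfig(rng_seed=42, n_genes=3, n_nuclei=2,
                              genome_length=2_000_000, block_size=1_000_000)

        def build(subdir):
            rng = np.random.default_rng(cfg.rng_seed)
            nuclei = generate_nuclei(cfg, n=2, preset="MB", rng=rng, render=True)
            loci = place_loci(nuclei[0][0], n=20, rng=rng)
            matrix, truth = generate_expression(cfg, np.random.default_rng(cfg.rng_seed))
            genome = generate_genome_annotation(cfg, np.random.default_rng(cfg.rng_seed))
            return save_dataset(tmp_path / subdir, cfg, nuclei, loci,
                                expression=matrix, outlier_truth=truth, genome=genome)

        build("run1")
        build("run2")
        for rel in ("spots.csv", "expression.csv", "genome.fa", "genes.bed",
                    "repeats.bed", "bacs.bed"):
            b1 = (tmp_path / "run1" / rel).read_bytes()
            b2 = (tmp_path / "run2" / rel).read_bytes()
            assert b1 == b2, f"{rel} differs between identically seeded runs"

    def test_manifest_files_exist_and_parse(self, tmp_path):
        from Bio import SeqIO

        from nucpos.genome import read_bed

        cfg = SyntheticConfig(rng_seed=7, n_genes=2, genome_length=2_000_000,
                              block_size=1_000_000)
        rng = np.random.default_rng(7)
        nuclei = generate_nuclei(cfg, n=1, preset="MT", rng=rng, render=True)
        loci = place_loci(nuclei[0][0], n=10, rng=rng)
        matrix, truth = generate_expression(cfg, rng)
        genome = generate_genome_annotation(cfg, rng)
        manifest = save_dataset(tmp_path, cfg, nuclei, loci, expression=matrix,
                                outlier_truth=truth, genome=genome)
        records = list(SeqIO.parse(manifest["files"]["genome"], "fasta"))
        assert len(records) == 1 and len(records[0].seq) == cfg.genome_length
        genes = read_bed(manifest["files"]["genes"])
        assert set(loci["locus_id"]).issubset(
            set(pd.read_csv(manifest["files"]["spots"])["locus_id"])
        )
        assert not genes.empty
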