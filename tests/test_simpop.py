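"""Tests of the RIL/phenotype/bulk/expression simulator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rilmap import simpop


def _uniform_haplotypes(n_snps, chrom="c1"):
    h0 = simpop.Haplotype({chrom: np.zeros(n_snps, dtype=np.uint8)})
    h1 = simpop.Haplotype({chrom: np.ones(n_snps, dtype=np.uint8)})
    return h0, h1


class TestMeiosis:
    def test_zero_genetic_length_returns_parental_haplotype(self, rng):
        genome = simpop.GenomeModel((simpop.ChromSpec("c1", 1_000_000, 0.0),), 100)
        h0, h1 = _uniform_haplotypes(50)
        g = simpop.sample_gamete((h0, h1), genome, rng)
        assert (g.labels["c1"] == 0).all() or (g.labels["c1"] == 1).all()

    def test_homozygous_diplotype_passes_through(self, rng):
        genome = simpop.GenomeModel((simpop.ChromSpec("c1", 1_000_000, 2.0),), 100)
        h0, _ = _uniform_haplotypes(50)
        g = simpop.sample_gamete((h0, h0), genome, rng)
        assert (g.labels["c1"] == 0).all()

    def test_mismatched_panels_rejected(self, rng):
        genome = simpop.GenomeModel((simpop.ChromSpec("c1", 1_000_000, 1.0),), 100)
        h0 = simpop.Haplotype({"c1": np.zeros(50, dtype=np.uint8)})
        h1 = simpop.Haplotype({"c1": np.ones(49, dtype=np.uint8)})
        with pytest.raises(ValueError):
            simpop.sample_gamete((h0, h1), genome, rng)

    def test_crossover_count_is_poisson_with_morgan_mean(self, rng):
        # 1-Morgan chromosome: mean crossover count 1.0 within 3 SE over 1e4
        # meioses, and the full count distribution passes a chi-square GOF.
        L = 1_000_000
        pos = np.sort(rng.integers(1, L, 200))
        counts = []
        for _ in range(10_000):
            lab = simpop._gamete_chrom(
                np.zeros(200, np.uint8), np.ones(200, np.uint8), 1.0, L, pos, rng
            )
            counts.append(int((np.diff(lab) != 0).sum()))
        counts = np.asarray(counts)
        se = 1.0 / np.sqrt(len(counts))
        assert abs(counts.mean() - 1.0) < 3 * se + 0.05
        kmax = 6
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        exp = stats.poisson.pmf(np.arange(kmax), 1.0) * len(counts)
        exp = np.append(exp, len(counts) - exp.sum())
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, df=kmax) > 0.01


class TestRILPopulation:
    def test_f2_heterozygosity_near_half(self, small_genome):
        cfg = simpop.RILSimConfig(n_lines=60, selfing_generations=0)
        gm, truth = simpop.simulate_ril_population(
            cfg, small_genome, np.random.default_rng(1)
        )
        het = np.mean([(truth.calls[c] == simpop.HET).mean() for c in truth.calls])
        assert abs(het - 0.5) < 0.05

    def test_f10_residual_heterozygosity_matches_halving(self, ril_population):
        # (1/2)^(g+1) expected after g selfing rounds beyond the F2
        truth = ril_population["truth"]
        het = np.concatenate(
            [(truth.calls[c] == simpop.HET).ravel() for c in truth.calls]
        )
        expected = 0.5**10
        se = np.sqrt(expected * (1 - expected) / het.size)
        assert abs(het.mean() - expected) < 3 * se + 2e-4
        homo = 1.0 - het.mean()
        assert homo > 0.99

    def test_noiseless_observation_equals_truth(self, small_genome):
        cfg = simpop.RILSimConfig(n_lines=20, selfing_generations=3)
        gm, truth = simpop.simulate_ril_population(
            cfg, small_genome, np.random.default_rng(2)
        )
        for c in gm.calls:
            np.testing.assert_array_equal(gm.calls[c], truth.calls[c])

    def test_seed_determinism(self, small_genome):
        cfg = simpop.RILSimConfig(
            n_lines=10, selfing_generations=2, genotyping_error_rate=0.02,
            missing_rate=0.05, seed=99,
        )
        a, _ = simpop.simulate_ril_population(cfg, small_genome)
        b, _ = simpop.simulate_ril_population(cfg, small_genome)
        for c in a.calls:
            np.testing.assert_array_equal(a.calls[c], b.calls[c])
            np.testing.assert_array_equal(a.positions[c], b.positions[c])

    def test_allele_frequency_conserved_without_selection(self, ril_population):
        truth = ril_population["truth"]
        dos = np.concatenate([truth.calls[c].ravel() for c in truth.calls])
        freq_b = dos.mean() / 2.0
        se = 0.5 / np.sqrt(len(ril_population["truth"].line_names))
        assert abs(freq_b - 0.5) < 3 * se

    def test_crossover_positions_inside_chromosome(self, ril_population):
        truth = ril_population["truth"]
        genome = ril_population["genome"]
        for line in range(len(truth.line_names)):
            for c in genome.chromosomes:
                iv = truth.crossovers[line][c.name]
                if iv.size:
                    assert iv.min() >= 1 and iv.max() <= c.length_bp


class TestPhenotypes:
    def test_zero_heritability_gives_pure_noise(self, ril_population, rng):
        truth = ril_population["truth"]
        genome = ril_population["genome"]
        spec = simpop.QTLSpec("t", ((genome.names[0], 2_500_000),), "additive", (1.0,))
        pheno, _ = simpop.simulate_phenotypes(
            truth, [spec], rng, heritability={"t": 0.0}, replicates=1
        )
        y = pheno["value"].to_numpy()
        x = simpop._dosage_at(truth, genome.names[0], 2_500_000)
        n = len(y)
        assert abs(np.corrcoef(x, y)[0, 1]) < 3 / np.sqrt(n)

    def test_and_epistatic_all_aa_scores_one(self):
        pos = {"c1": np.array([100, 200])}
        calls = {"c1": np.zeros((5, 2), dtype=np.int8)}  # all AA
        truth = simpop.TruthSet(
            [f"L{i}" for i in range(5)], pos, calls, [{"c1": np.empty((0, 2))}] * 5
        )
        spec = simpop.QTLSpec(
            "bin", (("c1", 100), ("c1", 200)), "AND-epistatic-binary"
        )
        pheno, _ = simpop.simulate_phenotypes(
            truth, [spec], np.random.default_rng(0), replicates=1
        )
        assert (pheno["value"] == 1.0).all()

    def test_realized_pve_matches_target(self, ril_population):
        # mean realized R^2 of the causal dosage on y tracks the target PVE
        truth = ril_population["truth"]
        genome = ril_population["genome"]
        rng = np.random.default_rng(11)
        r2 = []
        for _ in range(500):
            ch = genome.names[int(rng.integers(len(genome.names)))]
            p = int(rng.integers(500_000, 4_500_000))
            spec = simpop.QTLSpec("t", ((ch, p),), "additive", (1.0,), 0.3)
            pheno, _ = simpop.simulate_phenotypes(truth, [spec], rng, replicates=1)
            x = simpop._dosage_at(truth, ch, p)
            r2.append(np.corrcoef(x, pheno["value"].to_numpy())[0, 1] ** 2)
        assert abs(np.mean(r2) - 0.30) < 0.02

    def test_replicates_share_genetic_values(self, ril_population, rng):
        truth = ril_population["truth"]
        genome = ril_population["genome"]
        spec = simpop.QTLSpec("t", ((genome.names[0], 2_500_000),), "additive",
                              (1.0,), 0.9)
        pheno, info = simpop.simulate_phenotypes(truth, [spec], rng, replicates=3)
        wide = pheno.pivot_table(index="line", columns="replicate", values="value")
        # high heritability: replicate columns strongly correlated via shared g
        assert wide.corr().to_numpy()[np.triu_indices(3, 1)].min() > 0.6


class TestBulks:
    def test_null_trait_gives_balanced_bulks(self, rng):
        # 12 chromosomes and 50-individual bulks keep the genome-wide bulk
        # B-frequency sd near 0.011, so 0.05 is a wide (>4 sigma) band
        genome = simpop.default_genome(snp_density=20)
        f2 = simpop.simulate_f2(200, genome, rng)
        y = rng.normal(size=200)  # no QTL at all
        counts = simpop.simulate_bsa_bulks(f2, y, simpop.BulkDesign(200, 0.25, 60), rng)
        hi = counts["high_alt"].sum() / (counts["high_alt"] + counts["high_ref"]).sum()
        lo = counts["low_alt"].sum() / (counts["low_alt"] + counts["low_ref"]).sum()
        assert abs(hi - 0.5) < 0.05 and abs(lo - 0.5) < 0.05

    def test_monomorphic_snp_yields_zero_alt(self, rng):
        pos = {"c1": np.array([100, 200, 300])}
        calls = {"c1": np.zeros((40, 3), dtype=np.int8)}  # fixed AA
        truth = simpop.TruthSet(
            [f"L{i}" for i in range(40)], pos, calls,
            [{"c1": np.empty((0, 2))}] * 40,
        )
        counts = simpop.simulate_bsa_bulks(
            truth, rng.normal(size=40), simpop.BulkDesign(40, 0.25, 50), rng
        )
        assert (counts["high_alt"] == 0).all() and (counts["low_alt"] == 0).all()

    def test_strong_qtl_separates_bulk_frequencies(self, rng):
        # exhaustive-count oracle: the bulk allele-frequency difference at the
        # QTL equals the mean dosage difference of the selected individuals
        genome = simpop.default_genome(n_chromosomes=2, snp_density=40)
        f2 = simpop.simulate_f2(220, genome, rng)
        ch, p = genome.names[0], 2_500_000
        spec = simpop.QTLSpec("t", ((ch, p),), "additive", (1.0,), 0.5)
        pheno, _ = simpop.simulate_phenotypes(f2, [spec], rng, replicates=1)
        y = pheno["value"].to_numpy()
        n_bulk = 22
        order = np.argsort(y, kind="stable")
        x = simpop._dosage_at(f2, ch, p)
        expected_diff = (x[order[-n_bulk:]].mean() - x[order[:n_bulk]].mean()) / 2
        assert expected_diff > 0.3
        counts = simpop.simulate_bsa_bulks(f2, y, simpop.BulkDesign(220, 0.1, 200), rng)
        pos = f2.positions[ch]
        j = int(np.argmin(np.abs(pos - p)))
        row = counts[(counts["chrom"] == ch) & (counts["pos"] == pos[j])].iloc[0]
        obs_diff = row["high_alt"] / (row["high_alt"] + row["high_ref"]) - row[
            "low_alt"
        ] / (row["low_alt"] + row["low_ref"])
        assert abs(obs_diff - expected_diff) < 0.15


class TestExpression:
    def test_noiseless_growth_archetype_tracks_growth_rate(self, rng):
        stages = simpop.default_stages()
        gr = np.gradient(simpop.fruit_length_curve(stages), stages)
        expr, labels, _ = simpop.simulate_expression(
            50, stages, gr, rng, archetype_mix={"growth": 1.0}, noise_sigma=0.0
        )
        from rilmap.coexpr import stage_means

        means = stage_means(expr)
        for g in means.index[:10]:
            r = np.corrcoef(means.loc[g].to_numpy(), gr)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_flat_archetype_has_zero_stage_variance(self, rng):
        stages = simpop.default_stages()
        gr = np.gradient(simpop.fruit_length_curve(stages), stages)
        expr, _, _ = simpop.simulate_expression(
            20, stages, gr, rng, archetype_mix={"flat": 1.0}, noise_sigma=0.0
        )
        from rilmap.coexpr import stage_means

        assert stage_means(expr).std(axis=1).max() == pytest.approx(0.0, abs=1e-12)

    def test_rejects_single_stage(self, rng):
        with pytest.raises(ValueError):
            simpop.simulate_expression(10, np.array([5.0]), np.array([1.0]), rng)
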