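"""End-to-end pipeline driver: simulate -> bin map -> GWAS -> network, with
optional BSA and co-expression stages.

One global seed is fanned out to per-stage child generators through
``numpy.random.SeedSequence.spawn`` at fixed offsets, so a config plus seed
fully determines every output byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, binmap, bsa, coexpr, io, simpop, traitnet

logger = logging.getLogger(__name__)

# fixed spawn offsets per stage
_STAGES = ("simulate", "phenotypes", "gwas", "bsa", "coexpr", "network")


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def _genome_from_config(cfg: io.PipelineConfig) -> simpop.GenomeModel:
    return simpop.default_genome(
        cfg.n_chromosomes, cfg.chrom_length_bp, cfg.chrom_morgans, cfg.snp_density
    )


def default_demo_traits(truth: simpop.TruthSet,
                        genome: simpop.GenomeModel) -> list[simpop.QTLSpec]:
    """A compact planted architecture exercising every trait class: a
    pleiotropic locus shared by two fruit traits, a linked second locus,
    an additive pair on separate chromosomes, and a two-locus AND-epistatic
    binary trait."""
    chroms = genome.names
    mid = genome.chromosomes[0].length_bp // 2
    shared = (chroms[0], mid)
    return [
        simpop.QTLSpec("fruit_length", (shared, (chroms[1], mid)),
                       "additive-pair", (1.0, 0.7), 0.5),
        simpop.QTLSpec("fruit_width", (shared,), "pleiotropic", (1.0,), 0.4),
        simpop.QTLSpec("seed_area", ((chroms[2 % len(chroms)], mid),),
                       "additive", (1.0,), 0.3),
        simpop.QTLSpec(
            "pungency",
            ((chroms[0], mid // 2), (chroms[3 % len(chroms)], mid)),
            "AND-epistatic-binary",
        ),
    ]


def run_pipeline(cfg: io.PipelineConfig) -> io.RunManifest:
    """Execute the configured stages and write a run manifest.

    Stage order: simulate (optional) -> binmap -> gwas (per trait) ->
    network; BSA and co-expression run independently when their inputs (or
    the simulation stage) provide data.  Raises on any stage failure with a
    stage-tagged message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = stage_rngs(cfg.seed)
    outputs: dict[str, str] = {}
    skipped: list[str] = []

    def _save(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        outputs[name] = io.file_checksum(path)

    try:
        genome = _genome_from_config(cfg)
        truth = None
        if cfg.genotypes_vcf:
            gm = io.read_genotypes(cfg.genotypes_vcf, cfg.parent_a, cfg.parent_b)
            genome = gm.genome
        elif cfg.simulate:
            sim_cfg = simpop.RILSimConfig(
                n_lines=cfg.n_lines,
                selfing_generations=cfg.selfing_generations,
                genotyping_error_rate=cfg.genotyping_error_rate,
                missing_rate=cfg.missing_rate,
            )
            gm, truth = simpop.simulate_ril_population(sim_cfg, genome, rngs["simulate"])
            _save("genotypes.vcf", io.write_vcf, gm)
            _save("truth_crossovers.tsv", io.write_truth, truth)
        else:
            raise RuntimeError("no genotype source: set genotypes_vcf or simulate")
        cfg.to_yaml(out / "config.yaml", snapshot=True)
        outputs["config.yaml"] = io.file_checksum(out / "config.yaml")
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc

    try:
        pbm, tracks = binmap.build_binmap(
            gm, cfg.window_size, cfg.min_match, cfg.min_bin_length
        )
        stats = binmap.binmap_stats(pbm, tracks)
        _save("binmap.tsv", io.write_binmap, pbm)
        _save("line_bins.tsv",
              lambda tr, p: io.write_line_bins(tr, gm.line_names, p), tracks)
        _save("binmap_per_line.tsv",
              lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.6g"),
              stats.per_line)
        _save("binmap_boundaries.tsv",
              lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.6g"),
              stats.boundaries)
        logger.info("binmap: %d population bins, homozygous fraction %.4f",
                    pbm.n_bins, stats.overall_homozygous_fraction)
    except Exception as exc:
        raise RuntimeError(f"[binmap] {exc}") from exc

    try:
        if cfg.phenotypes_tsv:
            pheno = io.read_phenotypes(cfg.phenotypes_tsv)
        elif truth is not None:
            specs = default_demo_traits(truth, genome)
            pheno, _ = simpop.simulate_phenotypes(truth, specs, rngs["phenotypes"])
            _save("phenotypes.tsv", io.write_phenotypes, pheno)
        else:
            pheno = None
            skipped.append("gwas: no phenotypes")
    except Exception as exc:
        raise RuntimeError(f"[phenotypes] {exc}") from exc

    if pheno is not None and pheno["trait"].nunique() > 1:
        corr = traitnet.trait_correlation_matrix(pheno)
        _save("trait_correlations.tsv",
              lambda df, p: df.to_csv(p, sep="\t", float_format="%.6g"), corr)

    locus_profiles: list[traitnet.TraitProfile] = []
    locus_dosages: dict[str, np.ndarray] = {}
    locus_lead_p: dict[str, dict[str, float]] = {}
    if pheno is not None:
        try:
            dm = assoc.dosage_matrix(pbm)
            K = assoc.kinship_matrix(dm)
            coords, evr = assoc.structure_pca(dm)
            pca_df = pd.DataFrame(
                coords[:, : min(5, coords.shape[1])],
                columns=[f"PC{i+1}" for i in range(min(5, coords.shape[1]))],
            )
            pca_df.insert(0, "line", pbm.line_names)
            _save("pca.tsv",
                  lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.6g"),
                  pca_df)
            traits = list(cfg.traits) or sorted(pheno["trait"].unique())
            all_loci = []
            for trait in traits:
                y = io.trait_vector(pheno, trait, pbm.line_names)
                ok = np.isfinite(y)
                if ok.sum() < 3:
                    skipped.append(f"gwas:{trait}: too few phenotyped lines")
                    continue
                if not ok.all():
                    sub_dm = assoc.DosageMatrix(
                        [n for n, k in zip(dm.line_names, ok) if k],
                        dm.bins, dm.X[ok], dm.testable,
                    )
                    sub_K = K[np.ix_(ok, ok)]
                    rec = assoc.lmm_scan(y[ok], sub_dm, sub_K)
                else:
                    sub_dm, sub_K = dm, K
                    rec = assoc.lmm_scan(y, dm, K)
                threshold = None
                if cfg.threshold_method == "permutation":
                    threshold = assoc.permutation_threshold(
                        y[ok], sub_dm, sub_K, rngs["gwas"], cfg.n_permutations, cfg.alpha
                    )
                loci = assoc.significance_and_loci(
                    rec, threshold, cfg.alpha, cfg.merge_gap
                )
                _save(f"assoc_{trait}.tsv", io.write_assoc, rec)
                fit = assoc.reml_fit(y[ok], sub_K)
                pves = []
                profile = traitnet.TraitProfile(trait)
                for li, row in loci.iterrows():
                    x = sub_dm.X[:, int(row["lead_bin"])]
                    pves.append(assoc.locus_pve(y[ok], x, sub_K, fit))
                    b = pbm.bins.iloc[int(row["lead_bin"])]
                    locus_id = f"{trait[:2].upper()}-{b['chrom']}:{int(row['lead_bin'])}"
                    profile.weights[locus_id] = traitnet.locus_weight(float(row["lead_p"]))
                    locus_dosages[locus_id] = dm.X[:, int(row["lead_bin"])]
                    locus_lead_p.setdefault(trait, {})[locus_id] = float(row["lead_p"])
                loci = loci.copy()
                loci["pve"] = pves
                loci.insert(0, "trait", trait)
                all_loci.append(loci)
                if profile.weights and profile.total_weight() > 0:
                    locus_profiles.append(profile)
            loci_all = (
                pd.concat(all_loci, ignore_index=True)
                if all_loci
                else pd.DataFrame(columns=["trait", "chrom", "start", "end",
                                           "lead_bin", "lead_p", "n_bins",
                                           "threshold", "pve"])
            )
            _save("loci.tsv", io.write_loci, loci_all)
        except Exception as exc:
            raise RuntimeError(f"[gwas] {exc}") from exc

    if cfg.run_bsa and (cfg.bulk_counts_tsv or truth is not None):
        try:
            if cfg.bulk_counts_tsv:
                counts = io.read_bulk_counts(cfg.bulk_counts_tsv)
            else:
                rng = rngs["bsa"]
                f2 = simpop.simulate_f2(220, genome, rng)
                spec = simpop.QTLSpec(
                    "bulked_trait", ((genome.names[0], genome.chromosomes[0].length_bp // 2),),
                    "additive", (1.0,), 0.5,
                )
                ph, _ = simpop.simulate_phenotypes(f2, [spec], rng, replicates=1)
                y = io.trait_vector(ph, "bulked_trait", f2.line_names)
                counts = simpop.simulate_bsa_bulks(
                    f2, y, simpop.BulkDesign(220, 0.1, 60.0), rng
                )
                _save("bulk_counts.tsv", io.write_bulk_counts, counts)
            profile = bsa.snp_index_profile(counts, cfg.bsa_min_depth)
            windowed = bsa.smooth_and_null(
                profile, cfg.bsa_bulk_size, rngs["bsa"],
                cfg.bsa_window_bp, cfg.bsa_step_bp, cfg.bsa_reps,
                {c.name: c.length_bp for c in genome.chromosomes},
            )
            regions = bsa.call_candidate_regions(windowed)
            _save("bsa_snp_index.tsv",
                  lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.6g"),
                  profile)
            _save("bsa_windows.tsv",
                  lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.6g"),
                  windowed.windows)
            _save("bsa_regions.bed",
                  lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.6g"),
                  regions)
        except Exception as exc:
            raise RuntimeError(f"[bsa] {exc}") from exc
    elif cfg.run_bsa:
        skipped.append("bsa: no input")
    else:
        skipped.append("bsa: disabled")

    if cfg.run_coexpr:
        try:
            rng = rngs["coexpr"]
            if cfg.expression_tsv:
                expr = io.read_expression(cfg.expression_tsv)
                growth = pd.read_csv(cfg.growth_tsv, sep="\t") if cfg.growth_tsv else None
                stages = np.array([float(s) for s in
                                   expr.columns.get_level_values("stage").unique()])
                gr = (coexpr.growth_rate_from_lengths(
                        growth["length"].to_numpy(), growth["day"].to_numpy())
                      if growth is not None else None)
            else:
                stages = simpop.default_stages()
                lengths = simpop.fruit_length_curve(stages)
                gr = np.gradient(simpop.fruit_length_curve(stages), stages)
                expr, labels, gr = simpop.simulate_expression(
                    1000, stages, gr, rng
                )
                _save("expression.tsv", io.write_expression, expr)
            clu = coexpr.cluster_trajectories(expr, cfg.k_clusters, seed=cfg.seed)
            if gr is not None:
                clu = coexpr.select_growth_cluster(clu, gr)
            _save("clusters.tsv",
                  lambda s, p: s.rename("cluster").to_csv(p, sep="\t"),
                  clu.assignments)
            _save("centroids.tsv",
                  lambda df, p: df.to_csv(p, sep="\t", float_format="%.6g"),
                  clu.centroids)
        except Exception as exc:
            raise RuntimeError(f"[coexpr] {exc}") from exc
    else:
        skipped.append("coexpr: disabled")

    if len(locus_profiles) >= 1:
        try:
            G, nc_table = traitnet.build_trait_locus_graph(
                locus_profiles, locus_dosages,
                locus_lead_p=locus_lead_p,
                d_prime_threshold=cfg.d_prime_threshold,
                r2_class_cut=cfg.r2_class_cut,
            )
            traitnet.export_graph(
                G, out / "network.graphml",
                out / "network_assoc_edges.tsv", out / "network_ld_edges.tsv",
            )
            for name in ("network.graphml", "network_assoc_edges.tsv",
                         "network_ld_edges.tsv"):
                outputs[name] = io.file_checksum(out / name)
            _save("network_nc.tsv",
                  lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.6g"),
                  nc_table)
        except Exception as exc:
            raise RuntimeError(f"[network] {exc}") from exc
    else:
        skipped.append("network: no significant loci")

    import importlib.metadata as md

    versions = {}
    for pkg in ("numpy", "scipy", "pandas", "scikit-learn", "networkx"):
        try:
            versions[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            pass
    cfg_dict = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(cfg).items()}
    manifest = io.RunManifest(
        config=cfg_dict, seed=cfg.seed, versions=versions,
        outputs=outputs, skipped=skipped,
    )
    manifest.write(out / "manifest.json")
    return manifest
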