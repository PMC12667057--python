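"""Readers, writers and configuration for the pipeline.

Conventions: all genomic coordinates are 1-based inclusive in every file;
tables are tab-separated with a header; p-values are printed in scientific
notation with six significant digits; genotype files are minimal VCF with a
GT-only FORMAT and the two parents as the first two samples.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .simpop import (AA, BB, HET, NA, ChromSpec, GenomeModel, GenotypeMatrix)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(gm: GenotypeMatrix, path, parent_a: str = "parentA",
              parent_b: str = "parentB") -> None:
    """Write genotypes as a minimal GT-only VCF.

    The two (fully homozygous, fully divergent) parents are included as the
    first two samples; offspring calls AA/HET/BB/NA map to 0/0, 0/1, 1/1
    and ./. against the parent-A reference allele.
    """
    path = Path(path)
    gt_map = {AA: "0/0", HET: "0/1", BB: "1/1", NA: "./."}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in gm.genome.chromosomes:
            fh.write(f"##contig=<ID={c.name},length={c.length_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join([parent_a, parent_b] + gm.line_names)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for chrom, pos in gm.positions.items():
            calls = gm.calls[chrom]
            for j, p in enumerate(pos):
                gts = "\t".join(gt_map[int(g)] for g in calls[:, j])
                fh.write(f"{chrom}\t{int(p)}\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1\t{gts}\n")


def read_genotypes(path, parent_a: str, parent_b: str,
                   genome: GenomeModel | None = None) -> GenotypeMatrix:
    """Read a VCF and recode offspring against the two parents.

    Only biallelic sites where the parents are opposite homozygotes are
    kept; offspring genotypes are recoded AA (parent-A homozygote), BB,
    HET or NA.  Dropped-site counts are logged.  If ``genome`` is omitted,
    chromosome lengths are taken from the VCF contig headers (falling back
    to the last observed position).
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    for s in (parent_a, parent_b):
        if s not in samples:
            raise ValueError(f"missing parent sample {s!r} in {path}")
    ia, ib = samples.index(parent_a), samples.index(parent_b)
    offspring = [i for i in range(len(samples)) if i not in (ia, ib)]
    line_names = [samples[i] for i in offspring]

    pos_by_chrom: dict[str, list[int]] = {}
    calls_by_chrom: dict[str, list[np.ndarray]] = {}
    dropped = 0
    kept = 0
    for var in vcf:
        if len(var.ALT) != 1:
            dropped += 1
            continue
        g = np.array([[x[0], x[1]] for x in var.genotypes], dtype=int)
        ga, gb = g[ia], g[ib]
        if -1 in ga or -1 in gb or ga[0] != ga[1] or gb[0] != gb[1] or ga[0] == gb[0]:
            dropped += 1
            continue
        a_allele, b_allele = ga[0], gb[0]
        row = np.full(len(offspring), NA, dtype=np.int8)
        for k, i in enumerate(offspring):
            al = g[i]
            if -1 in al:
                continue
            n_b = int(al[0] == b_allele) + int(al[1] == b_allele)
            n_a = int(al[0] == a_allele) + int(al[1] == a_allele)
            if n_a + n_b < 2:
                continue
            row[k] = (AA, HET, BB)[n_b]
        pos_by_chrom.setdefault(var.CHROM, []).append(var.POS)
        calls_by_chrom.setdefault(var.CHROM, []).append(row)
        kept += 1
    logger.info("read_genotypes: kept %d sites, dropped %d uninformative", kept, dropped)

    header_lengths = {}
    for raw in vcf.raw_header.splitlines():
        if raw.startswith("##contig"):
            body = raw.split("<", 1)[1].rstrip(">")
            kv = dict(item.split("=", 1) for item in body.split(","))
            if "ID" in kv and "length" in kv:
                header_lengths[kv["ID"]] = int(kv["length"])

    positions = {c: np.array(v, dtype=np.int64) for c, v in pos_by_chrom.items()}
    calls = {c: np.vstack(v).T.copy() for c, v in calls_by_chrom.items()}
    # vstack gives sites x lines; transpose to lines x sites
    calls = {c: np.ascontiguousarray(a) for c, a in calls.items()}
    if genome is None:
        chroms = tuple(
            ChromSpec(c, header_lengths.get(c, int(positions[c].max())), 1.0)
            for c in positions
        )
        genome = GenomeModel(chroms, snp_density=1.0)
    return GenotypeMatrix(line_names, genome, positions, calls)


# ---------------------------------------------------------------------------
# tables


def _fmt_p(p: float) -> str:
    return f"{p:.6g}"


def write_truth(truth, path) -> None:
    """Truth-set sidecar: one row per true crossover interval.

    Columns: line, chrom, left, right, mid (bp of the flanking SNPs around
    each junction and the midpoint point estimate).
    """
    rows = []
    for li, name in enumerate(truth.line_names):
        for chrom, iv in truth.crossovers[li].items():
            for left, right in iv:
                rows.append((name, chrom, int(left), int(right),
                             int((left + right) // 2)))
    pd.DataFrame(rows, columns=["line", "chrom", "left", "right", "mid"]).to_csv(
        path, sep="\t", index=False
    )


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    """Long phenotype table: line, trait, replicate, value."""
    pheno.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"line", "trait", "replicate", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(need)}")
    return df


def trait_vector(pheno: pd.DataFrame, trait: str, line_names: list[str]) -> np.ndarray:
    """Per-line phenotype for one trait, averaging replicate columns.

    Lines missing the trait get NaN (callers drop them per trait)."""
    sub = pheno[pheno["trait"] == trait]
    means = sub.groupby("line")["value"].mean()
    return np.array([means.get(name, np.nan) for name in line_names])


def write_bulk_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_bulk_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "pos", "high_ref", "high_alt", "low_ref", "low_alt"}
    if not need.issubset(df.columns):
        raise ValueError(f"bulk count table needs columns {sorted(need)}")
    return df


def write_binmap(pbm, path) -> None:
    """Population bin map as BED-like TSV (1-based inclusive) with one
    genotype column per line."""
    from .simpop import CODE_TO_LABEL

    df = pbm.bins.copy()
    for i, name in enumerate(pbm.line_names):
        df[name] = [CODE_TO_LABEL[int(g)] for g in pbm.table[i]]
    df.to_csv(path, sep="\t", index=False)


def read_binmap(path):
    from .binmap import PopulationBinMap
    from .simpop import LABEL_TO_CODE

    df = pd.read_csv(path, sep="\t", keep_default_na=False)  # "NA" is a genotype
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    line_names = [c for c in df.columns if c not in ("chrom", "start", "end")]
    table = np.array(
        [[LABEL_TO_CODE[v] for v in df[name]] for name in line_names], dtype=np.int8
    )
    bins = df[["chrom", "start", "end"]].copy()
    lengths = bins.groupby("chrom", sort=False)["end"].max().to_dict()
    return PopulationBinMap(line_names, bins, table, {k: int(v) for k, v in lengths.items()})


def write_line_bins(line_tracks, line_names, path) -> None:
    """Per-line recombination bins as BED-like TSV (1-based inclusive)."""
    from .simpop import CODE_TO_LABEL

    rows = []
    for chrom, tracks in line_tracks.items():
        for li, t in enumerate(tracks):
            for start, end, g in t.bins:
                rows.append((line_names[li], chrom, start, end, CODE_TO_LABEL[g]))
    pd.DataFrame(
        rows, columns=["line", "chrom", "start", "end", "genotype"]
    ).to_csv(path, sep="\t", index=False)


def write_assoc(records: pd.DataFrame, path) -> None:
    df = records.copy()
    df["p"] = df["p"].map(_fmt_p)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_loci(loci: pd.DataFrame, path) -> None:
    df = loci.copy()
    for col in ("lead_p", "threshold"):
        if col in df.columns:
            df[col] = df[col].map(_fmt_p)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_expression(expr: pd.DataFrame, path) -> None:
    """Long expression table: gene, stage, replicate, fpkm."""
    long = expr.stack(["stage", "replicate"], future_stack=True).rename("fpkm").reset_index()
    long.columns = ["gene", "stage", "replicate", "fpkm"]
    long.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression(path) -> pd.DataFrame:
    """Read a long expression table into a gene x (stage, replicate) frame."""
    long = pd.read_csv(path, sep="\t", dtype={"stage": str})
    need = {"gene", "stage", "replicate", "fpkm"}
    if not need.issubset(long.columns):
        raise ValueError(f"expression table needs columns {sorted(need)}")
    wide = long.pivot_table(
        index="gene", columns=["stage", "replicate"], values="fpkm", sort=False
    )
    return wide


# ---------------------------------------------------------------------------
# configuration and manifest


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration with module defaults."""

    seed: int = 1
    out_dir: str = "rilmap_out"
    # simulation stage (used when no genotype VCF is supplied)
    simulate: bool = True
    n_lines: int = 216
    selfing_generations: int = 9
    genotyping_error_rate: float = 0.01
    missing_rate: float = 0.05
    n_chromosomes: int = 12
    chrom_length_bp: int = 5_000_000
    chrom_morgans: float = 1.0
    snp_density: float = 200.0
    # external inputs (optional)
    genotypes_vcf: str | None = None
    parent_a: str = "parentA"
    parent_b: str = "parentB"
    phenotypes_tsv: str | None = None
    bulk_counts_tsv: str | None = None
    expression_tsv: str | None = None
    growth_tsv: str | None = None
    tf_annotation_tsv: str | None = None
    # bin map stage
    window_size: int = 15
    min_match: int = 9
    min_bin_length: int = 250_000
    # association stage
    traits: tuple[str, ...] = ()
    threshold_method: str = "bonferroni"
    alpha: float = 0.05
    merge_gap: int = 2_000_000
    n_permutations: int = 200
    # BSA stage
    run_bsa: bool = False
    bsa_window_bp: int = 1_000_000
    bsa_step_bp: int = 100_000
    bsa_reps: int = 500
    bsa_bulk_size: int = 22
    bsa_min_depth: int = 10
    # co-expression stage
    run_coexpr: bool = False
    k_clusters: int = 6
    # network stage
    d_prime_threshold: float = 0.8
    r2_class_cut: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "traits" in raw and raw["traits"] is not None:
            raw["traits"] = tuple(raw["traits"])
        return cls(**raw)

    def to_yaml(self, path, snapshot: bool = False) -> None:
        """Write the config; ``snapshot=True`` omits the run-specific
        output path so identical analyses produce identical snapshots."""
        d = asdict(self)
        d["traits"] = list(d["traits"])
        if snapshot:
            d.pop("out_dir")
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of a pipeline run."""

    config: dict
    seed: int
    versions: dict
    outputs: dict  # relative path -> sha256
    skipped: list

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
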