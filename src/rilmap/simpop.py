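"""Simulation of biparental RIL populations and the data they generate.

The simulator produces, from a configurable genome model, the four kinds of
input the downstream analysis stages consume:

* near-homozygous recombinant inbred lines (RILs) derived from a cross of two
  fully divergent inbred parents by single-seed descent (SSD),
* quantitative and binary phenotypes with planted QTL architectures
  (single additive locus, additive pairs, pleiotropic loci, two-locus
  AND-epistatic binary traits),
* extreme-phenotype F2 bulks with binomial sequencing read depths, and
* stage-wise FPKM expression trajectories correlated (or not) with a fruit
  growth-rate curve.

Meiosis follows a no-interference model: crossover counts per chromosome are
Poisson with mean equal to the genetic length in Morgans and crossover
positions are uniform.  Every operation draws from a caller-supplied
``numpy.random.Generator`` so that identical configuration and seed yield
bit-identical output.

Genotype calls are encoded as small integers throughout the package:
``AA = 0`` (homozygous for parent A), ``HET = 1``, ``BB = 2`` and ``NA = -1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

# Genotype codes shared by the whole package.
AA: int = 0
HET: int = 1
BB: int = 2
NA: int = -1

CODE_TO_LABEL = {AA: "AA", HET: "HET", BB: "BB", NA: "NA"}
LABEL_TO_CODE = {v: k for k, v in CODE_TO_LABEL.items()}


@dataclass(frozen=True)
class ChromSpec:
    """One chromosome: physical length in bp and genetic length in Morgans."""

    name: str
    length_bp: int
    morgans: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: length_bp must be > 0")
        if self.morgans < 0:
            raise ValueError(f"chromosome {self.name}: morgans must be >= 0")


@dataclass(frozen=True)
class GenomeModel:
    """A genome as a list of chromosomes plus an expected SNP density.

    Parameters
    ----------
    chromosomes
        Physical and genetic lengths per chromosome.
    snp_density
        Expected number of parent-discriminating SNPs per Mb.
    """

    chromosomes: tuple[ChromSpec, ...]
    snp_density: float = 200.0

    def __post_init__(self) -> None:
        if len(self.chromosomes) < 1:
            raise ValueError("genome needs at least one chromosome")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be > 0")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom(self, name: str) -> ChromSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)


def default_genome(
    n_chromosomes: int = 12,
    length_bp: int = 5_000_000,
    morgans: float = 1.0,
    snp_density: float = 200.0,
) -> GenomeModel:
    """Desk-scale stand-in for a 12-chromosome pepper genome."""
    chroms = tuple(
        ChromSpec(f"chr{i + 1:02d}", length_bp, morgans) for i in range(n_chromosomes)
    )
    return GenomeModel(chroms, snp_density)


@dataclass
class Haplotype:
    """Parental-origin labels (0 = parent A, 1 = parent B) at each SNP."""

    labels: dict[str, np.ndarray]

    def chrom_names(self) -> list[str]:
        return list(self.labels)


@dataclass
class GenotypeMatrix:
    """Lines x SNPs genotype calls, stored per chromosome.

    ``calls[chrom]`` is an ``(n_lines, n_snps)`` int8 array with codes
    AA/HET/BB/NA; ``positions[chrom]`` holds the matching 1-based bp
    positions, sorted ascending.
    """

    line_names: list[str]
    genome: GenomeModel
    positions: dict[str, np.ndarray]
    calls: dict[str, np.ndarray]

    @property
    def n_lines(self) -> int:
        return len(self.line_names)

    @property
    def n_snps(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def heterozygous_fraction(self) -> float:
        """SNP-wise heterozygous fraction over non-missing calls."""
        het = 0
        tot = 0
        for arr in self.calls.values():
            het += int((arr == HET).sum())
            tot += int((arr != NA).sum())
        return het / tot if tot else float("nan")


@dataclass
class TruthSet:
    """Ground truth retained from a simulation for recovery experiments.

    ``crossovers[line][chrom]`` is an ``(k, 2)`` array of (left_bp, right_bp)
    flanking-SNP intervals bracketing each true junction (a genotype change
    point in the final line); midpoints are the point estimates.  ``calls``
    mirrors :class:`GenotypeMatrix` but without genotyping error or
    missingness.
    """

    line_names: list[str]
    positions: dict[str, np.ndarray]
    calls: dict[str, np.ndarray]
    crossovers: list[dict[str, np.ndarray]]
    qtls: list["QTLSpec"] = field(default_factory=list)

    def crossover_midpoints(self, line: int, chrom: str) -> np.ndarray:
        iv = self.crossovers[line][chrom]
        if iv.size == 0:
            return np.empty(0)
        return iv.mean(axis=1)


@dataclass(frozen=True)
class RILSimConfig:
    """Configuration of the SSD population simulation.

    ``selfing_generations`` counts selfing rounds after the F2 (the F2 itself
    is one selfing of the F1), so the default of 9 produces lines with
    expected residual heterozygosity (1/2)^10, matching an F10 SSD
    population.
    """

    n_lines: int = 216
    selfing_generations: int = 9
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        for name in ("genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass(frozen=True)
class QTLSpec:
    """A planted trait architecture.

    ``architecture`` is one of ``additive`` (any number of placements),
    ``additive-pair`` (two additive loci), ``pleiotropic`` (an additive locus
    shared with another trait; the sharing is expressed by reusing the same
    placement in two specs) or ``AND-epistatic-binary`` (trait is 1 iff both
    placements are homozygous for the A parent).
    """

    trait: str
    placements: tuple[tuple[str, int], ...]
    architecture: str = "additive"
    effects: tuple[float, ...] = ()
    target_pve: float = 0.3

    def __post_init__(self) -> None:
        archs = {"additive", "additive-pair", "pleiotropic", "AND-epistatic-binary"}
        if self.architecture not in archs:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "AND-epistatic-binary":
            if len(self.placements) != 2:
                raise ValueError("AND-epistatic-binary requires exactly 2 placements")
        elif not (0.0 < self.target_pve < 1.0):
            raise ValueError("target_pve must be in (0, 1) for quantitative traits")
        if self.architecture == "additive-pair" and len(self.placements) != 2:
            raise ValueError("additive-pair requires exactly 2 placements")
        if self.effects and len(self.effects) != len(self.placements):
            raise ValueError("effects must match placements")


@dataclass(frozen=True)
class BulkDesign:
    """Design of an extreme-phenotype F2 bulked-segregant experiment."""

    f2_size: int = 220
    bulk_fraction: float = 0.1
    mean_depth: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 < self.bulk_fraction <= 0.5):
            raise ValueError("bulk_fraction must be in (0, 0.5]")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if self.f2_size < 2:
            raise ValueError("f2_size must be >= 2")


# ---------------------------------------------------------------------------
# meiosis


def sample_snp_positions(genome: GenomeModel, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw sorted, unique, 1-based SNP positions per chromosome."""
    out: dict[str, np.ndarray] = {}
    for c in genome.chromosomes:
        n = int(round(genome.snp_density * c.length_bp / 1e6))
        n = max(n, 1)
        pos = np.unique((rng.random(n) * c.length_bp).astype(np.int64) + 1)
        while len(pos) < n:  # collisions are rare at desk densities
            extra = (rng.random(n - len(pos)) * c.length_bp).astype(np.int64) + 1
            pos = np.unique(np.concatenate([pos, extra]))
        out[c.name] = pos[:n] if len(pos) > n else pos
    return out


def _gamete_chrom(
    hap0: np.ndarray,
    hap1: np.ndarray,
    morgans: float,
    length_bp: int,
    snp_pos: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product for one chromosome (Poisson crossovers, no
    interference); starting phase is a fair coin."""
    start = int(rng.integers(2))
    k = int(rng.poisson(morgans)) if morgans > 0 else 0
    if k == 0:
        return hap0.copy() if start == 0 else hap1.copy()
    xo = np.sort(rng.uniform(0.0, float(length_bp), size=k))
    phase = (start + np.searchsorted(xo, snp_pos.astype(np.float64))) % 2
    return np.where(phase == 0, hap0, hap1).astype(np.uint8)


def sample_gamete(
    diplotype: tuple[Haplotype, Haplotype],
    genome: GenomeModel,
    rng: np.random.Generator,
    snp_positions: dict[str, np.ndarray] | None = None,
) -> Haplotype:
    """Sample one gamete from a diplotype.

    Raises ``ValueError`` if the two haplotypes do not cover identical SNP
    panels.
    """
    h0, h1 = diplotype
    if set(h0.labels) != set(h1.labels):
        raise ValueError("mismatched SNP panels between the two haplotypes")
    labels: dict[str, np.ndarray] = {}
    for c in genome.chromosomes:
        if c.name not in h0.labels:
            continue
        a, b = h0.labels[c.name], h1.labels[c.name]
        if a.shape != b.shape:
            raise ValueError("mismatched SNP panels between the two haplotypes")
        if snp_positions is not None:
            pos = snp_positions[c.name]
        else:
            # positions only matter relative to crossovers; assume uniform grid
            pos = np.linspace(1, c.length_bp, num=len(a)).astype(np.int64)
        labels[c.name] = _gamete_chrom(a, b, c.morgans, c.length_bp, pos, rng)
    return Haplotype(labels)


# ---------------------------------------------------------------------------
# population simulation


def _true_crossover_intervals(
    geno: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    """Flanking-SNP intervals around genotype change points of one line."""
    if len(geno) < 2:
        return np.empty((0, 2), dtype=np.int64)
    change = np.nonzero(np.diff(geno) != 0)[0]
    if change.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.column_stack([pos[change], pos[change + 1]]).astype(np.int64)


def simulate_ril_population(
    config: RILSimConfig,
    genome: GenomeModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate an SSD RIL population from two fully divergent parents.

    The F1 is heterozygous A/B genome-wide; each line is founded by selfing
    the F1 once (giving its F2 individual) and then advanced by
    ``config.selfing_generations`` further rounds of single-seed descent.
    The observed matrix is the truth perturbed by a symmetric genotyping
    error (a wrong call is one of the two other states with equal
    probability) and by missingness.

    Returns the observed :class:`GenotypeMatrix` (with parents attached as
    attributes in the VCF writer, not here) and the unperturbed
    :class:`TruthSet`.
    """
    if genome is None:
        genome = default_genome()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions = sample_snp_positions(genome, rng)

    n = config.n_lines
    true_calls: dict[str, np.ndarray] = {
        c.name: np.empty((n, len(positions[c.name])), dtype=np.int8)
        for c in genome.chromosomes
    }
    crossovers: list[dict[str, np.ndarray]] = []
    for i in range(n):
        # diplotype per chromosome, uint8 labels
        dip = {
            c.name: (
                np.zeros(len(positions[c.name]), dtype=np.uint8),
                np.ones(len(positions[c.name]), dtype=np.uint8),
            )
            for c in genome.chromosomes
        }
        for _ in range(config.selfing_generations + 1):  # F1->F2, then SSD
            new = {}
            for c in genome.chromosomes:
                h0, h1 = dip[c.name]
                pos = positions[c.name]
                g0 = _gamete_chrom(h0, h1, c.morgans, c.length_bp, pos, rng)
                g1 = _gamete_chrom(h0, h1, c.morgans, c.length_bp, pos, rng)
                new[c.name] = (g0, g1)
            dip = new
        line_xo: dict[str, np.ndarray] = {}
        for c in genome.chromosomes:
            h0, h1 = dip[c.name]
            g = (h0.astype(np.int8) + h1.astype(np.int8))  # 0=AA,1=HET,2=BB
            true_calls[c.name][i] = g
            line_xo[c.name] = _true_crossover_intervals(g, positions[c.name])
        crossovers.append(line_xo)

    line_names = [f"RIL{i + 1:03d}" for i in range(n)]
    truth = TruthSet(
        line_names=line_names,
        positions={k: v.copy() for k, v in positions.items()},
        calls={k: v.copy() for k, v in true_calls.items()},
        crossovers=crossovers,
    )

    observed: dict[str, np.ndarray] = {}
    e, m = config.genotyping_error_rate, config.missing_rate
    for c in genome.chromosomes:
        arr = true_calls[c.name].copy()
        if e > 0:
            flip = rng.random(arr.shape) < e
            # symmetric flip: add 1 or 2 (mod 3) to move to another state
            shift = rng.integers(1, 3, size=arr.shape).astype(np.int8)
            arr = np.where(flip, (arr + shift) % 3, arr).astype(np.int8)
        if m > 0:
            arr = np.where(rng.random(arr.shape) < m, np.int8(NA), arr)
        observed[c.name] = arr

    gm = GenotypeMatrix(line_names, genome, positions, observed)
    return gm, truth


# ---------------------------------------------------------------------------
# phenotypes


def _dosage_at(truth: TruthSet, chrom: str, pos_bp: int) -> np.ndarray:
    """True B-allele dosage (0/1/2) per line at the SNP nearest pos_bp."""
    if chrom not in truth.positions:
        raise ValueError(f"QTL placement on unknown chromosome {chrom!r}")
    pos = truth.positions[chrom]
    j = int(np.argmin(np.abs(pos.astype(np.int64) - int(pos_bp))))
    return truth.calls[chrom][:, j].astype(np.float64)


def simulate_phenotypes(
    truth: TruthSet,
    specs: Sequence[QTLSpec],
    rng: np.random.Generator,
    heritability: dict[str, float] | None = None,
    replicates: int = 2,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Simulate phenotypes for planted QTL architectures.

    A quantitative trait is ``y = sum_q a_q x_q + eps`` with ``x_q`` the
    0/1/2 B-allele dosage at each placement and the noise variance scaled so
    the genetic fraction of the phenotypic variance equals the trait's target
    PVE (``heritability`` overrides per trait; 0 gives pure noise).  An
    AND-epistatic binary trait is 1 iff the line is homozygous AA at both
    placements; replicates repeat the same value.  Replicate columns share
    genetic values and draw independent noise.

    Returns a long table (line, trait, replicate, value) and a per-trait
    truth dict with placements, effects and per-line genetic values.
    """
    heritability = heritability or {}
    rows = []
    info: dict[str, dict] = {}
    n = len(truth.line_names)
    for spec in specs:
        dosages = [_dosage_at(truth, c, p) for c, p in spec.placements]
        if spec.architecture == "AND-epistatic-binary":
            val = np.ones(n)
            for x in dosages:
                val = val * (x == 0)  # homozygous for the A parent
            g = val.astype(np.float64)
            for r in range(replicates):
                for i, name in enumerate(truth.line_names):
                    rows.append((name, spec.trait, r + 1, float(g[i])))
            info[spec.trait] = {
                "placements": spec.placements,
                "effects": None,
                "genetic": g,
            }
            continue
        effects = np.asarray(spec.effects if spec.effects else [1.0] * len(dosages))
        g = np.zeros(n)
        for a, x in zip(effects, dosages):
            g += a * x
        h2 = heritability.get(spec.trait, spec.target_pve)
        var_g = float(np.var(g))
        if h2 <= 0 or var_g == 0:
            g = np.zeros(n)
            sd_e = 1.0
        elif h2 >= 1:
            raise ValueError("target_pve / heritability must be < 1")
        else:
            sd_e = float(np.sqrt(var_g * (1 - h2) / h2))
        for r in range(replicates):
            eps = rng.normal(0.0, sd_e, size=n) if sd_e > 0 else np.zeros(n)
            y = g + eps
            for i, name in enumerate(truth.line_names):
                rows.append((name, spec.trait, r + 1, float(y[i])))
        info[spec.trait] = {
            "placements": spec.placements,
            "effects": effects,
            "genetic": g,
            "noise_sd": sd_e,
        }
    df = pd.DataFrame(rows, columns=["line", "trait", "replicate", "value"])
    return df, info


# ---------------------------------------------------------------------------
# BSA bulks


def simulate_bsa_bulks(
    truth: TruthSet,
    phenotype: np.ndarray,
    design: BulkDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Form extreme bulks from an F2 population and draw sequencing depths.

    ``truth`` holds the (noise-free) F2 genotypes; ``phenotype`` is one value
    per individual.  The top and bottom ``bulk_fraction`` of individuals form
    the high and low bulks.  At each SNP the per-bulk B-allele frequency is
    the mean B dosage / 2 over bulk members; total depth is
    Poisson(mean_depth) and the B-allele (alt) read count is
    Binomial(depth, frequency).

    Returns a tidy table: chrom, pos, high_ref, high_alt, low_ref, low_alt.
    """
    n = len(phenotype)
    if n != len(truth.line_names):
        raise ValueError("phenotype length must match population size")
    n_bulk = max(1, int(round(design.bulk_fraction * n)))
    order = np.argsort(phenotype, kind="stable")
    low_idx = order[:n_bulk]
    high_idx = order[-n_bulk:]
    if len(low_idx) == 0 or len(high_idx) == 0:
        raise ValueError("empty bulks")

    frames = []
    for chrom, pos in truth.positions.items():
        calls = truth.calls[chrom]
        freq_hi = calls[high_idx].mean(axis=0) / 2.0
        freq_lo = calls[low_idx].mean(axis=0) / 2.0
        depth_hi = rng.poisson(design.mean_depth, size=len(pos))
        depth_lo = rng.poisson(design.mean_depth, size=len(pos))
        alt_hi = rng.binomial(depth_hi, freq_hi)
        alt_lo = rng.binomial(depth_lo, freq_lo)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "high_ref": depth_hi - alt_hi,
                    "high_alt": alt_hi,
                    "low_ref": depth_lo - alt_lo,
                    "low_alt": alt_lo,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_f2(
    n_individuals: int,
    genome: GenomeModel | None = None,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Convenience: a noise-free F2 population (one selfing of the F1)."""
    cfg = RILSimConfig(n_lines=n_individuals, selfing_generations=0)
    _, truth = simulate_ril_population(cfg, genome, rng)
    return truth


# ---------------------------------------------------------------------------
# expression


ARCHETYPES = ("growth", "flat", "declining", "late")


def fruit_length_curve(days: np.ndarray, l_max: float = 20.0, k: float = 0.25,
                       t_mid: float = 18.0) -> np.ndarray:
    """Logistic fruit-length curve (cm) over days after anthesis."""
    days = np.asarray(days, dtype=float)
    return l_max / (1.0 + np.exp(-k * (days - t_mid)))


def default_stages() -> np.ndarray:
    """Five pericarp sampling stages (days after anthesis)."""
    return np.array([5.0, 12.0, 19.0, 26.0, 33.0])


def _archetype_shapes(stages: np.ndarray, growth_rate: np.ndarray) -> dict[str, np.ndarray]:
    s = np.asarray(stages, dtype=float)
    gr = np.asarray(growth_rate, dtype=float)
    rng_span = gr.max() - gr.min()
    if rng_span == 0:
        track = np.ones_like(gr)
    else:
        track = 0.2 + 0.8 * (gr - gr.min()) / rng_span  # affine in growth rate
    t01 = (s - s.min()) / (s.max() - s.min())
    return {
        "growth": track,
        "flat": np.ones_like(s),
        "declining": 1.0 - 0.9 * t01,
        "late": 0.05 + 0.95 * t01**3,
    }


def simulate_expression(
    n_genes: int,
    stages: np.ndarray,
    growth_rate: np.ndarray,
    rng: np.random.Generator,
    archetype_mix: dict[str, float] | None = None,
    n_replicates: int = 3,
    noise_sigma: float = 0.2,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Simulate stage-wise FPKM trajectories with known archetype labels.

    Each gene is assigned an archetype (growth-tracking, flat, declining or
    late-peaking); its FPKM trajectory is the archetype shape scaled by a
    gene-specific log-normal abundance and multiplied by per-observation
    log-normal noise (``exp(noise_sigma * N(0,1))``).

    Returns (expression, labels, growth_rate): expression has genes as the
    index and a (stage, replicate) MultiIndex on the columns.
    """
    stages = np.asarray(stages, dtype=float)
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    growth_rate = np.asarray(growth_rate, dtype=float)
    if len(growth_rate) != len(stages):
        raise ValueError("growth_rate must have one value per stage")
    mix = archetype_mix or {"growth": 0.3, "flat": 0.3, "declining": 0.2, "late": 0.2}
    names = [a for a in ARCHETYPES if mix.get(a, 0) > 0]
    probs = np.array([mix[a] for a in names], dtype=float)
    probs = probs / probs.sum()
    shapes = _archetype_shapes(stages, growth_rate)

    labels = pd.Series(
        np.array(names)[rng.choice(len(names), size=n_genes, p=probs)],
        index=[f"gene{i + 1:05d}" for i in range(n_genes)],
        name="archetype",
    )
    scale = rng.lognormal(mean=2.0, sigma=1.0, size=n_genes)
    cols = pd.MultiIndex.from_product(
        [[f"{d:g}" for d in stages], [f"rep{r + 1}" for r in range(n_replicates)]],
        names=["stage", "replicate"],
    )
    out = np.empty((n_genes, len(stages) * n_replicates))
    for gi in range(n_genes):
        base = shapes[labels.iloc[gi]] * scale[gi]
        traj = np.repeat(base, n_replicates)
        if noise_sigma > 0:
            traj = traj * np.exp(noise_sigma * rng.normal(size=traj.size))
        out[gi] = traj
    expr = pd.DataFrame(out, index=labels.index, columns=cols)
    return expr, labels, growth_rate
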