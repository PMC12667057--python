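"""Recombination-bin construction from dense RIL genotypes.

The caller slides a 15-SNP window one SNP at a time along each line's
genotype track and assigns the window the parental state (AA, BB or HET)
reached by at least 9 of the 15 SNPs; windows where no state reaches the
majority are "unavailable".  Window calls are projected back onto SNPs by a
majority vote over the covering windows, maximal runs of identical SNP calls
become recombination bins, and bins spanning fewer than 250 kb are discarded
(their span becomes missing rather than being merged into a neighbour).
Breakpoint intervals — the uninformative gaps between consecutive runs — are
pooled over lines; their midpoints partition each chromosome into the
population bins that serve as association markers.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simpop import AA, BB, HET, NA, GenomeModel, GenotypeMatrix

logger = logging.getLogger(__name__)

UNAVAILABLE: int = -2  # window with no majority state

DEFAULT_WINDOW_SIZE = 15
DEFAULT_MIN_MATCH = 9
DEFAULT_MIN_BIN_LENGTH = 250_000


def call_windows(
    calls: np.ndarray,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_match: int = DEFAULT_MIN_MATCH,
) -> np.ndarray:
    """Sliding-window genotype calls for one chromosome.

    ``calls`` is ``(n_snps,)`` or ``(n_lines, n_snps)`` with codes
    AA/HET/BB/NA, ordered by position.  Each window of ``window_size``
    consecutive SNPs is called as the state attained by at least
    ``min_match`` of its SNPs; missing SNPs count toward the window size but
    match no state.  Windows without a majority state are ``UNAVAILABLE``.
    A chromosome with fewer SNPs than ``window_size`` yields zero windows.
    """
    if min_match > window_size or min_match < window_size // 2 + 1:
        raise ValueError("require window_size >= min_match >= window_size//2 + 1")
    arr = np.atleast_2d(np.asarray(calls, dtype=np.int8))
    n_lines, n_snps = arr.shape
    n_win = n_snps - window_size + 1
    if n_win <= 0:
        logger.debug("chromosome with %d SNPs < window %d: no windows", n_snps, window_size)
        out = np.empty((n_lines, 0), dtype=np.int8)
        return out[0] if np.asarray(calls).ndim == 1 else out

    out = np.full((n_lines, n_win), UNAVAILABLE, dtype=np.int8)
    for state in (AA, HET, BB):
        one = (arr == state).astype(np.int32)
        csum = np.cumsum(one, axis=1)
        wc = csum[:, window_size - 1 :].copy()
        wc[:, 1:] -= csum[:, : n_win - 1]
        # min_match > window_size/2 guarantees at most one state qualifies
        out[wc >= min_match] = state
    return out[0] if np.asarray(calls).ndim == 1 else out


def project_snp_calls(
    window_calls: np.ndarray, n_snps: int, window_size: int = DEFAULT_WINDOW_SIZE
) -> np.ndarray:
    """Per-SNP consensus genotype from the windows covering each SNP.

    Each SNP takes the strict-majority state among its covering windows'
    called states (unavailable windows carry no state); ties or no covering
    called window give NA.
    """
    wc = np.atleast_2d(np.asarray(window_calls, dtype=np.int8))
    n_lines, n_win = wc.shape
    if n_win == 0:
        out = np.full((n_lines, n_snps), NA, dtype=np.int8)
        return out[0] if np.asarray(window_calls).ndim == 1 else out
    idx = np.arange(n_snps)
    lo = np.clip(idx - window_size + 1, 0, n_win - 1)  # first covering window
    hi = np.clip(idx, 0, n_win - 1)  # last covering window
    counts = np.empty((3, n_lines, n_snps), dtype=np.int32)
    for state in (AA, HET, BB):
        one = (wc == state).astype(np.int32)
        csum = np.concatenate(
            [np.zeros((n_lines, 1), dtype=np.int32), np.cumsum(one, axis=1)], axis=1
        )
        counts[state] = csum[:, hi + 1] - csum[:, lo]
    best = counts.max(axis=0)
    argbest = counts.argmax(axis=0)
    n_best = (counts == best[None, :, :]).sum(axis=0)
    out = np.where((best > 0) & (n_best == 1), argbest, NA).astype(np.int8)
    return out[0] if np.asarray(window_calls).ndim == 1 else out


@dataclass
class LineBinTrack:
    """Bins and breakpoint intervals of a single line on one chromosome."""

    bins: list[tuple[int, int, int]]  # (start, end, genotype), retained only
    breakpoints: list[tuple[int, int]]  # open intervals between adjacent runs


def build_line_bins(
    snp_calls: np.ndarray,
    positions: np.ndarray,
    min_bin_length: int = DEFAULT_MIN_BIN_LENGTH,
) -> LineBinTrack:
    """Turn one line's per-SNP consensus calls into recombination bins.

    Missing SNPs are transparent: runs are maximal stretches of identical
    non-missing calls.  Each run spans first-to-last SNP (inclusive; length
    = end - start + 1).  The open interval between consecutive runs is a
    breakpoint interval and belongs to no bin.  Runs spanning less than
    ``min_bin_length`` bp are dropped from the bin list (span becomes
    missing); a span of exactly ``min_bin_length`` is retained.  Breakpoint
    intervals are recorded between runs before the length filter, since each
    run boundary marks an inferred crossover whether or not the short run
    survives the filter.
    """
    positions = np.asarray(positions)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    keep = snp_calls != NA
    calls = np.asarray(snp_calls)[keep]
    pos = positions[keep]
    if calls.size == 0:
        return LineBinTrack([], [])
    change = np.nonzero(np.diff(calls) != 0)[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [calls.size - 1]])
    bins: list[tuple[int, int, int]] = []
    breakpoints: list[tuple[int, int]] = []
    for k, (s, e) in enumerate(zip(starts, ends)):
        b_start, b_end = int(pos[s]), int(pos[e])
        if k > 0:
            breakpoints.append((int(pos[starts[k] - 1]), b_start))
        if b_end - b_start + 1 >= min_bin_length:
            bins.append((b_start, b_end, int(calls[s])))
    return LineBinTrack(bins, breakpoints)


@dataclass
class PopulationBinMap:
    """Population bins (a chromosome partition) and the lines x bins table.

    ``bins`` has columns chrom/start/end (1-based inclusive, tiling each
    chromosome); ``table`` is ``(n_lines, n_bins)`` int8 AA/HET/BB/NA.
    """

    line_names: list[str]
    bins: pd.DataFrame
    table: np.ndarray
    chrom_lengths: dict[str, int]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def lengths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"] + 1).to_numpy()


def _line_tracks(
    gm: GenotypeMatrix,
    window_size: int,
    min_match: int,
    min_bin_length: int,
) -> dict[str, list[LineBinTrack]]:
    """Per-chromosome list (over lines) of line bin tracks."""
    tracks: dict[str, list[LineBinTrack]] = {}
    for chrom, pos in gm.positions.items():
        wc = call_windows(gm.calls[chrom], window_size, min_match)
        snp_calls = project_snp_calls(wc, len(pos), window_size)
        tracks[chrom] = [
            build_line_bins(snp_calls[i], pos, min_bin_length)
            for i in range(gm.n_lines)
        ]
    return tracks


def build_population_binmap(
    line_tracks: dict[str, list[LineBinTrack]],
    line_names: list[str],
    chrom_lengths: dict[str, int],
) -> PopulationBinMap:
    """Integrate line-level bins into the population bin map.

    Breakpoint-interval midpoints pooled over lines cut each chromosome into
    population bins.  A line's genotype in a population bin is the unique
    genotype among its (retained) bins overlapping it; no overlap or mixed
    genotypes give NA.
    """
    if not line_names:
        raise ValueError("need at least one line")
    n_lines = len(line_names)
    bin_rows = []
    cols: list[np.ndarray] = []
    for chrom, tracks in line_tracks.items():
        length = chrom_lengths[chrom]
        mids = sorted(
            {
                int((left + right) // 2)
                for t in tracks
                for (left, right) in t.breakpoints
                if 1 <= (left + right) // 2 < length
            }
        )
        cuts = np.array(mids, dtype=np.int64)
        starts = np.concatenate([[1], cuts + 1])
        ends = np.concatenate([cuts, [length]])
        geno = np.full((n_lines, len(starts)), NA, dtype=np.int8)
        for li, t in enumerate(tracks):
            if not t.bins:
                continue
            covered = np.full(len(starts), NA, dtype=np.int16)
            mixed = np.zeros(len(starts), dtype=bool)
            for (bs, be, g) in t.bins:
                # population bins overlapping [bs, be]
                j0 = int(np.searchsorted(ends, bs))
                j1 = int(np.searchsorted(starts, be, side="right") - 1)
                for j in range(j0, j1 + 1):
                    if covered[j] == NA:
                        covered[j] = g
                    elif covered[j] != g:
                        mixed[j] = True
            covered[mixed] = NA
            geno[li] = covered.astype(np.int8)
        for s, e in zip(starts, ends):
            bin_rows.append((chrom, int(s), int(e)))
        cols.append(geno)
    bins = pd.DataFrame(bin_rows, columns=["chrom", "start", "end"])
    table = np.concatenate(cols, axis=1) if cols else np.empty((n_lines, 0), np.int8)
    return PopulationBinMap(line_names, bins, table, dict(chrom_lengths))


def build_binmap(
    gm: GenotypeMatrix,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_match: int = DEFAULT_MIN_MATCH,
    min_bin_length: int = DEFAULT_MIN_BIN_LENGTH,
) -> tuple[PopulationBinMap, dict[str, list[LineBinTrack]]]:
    """Full pipeline: windows -> SNP consensus -> line bins -> population map."""
    tracks = _line_tracks(gm, window_size, min_match, min_bin_length)
    lengths = {c.name: c.length_bp for c in gm.genome.chromosomes}
    pbm = build_population_binmap(tracks, gm.line_names, lengths)
    return pbm, tracks


@dataclass
class BinMapStats:
    """Summary statistics of a population bin map."""

    per_line: pd.DataFrame  # line, homozygous_fraction, breakpoints, frac_AA/BB/HET/NA
    boundaries: pd.DataFrame  # chrom, boundary_bp, recombination_frequency
    overall_homozygous_fraction: float
    n_population_bins: int
    n_line_bins: int


def binmap_stats(
    pbm: PopulationBinMap,
    line_tracks: dict[str, list[LineBinTrack]] | None = None,
) -> BinMapStats:
    """bp-weighted genotype composition, breakpoint counts and per-boundary
    recombination frequencies.

    The homozygous fraction is computed over the non-NA genome; the per-line
    AA/BB/HET/NA fractions are of the whole genome and sum to 1.  The
    recombination frequency at a population-bin boundary is the fraction of
    lines, non-NA on both sides, whose genotype differs across it.
    """
    if pbm.n_bins == 0:
        raise ValueError("empty bin map")
    L = pbm.lengths().astype(np.float64)
    tab = pbm.table
    total = L.sum()
    homo = ((tab == AA) | (tab == BB)) @ L
    het = (tab == HET) @ L
    na = (tab == NA) @ L
    aa = (tab == AA) @ L
    bb = (tab == BB) @ L
    non_na = total - na

    # per-line breakpoint count: genotype changes between consecutive non-NA
    # bins within each chromosome
    n_lines = tab.shape[0]
    bp_count = np.zeros(n_lines, dtype=int)
    chroms = pbm.bins["chrom"].to_numpy()
    boundary_rows = []
    for chrom in pbm.bins["chrom"].unique():
        sel = np.nonzero(chroms == chrom)[0]
        sub = tab[:, sel]
        ends = pbm.bins["end"].to_numpy()[sel]
        for li in range(n_lines):
            row = sub[li]
            r = row[row != NA]
            if r.size > 1:
                bp_count[li] += int((np.diff(r) != 0).sum())
        for j in range(sub.shape[1] - 1):
            left, right = sub[:, j], sub[:, j + 1]
            ok = (left != NA) & (right != NA)
            freq = float((left[ok] != right[ok]).mean()) if ok.any() else float("nan")
            boundary_rows.append((chrom, int(ends[j]), freq))

    per_line = pd.DataFrame(
        {
            "line": pbm.line_names,
            "homozygous_fraction": np.where(non_na > 0, homo / np.maximum(non_na, 1), np.nan),
            "breakpoints": bp_count,
            # one of several candidate per-line "recombination frequency"
            # statistics; breakpoint count and per-boundary switch rates are
            # the others
            "minor_parent_fraction": np.minimum(aa, bb) / total,
            "frac_AA": aa / total,
            "frac_BB": bb / total,
            "frac_HET": het / total,
            "frac_NA": na / total,
        }
    )
    boundaries = pd.DataFrame(
        boundary_rows, columns=["chrom", "boundary_bp", "recombination_frequency"]
    )
    overall = float(homo.sum() / non_na.sum()) if non_na.sum() > 0 else float("nan")
    n_line_bins = (
        sum(len(t.bins) for tracks in line_tracks.values() for t in tracks)
        if line_tracks is not None
        else -1
    )
    return BinMapStats(per_line, boundaries, overall, pbm.n_bins, n_line_bins)
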