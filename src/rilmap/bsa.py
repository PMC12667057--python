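"""Bulked-segregant QTL localization from ΔSNP-index profiles.

Two extreme-phenotype bulks of an F2 population are sequenced; at each SNP
the SNP-index of a bulk is the fraction of reads carrying the B-parent
(alt) allele, and Δ(SNP-index) is the high-bulk minus low-bulk index.  Away
from a trait locus both bulks segregate 1:1 and Δ fluctuates around zero;
near a locus the bulks are enriched for opposite alleles and |Δ| rises.

The per-SNP profile is averaged in sliding windows, and significance is
assessed against a Monte Carlo null: with no linkage, a bulk of ``b``
individuals carries ``2b`` chromosomes whose B-allele frequency is
Binomial(2b, 1/2)/2b, and read counts are binomial at depths resampled from
the observed depth distribution.  Per-window two-sided 95% and 99%
envelopes come from the quantiles of the simulated windowed Δ.  Maximal
runs of windows outside the 95% envelope are reported as candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_DEPTH = 10
DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_STEP_BP = 100_000


def snp_index_profile(counts: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Per-SNP SNP-index and ΔSNP-index.

    ``counts`` needs columns chrom, pos, high_ref, high_alt, low_ref,
    low_alt, sorted by position within chromosome.  The index of a bulk is
    alt / (ref + alt); Δ = high − low.  SNPs with total depth below
    ``min_depth`` in either bulk are masked (index NaN, ``masked`` True).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    df = counts.copy()
    for c in ("high_ref", "high_alt", "low_ref", "low_alt"):
        if (df[c] < 0).any():
            raise ValueError(f"negative depth in column {c}")
    grp_sorted = df.groupby("chrom", sort=False)["pos"].apply(
        lambda s: bool(np.all(np.diff(s.to_numpy()) >= 0))
    )
    if not grp_sorted.all():
        raise ValueError("counts must be sorted by position within chromosome")
    hi_tot = df["high_ref"] + df["high_alt"]
    lo_tot = df["low_ref"] + df["low_alt"]
    mask = (hi_tot < min_depth) | (lo_tot < min_depth)
    with np.errstate(divide="ignore", invalid="ignore"):
        hi = np.where(hi_tot > 0, df["high_alt"] / hi_tot, np.nan)
        lo = np.where(lo_tot > 0, df["low_alt"] / lo_tot, np.nan)
    df["high_index"] = np.where(mask, np.nan, hi)
    df["low_index"] = np.where(mask, np.nan, lo)
    df["delta"] = df["high_index"] - df["low_index"]
    df["masked"] = mask.to_numpy()
    return df


def _window_starts(length: int, window_bp: int, step_bp: int) -> np.ndarray:
    if length <= window_bp:
        return np.array([1], dtype=np.int64)
    starts = np.arange(1, length - window_bp + 2, step_bp, dtype=np.int64)
    return starts


def _windowed_means(
    pos: np.ndarray, delta: np.ndarray, starts: np.ndarray, window_bp: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean Δ and SNP count for each window [start, start + window_bp - 1]."""
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    delta = delta[order]
    csum = np.concatenate([[0.0], np.cumsum(delta)])
    cnt = np.arange(len(pos) + 1)
    i0 = np.searchsorted(pos, starts)
    i1 = np.searchsorted(pos, starts + window_bp - 1, side="right")
    n = (cnt[i1] - cnt[i0]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, (csum[i1] - csum[i0]) / np.maximum(n, 1), np.nan)
    return mean, n


@dataclass
class WindowedProfile:
    """Sliding-window ΔSNP-index with Monte Carlo null envelopes."""

    windows: pd.DataFrame  # chrom, start, end, mid, n_snps, delta,
    #                        q025, q975, q005, q995


def smooth_and_null(
    profile: pd.DataFrame,
    bulk_size: int,
    rng: np.random.Generator,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    reps: int = 500,
    chrom_lengths: dict[str, int] | None = None,
) -> WindowedProfile:
    """Windowed ΔSNP-index plus per-window null envelopes.

    For each null replicate, each bulk's allele frequency at every SNP is
    drawn as Binomial(2·bulk_size, 0.5) / (2·bulk_size); depths are
    resampled with replacement from the observed (unmasked) depths of that
    bulk, and Δ is recomputed and windowed.  Envelopes are the 2.5/97.5 and
    0.5/99.5 percent quantiles per window.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for stable envelope quantiles")
    if bulk_size < 1:
        raise ValueError("bulk_size must be >= 1")
    unmasked = profile[~profile["masked"]]
    if unmasked.empty:
        raise ValueError("no unmasked SNPs")
    hi_depth_pool = (unmasked["high_ref"] + unmasked["high_alt"]).to_numpy()
    lo_depth_pool = (unmasked["low_ref"] + unmasked["low_alt"]).to_numpy()

    rows = []
    for chrom, grp in unmasked.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        delta = grp["delta"].to_numpy()
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else int(pos.max())
        )
        starts = _window_starts(length, window_bp, step_bp)
        obs_mean, n_snps = _windowed_means(pos, delta, starts, window_bp)

        m = len(pos)
        sims = np.empty((reps, len(starts)))
        two_b = 2 * bulk_size
        for r in range(reps):
            f_hi = rng.binomial(two_b, 0.5, size=m) / two_b
            f_lo = rng.binomial(two_b, 0.5, size=m) / two_b
            d_hi = hi_depth_pool[rng.integers(0, len(hi_depth_pool), size=m)]
            d_lo = lo_depth_pool[rng.integers(0, len(lo_depth_pool), size=m)]
            idx_hi = rng.binomial(d_hi, f_hi) / np.maximum(d_hi, 1)
            idx_lo = rng.binomial(d_lo, f_lo) / np.maximum(d_lo, 1)
            sims[r], _ = _windowed_means(pos, idx_hi - idx_lo, starts, window_bp)
        with np.errstate(invalid="ignore"):
            q025, q975 = np.nanquantile(sims, [0.025, 0.975], axis=0)
            q005, q995 = np.nanquantile(sims, [0.005, 0.995], axis=0)
        ends = np.minimum(starts + window_bp - 1, length)
        for k in range(len(starts)):
            rows.append(
                (
                    chrom,
                    int(starts[k]),
                    int(ends[k]),
                    int((starts[k] + ends[k]) // 2),
                    int(n_snps[k]),
                    obs_mean[k],
                    q025[k],
                    q975[k],
                    q005[k],
                    q995[k],
                )
            )
    windows = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "mid", "n_snps", "delta",
            "q025", "q975", "q005", "q995",
        ],
    )
    windows = windows[windows["n_snps"] > 0].reset_index(drop=True)
    return WindowedProfile(windows)


def call_candidate_regions(windowed: WindowedProfile) -> pd.DataFrame:
    """Maximal runs of consecutive windows outside the 95% envelope.

    Returns a DataFrame: chrom, start, end, peak_mid, peak_delta, n_windows
    (1-based inclusive coordinates; empty if nothing exceeds the envelope).
    """
    w = windowed.windows
    out_rows = []
    for chrom, grp in w.groupby("chrom", sort=False):
        grp = grp.sort_values("start", kind="stable")
        exceed = (
            (grp["delta"] > grp["q975"]) | (grp["delta"] < grp["q025"])
        ).to_numpy()
        idx = np.nonzero(exceed)[0]
        if idx.size == 0:
            continue
        splits = np.nonzero(np.diff(idx) > 1)[0]
        run_starts = np.concatenate([[0], splits + 1])
        run_ends = np.concatenate([splits, [idx.size - 1]])
        for rs, re in zip(run_starts, run_ends):
            members = grp.iloc[idx[rs] : idx[re] + 1]
            peak = members.loc[members["delta"].abs().idxmax()]
            out_rows.append(
                {
                    "chrom": chrom,
                    "start": int(members["start"].min()),
                    "end": int(members["end"].max()),
                    "peak_mid": int(peak["mid"]),
                    "peak_delta": float(peak["delta"]),
                    "n_windows": len(members),
                }
            )
    return pd.DataFrame(
        out_rows,
        columns=["chrom", "start", "end", "peak_mid", "peak_delta", "n_windows"],
    )
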