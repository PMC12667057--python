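"""Bin-based association mapping with a kinship-aware linear mixed model.

The scan follows the EMMA/EMMAX approach: the model per bin is

    y = W alpha + x beta + u + e,   u ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

with K the centered cross-product kinship from the bin dosages.  The
variance ratio delta = se^2/sg^2 is estimated once by REML under the null
(no marker) using the eigendecomposition of K and a one-dimensional
likelihood optimization; every bin is then tested by generalized least
squares with delta fixed (the "population parameters previously determined"
approximation; an exact per-bin REML option is available).  Wald p-values
use the standard normal reference.

Significant bins are merged into loci, each locus reports its lead bin and a
proportion of variance explained (PVE = beta^2 Var(x) / Var(y) with beta the
mixed-model GLS estimate), and a PCA of the dosage matrix provides the
population-structure check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import PCA

from .binmap import PopulationBinMap
from .simpop import NA


@dataclass
class DosageMatrix:
    """Lines x bins numeric dosages: AA=0, HET=1, BB=2, NA=NaN."""

    line_names: list[str]
    bins: pd.DataFrame  # chrom, start, end (one row per column)
    X: np.ndarray  # float64 with NaN for missing
    testable: np.ndarray  # bool per column: polymorphic after missing removal


def dosage_matrix(pbm: PopulationBinMap) -> DosageMatrix:
    """Encode a population bin map as numeric dosages for the LMM."""
    if pbm.n_bins == 0:
        raise ValueError("empty bin map")
    X = pbm.table.astype(np.float64)
    X[pbm.table == NA] = np.nan
    testable = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        col = X[:, j]
        col = col[~np.isnan(col)]
        testable[j] = col.size >= 2 and np.nanvar(col) > 0
    return DosageMatrix(list(pbm.line_names), pbm.bins.copy(), X, testable)


def _impute_center(X: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing values per column and center; optionally scale to
    unit variance.  Returns (Z, polymorphic mask)."""
    Z = X.copy()
    mu = np.nanmean(Z, axis=0)
    idx = np.where(np.isnan(Z))
    Z[idx] = np.take(mu, idx[1])
    Z -= Z.mean(axis=0)
    sd = Z.std(axis=0)
    poly = sd > 0
    if scale:
        Z[:, poly] /= sd[poly]
    Z[:, ~poly] = 0.0
    return Z, poly


def kinship_matrix(dm: DosageMatrix | np.ndarray) -> np.ndarray:
    """Centered cross-product kinship K = Z Z^T / c.

    Columns are mean-imputed, centered and scaled to unit variance; ``c`` is
    the number of polymorphic bins used, so the diagonal averages about 1.
    """
    X = dm.X if isinstance(dm, DosageMatrix) else np.asarray(dm, dtype=float)
    Z, poly = _impute_center(X, scale=True)
    c = int(poly.sum())
    if c == 0:
        raise ValueError("all bins monomorphic: kinship undefined")
    K = (Z @ Z.T) / c
    return (K + K.T) / 2.0


@dataclass
class LMMFit:
    """Null-model REML fit: variance components and the cached eigensystem."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    loglik: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


def _reml_neg2ll(delta: float, s: np.ndarray, yt: np.ndarray, Wt: np.ndarray) -> float:
    w = 1.0 / (s + delta)
    A = (Wt * w[:, None]).T @ Wt
    b = (Wt * w[:, None]).T @ yt
    alpha = np.linalg.solve(A, b)
    r = yt - Wt @ alpha
    rss = float(np.sum(w * r * r))
    n, q = len(yt), Wt.shape[1]
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0 or rss <= 0:
        return np.inf
    return (n - q) * np.log(rss / (n - q)) + float(np.sum(np.log(s + delta))) + logdetA


def reml_fit(
    y: np.ndarray,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
) -> LMMFit:
    """REML estimate of the variance ratio delta = se^2/sg^2 under the null.

    The 1-D profile REML criterion in delta is minimized over a log grid and
    refined by bounded scalar optimization.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    n = len(y)
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Wt = U.T @ W
    grid = np.logspace(-5, 5, 41)
    vals = [_reml_neg2ll(d, s, yt, Wt) for d in grid]
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda ld: _reml_neg2ll(np.exp(ld), s, yt, Wt),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    delta = float(np.exp(res.x))
    w = 1.0 / (s + delta)
    A = (Wt * w[:, None]).T @ Wt
    alpha = np.linalg.solve(A, (Wt * w[:, None]).T @ yt)
    r = yt - Wt @ alpha
    q = W.shape[1]
    sigma_g2 = float(np.sum(w * r * r) / (n - q))
    return LMMFit(
        sigma_g2=sigma_g2,
        sigma_e2=delta * sigma_g2,
        delta=delta,
        loglik=-0.5 * float(res.fun),
        eigenvalues=s,
        eigenvectors=U,
    )


def _gls_scan_core(
    yt: np.ndarray,
    Xt: np.ndarray,
    Wt: np.ndarray,
    w: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized weighted regression of y on each column of X given
    covariates W.  Returns (beta, se) per column."""
    sw = np.sqrt(w)
    yw = yt * sw
    Ww = Wt * sw[:, None]
    Xw = Xt * sw[:, None]
    Q, _ = np.linalg.qr(Ww)
    y_r = yw - Q @ (Q.T @ yw)
    X_r = Xw - Q @ (Q.T @ Xw)
    sxx = np.einsum("ij,ij->j", X_r, X_r)
    sxy = X_r.T @ y_r
    syy = float(y_r @ y_r)
    n, q = len(yt), Wt.shape[1]
    df = n - q - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 1e-12, sxy / np.maximum(sxx, 1e-300), 0.0)
        rss = np.maximum(syy - beta * sxy, 0.0)
        sigma2 = rss / df
        se = np.sqrt(np.where(sxx > 1e-12, sigma2 / np.maximum(sxx, 1e-300), np.inf))
    return beta, se


def lmm_scan(
    y: np.ndarray,
    dm: DosageMatrix,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    fit: LMMFit | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Mixed-model association scan over all bins.

    Missing dosages are mean-imputed per bin.  With ``exact=False`` (the
    default) the null REML variance ratio is reused for every bin; with
    ``exact=True`` delta is re-estimated per bin by REML with the marker in
    the model (slow, for verification).  Untestable (monomorphic) bins get
    beta = 0, se = inf and p = 1.

    Returns a DataFrame: bin, chrom, start, end, beta, se, wald, p, testable.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    n = len(y)
    if n != dm.X.shape[0]:
        raise ValueError("phenotype length must equal number of lines")
    if fit is None:
        fit = reml_fit(y, K, covariates)
    U, s = fit.eigenvectors, fit.eigenvalues
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("singular design after covariate inclusion")
    Ximp, _ = _impute_center(dm.X, scale=False)
    yt, Wt, Xt = U.T @ y, U.T @ W, U.T @ Ximp

    if not exact:
        w = 1.0 / (s + fit.delta)
        beta, se = _gls_scan_core(yt, Xt, Wt, w)
    else:
        beta = np.zeros(dm.X.shape[1])
        se = np.full(dm.X.shape[1], np.inf)
        for j in range(dm.X.shape[1]):
            if not dm.testable[j]:
                continue
            Wj = np.column_stack([W, Ximp[:, j]])
            fj = reml_fit(y, K, Wj[:, 1:])
            wj = 1.0 / (fj.eigenvalues + fj.delta)
            b, e_ = _gls_scan_core(
                fj.eigenvectors.T @ y,
                (fj.eigenvectors.T @ Ximp[:, j])[:, None],
                fj.eigenvectors.T @ W,
                wj,
            )
            beta[j], se[j] = b[0], e_[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    p = stats.chi2.sf(wald**2, df=1)
    p = np.where(dm.testable, p, 1.0)
    beta = np.where(dm.testable, beta, 0.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = dm.bins.copy()
    out.insert(0, "bin", np.arange(len(out)))
    out["beta"] = beta
    out["se"] = se
    out["wald"] = wald
    out["p"] = p
    out["testable"] = dm.testable
    return out


def permutation_threshold(
    y: np.ndarray,
    dm: DosageMatrix,
    K: np.ndarray,
    rng: np.random.Generator,
    n_perm: int = 200,
    alpha: float = 0.05,
) -> float:
    """Genome-wide threshold: the alpha-quantile of the minimum p-value over
    phenotype permutations."""
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    mins = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        rec = lmm_scan(yp, dm, K)
        mins[b] = rec.loc[rec["testable"], "p"].min()
    return float(np.quantile(mins, alpha))


def significance_and_loci(
    records: pd.DataFrame,
    threshold: float | None = None,
    alpha: float = 0.05,
    merge_gap: float = 2_000_000,
) -> pd.DataFrame:
    """Call significant bins and merge them into loci.

    The default threshold is Bonferroni: alpha / number of testable bins.
    Significant bins on the same chromosome whose intervals are within
    ``merge_gap`` bp of each other are merged into one locus; the lead bin is
    the minimum-p bin.  Returns a DataFrame (possibly empty): chrom, start,
    end, lead_bin, lead_p, n_bins.
    """
    n_testable = int(records["testable"].sum())
    if threshold is None:
        threshold = alpha / max(n_testable, 1)
    sig = records[(records["p"] < threshold) & records["testable"]].copy()
    if sig.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "lead_bin", "lead_p", "n_bins", "threshold"]
        )
    sig = sig.sort_values(["chrom", "start"], kind="stable")
    loci = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        cur: list[pd.Series] = []
        last_end = None
        for _, row in grp.iterrows():
            if last_end is not None and row["start"] - last_end > merge_gap:
                loci.append((chrom, cur))
                cur = []
            cur.append(row)
            last_end = max(last_end or row["end"], row["end"])
        if cur:
            loci.append((chrom, cur))
    rows = []
    for chrom, members in loci:
        sub = pd.DataFrame(members)
        lead = sub.loc[sub["p"].idxmin()]
        rows.append(
            {
                "chrom": chrom,
                "start": int(sub["start"].min()),
                "end": int(sub["end"].max()),
                "lead_bin": int(lead["bin"]),
                "lead_p": float(lead["p"]),
                "n_bins": len(sub),
                "threshold": threshold,
            }
        )
    out = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable")
    return out.reset_index(drop=True)


def locus_pve(
    y: np.ndarray,
    x: np.ndarray,
    K: np.ndarray,
    fit: LMMFit | None = None,
) -> float:
    """Proportion of phenotypic variance explained by a lead bin.

    PVE = beta^2 Var(x) / Var(y), with beta from the mixed-model GLS fit at
    the null variance ratio; clamped to [0, 1].
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.var(y) == 0:
        raise ValueError("zero phenotypic variance")
    mu = np.nanmean(x)
    x = np.where(np.isnan(x), mu, x)
    if fit is None:
        fit = reml_fit(y, K)
    U, s = fit.eigenvectors, fit.eigenvalues
    w = 1.0 / (s + fit.delta)
    beta, _ = _gls_scan_core(U.T @ y, (U.T @ x)[:, None], U.T @ np.ones((len(y), 1)), w)
    pve = float(beta[0] ** 2 * np.var(x) / np.var(y))
    return float(np.clip(pve, 0.0, 1.0))


def structure_pca(
    dm: DosageMatrix | np.ndarray, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the centered (mean-imputed) dosage matrix.

    Returns (coordinates, explained variance ratios)."""
    X = dm.X if isinstance(dm, DosageMatrix) else np.asarray(dm, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 lines")
    Z, _ = _impute_center(X, scale=False)
    n_components = min(n_components, min(Z.shape) - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(Z)
    return coords, pca.explained_variance_ratio_
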