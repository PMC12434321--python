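"""Genotype-environment association by redundancy analysis (RDA).

Genotype likelihoods are converted to hard calls under per-individual depth
gates, filtered, mode-imputed, and regressed on standardized deme-level
environmental predictors.  The constrained ordination is the SVD of the
fitted values; significance comes from row-permutation of the predictors,
and candidate loci are SNPs whose axis loadings lie more than k standard
deviations from the mean, intersected with the haploblock regions.

Individuals inherit their deme's environmental values (streams were
measured, not fish); that pseudo-replication is faithful to the source
design and recorded in the fit metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gtio import GLDataset, RegionRecord

__all__ = [
    "hard_call",
    "filter_impute",
    "RdaFit",
    "rda_fit",
    "rda_significance",
    "rda_outliers",
]

MISSING = -1


def hard_call(
    ds: GLDataset,
    min_depth: int = 2,
    max_depth: int = 5,
) -> np.ndarray:
    """Argmax-likelihood genotype calls gated on per-individual depth.

    Entry (i, s) is the most likely genotype of individual i at SNP s iff
    that individual's read depth there lies in [min_depth, max_depth];
    otherwise missing (-1).  Likelihood ties are treated as missing.
    Returns an individuals x SNPs int8 matrix.
    """
    if ds.depth is None:
        raise ValueError("hard calling requires a depth layer")
    gl = ds.gl  # (S, N, 3)
    best = gl.argmax(axis=2)
    sorted_gl = np.sort(gl, axis=2)
    tied = np.isclose(sorted_gl[:, :, 2], sorted_gl[:, :, 1])
    in_gate = (ds.depth >= min_depth) & (ds.depth <= max_depth)
    calls = np.where(in_gate & ~tied, best, MISSING).astype(np.int8)
    return calls.T  # individuals x SNPs


@dataclass
class ImputeReport:
    n_snps_in: int
    n_snps_kept: int
    missing_fraction: float  # among kept SNPs, before imputation
    kept: np.ndarray  # column indices kept


def filter_impute(
    G: np.ndarray,
    min_maf: float = 0.10,
    min_ind: float = 0.90,
) -> tuple[np.ndarray, ImputeReport]:
    """Drop poorly called / low-MAF SNPs and fill the rest with the mode.

    A SNP survives iff its called fraction is >= ``min_ind`` and its
    called-genotype minor-allele frequency is >= ``min_maf``.  Remaining
    missing entries take the SNP's modal genotype (ties: the lower genotype
    value).  The report carries the pre-imputation missingness of the kept
    columns.
    """
    G = np.asarray(G)
    n, m = G.shape
    called = G != MISSING
    frac = called.mean(axis=0)
    with np.errstate(invalid="ignore"):
        mean_g = np.where(
            called.sum(axis=0) > 0,
            np.where(G == MISSING, 0, G).sum(axis=0) / np.maximum(called.sum(axis=0), 1),
            np.nan,
        )
    p = mean_g / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = (frac >= min_ind) & (maf >= min_maf)
    if not keep.any():
        raise ValueError("all SNPs dropped by filtering")
    kept_idx = np.flatnonzero(keep)
    Gk = G[:, kept_idx].copy()
    miss = Gk == MISSING
    missing_fraction = float(miss.mean())
    for j in np.flatnonzero(miss.any(axis=0)):
        col = Gk[:, j]
        counts = np.bincount(col[col != MISSING], minlength=3)
        mode = int(np.argmax(counts))  # argmax takes the lower value on ties
        col[col == MISSING] = mode
    return Gk, ImputeReport(m, len(kept_idx), missing_fraction, kept_idx)


@dataclass
class RdaFit:
    """Constrained ordination of a genotype matrix on environment."""

    Y: np.ndarray  # centered genotypes, n x m
    X: np.ndarray  # standardized environment, n x p
    fitted: np.ndarray  # n x m
    singular_values: np.ndarray  # length min(p, rank)
    loadings: np.ndarray  # m x axes (right singular vectors)
    scores: np.ndarray  # n x axes (left singular vectors * d)
    r2: float
    adj_r2: float
    axis_proportion: np.ndarray
    env_names: list[str]
    coef: np.ndarray  # p x m regression coefficients

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)


def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant environmental column cannot be standardized")
    return (X - mu) / sd


def rda_fit(
    G: np.ndarray,
    env: pd.DataFrame,
    scale_genotypes: bool = False,
    max_env_corr: float = 0.70,
) -> RdaFit:
    """Redundancy analysis of genotypes on environmental predictors.

    Y is the column-centered (optionally scaled) genotype matrix, X the
    standardized environment.  The fit is Yhat = X (X'X)^-1 X' Y; the
    canonical axes are the SVD of Yhat.  R^2 = |Yhat|^2 / |Y|^2 and the
    adjusted R^2 applies the Ezekiel correction 1 - (1-R^2)(n-1)/(n-p-1).
    Environmental collinearity (|Pearson r| >= 0.70 for any pair) is an
    error naming the offending pair.
    """
    G = np.asarray(G, float)
    n, m = G.shape
    env_names = list(env.columns)
    X_raw = env.to_numpy(dtype=float)
    if X_raw.shape[0] != n:
        raise ValueError("environment rows must match individuals")
    p = X_raw.shape[1]
    if p >= n:
        raise ValueError("need more individuals than predictors")
    corr = np.corrcoef(X_raw, rowvar=False)
    for a in range(p):
        for b in range(a + 1, p):
            if abs(corr[a, b]) >= max_env_corr:
                raise ValueError(
                    f"collinear predictors {env_names[a]!r} and {env_names[b]!r}: "
                    f"|r| = {abs(corr[a, b]):.3f} >= {max_env_corr}"
                )
    X = _standardize(X_raw)
    Y = G - G.mean(axis=0)
    if scale_genotypes:
        sd = Y.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Y = Y / sd
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        raise ValueError("singular predictor cross-product")
    coef = np.linalg.solve(xtx, X.T @ Y)
    fitted = X @ coef
    U, d, Vt = np.linalg.svd(fitted, full_matrices=False)
    k = min(p, len(d))
    U, d, Vt = U[:, :k], d[:k], Vt[:k]
    ss_fit = float(np.sum(fitted**2))
    ss_tot = float(np.sum(Y**2))
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    prop = d**2 / np.sum(d**2) if np.sum(d**2) > 0 else np.zeros_like(d)
    return RdaFit(
        Y=Y,
        X=X,
        fitted=fitted,
        singular_values=d,
        loadings=Vt.T,
        scores=U * d,
        r2=r2,
        adj_r2=adj,
        axis_proportion=prop,
        env_names=env_names,
        coef=coef,
    )


def rda_significance(
    fit: RdaFit, n_perm: int = 999, seed: int = 0, axes: bool = True
) -> dict:
    """Permutation significance for the overall model and each axis.

    The overall statistic is the pseudo-F
    (|Yhat|^2 / p) / (|Y - Yhat|^2 / (n - p - 1)); predictors' rows are
    permuted (equivalently Y's) and p = (1 + #{F_perm >= F_obs})/(1+n_perm).
    Per axis k, Y is residualized on the preceding canonical axes and the
    null statistic is the leading squared singular value of the projected
    permuted residual.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    X, Y = fit.X, fit.Y
    n, p = X.shape
    H = X @ np.linalg.solve(X.T @ X, X.T)
    ss_res = float(np.sum((Y - fit.fitted) ** 2))
    df_res = n - p - 1
    f_obs = (np.sum(fit.fitted**2) / p) / (ss_res / df_res)
    exceed = 0
    perms = [rng.permutation(n) for _ in range(n_perm)]
    for perm in perms:
        Yp = Y[perm]
        fit_p = H @ Yp
        ssf = float(np.sum(fit_p**2))
        f_p = (ssf / p) / ((np.sum(Yp**2) - ssf) / df_res)
        if f_p >= f_obs - 1e-12:
            exceed += 1
    p_overall = (1 + exceed) / (1 + n_perm)

    if not axes:
        return {"overall": p_overall, "axes": None, "n_perm": n_perm}

    axis_p = []
    resid = Y.copy()
    for k in range(fit.n_axes):
        d2_obs = fit.singular_values[k] ** 2
        exceed_k = 0
        for perm in perms:
            Rp = resid[perm]
            s = np.linalg.svd(H @ Rp, compute_uv=False)
            if (s[0] ** 2) >= d2_obs - 1e-12:
                exceed_k += 1
        axis_p.append((1 + exceed_k) / (1 + n_perm))
        # peel off axis k before testing the next one
        v = fit.loadings[:, k : k + 1]
        resid = resid - (resid @ v) @ v.T
    return {"overall": p_overall, "axes": np.asarray(axis_p), "n_perm": n_perm}


def rda_outliers(
    fit: RdaFit,
    snp_positions: np.ndarray,
    snp_chroms: np.ndarray | None = None,
    k_sd: float = 3.0,
    blocks: list[RegionRecord] | None = None,
    G: np.ndarray | None = None,
    env: pd.DataFrame | None = None,
    pooled: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """SNPs with loadings more than ``k_sd`` SD from the axis mean.

    Flagging is per constrained axis with a union across axes (set
    ``pooled=True`` to pool loadings over axes instead).  If genotypes and
    environment are supplied, each outlier is annotated with its most
    correlated environmental variable.  Returns (outlier table, per-block
    counts).  A degenerate axis (zero loading SD) flags nothing.
    """
    L = fit.loadings
    m = L.shape[0]
    flagged = np.zeros(m, dtype=bool)
    if pooled:
        vals = L.ravel()
        mu, sd = vals.mean(), vals.std()
        if sd > 0:
            flagged = (np.abs(L - mu) > k_sd * sd).any(axis=1)
    else:
        for k in range(L.shape[1]):
            lk = L[:, k]
            sd = lk.std()
            if sd == 0:
                continue
            flagged |= np.abs(lk - lk.mean()) > k_sd * sd
    idx = np.flatnonzero(flagged)
    positions = np.asarray(snp_positions)
    chroms = (
        np.asarray(snp_chroms)
        if snp_chroms is not None
        else np.full(m, "chr", dtype=object)
    )
    best_env = np.full(len(idx), "", dtype=object)
    best_r = np.full(len(idx), np.nan)
    if G is not None and env is not None and len(idx):
        E = env.to_numpy(dtype=float)
        for row, j in enumerate(idx):
            g = G[:, j].astype(float)
            if g.std() == 0:
                continue
            rs = [
                abs(np.corrcoef(g, E[:, c])[0, 1]) if E[:, c].std() > 0 else 0.0
                for c in range(E.shape[1])
            ]
            c = int(np.argmax(rs))
            best_env[row] = env.columns[c]
            best_r[row] = rs[c]
    table = pd.DataFrame(
        {
            "snp_index": idx,
            "chrom": chroms[idx],
            "position": positions[idx],
            "env_variable": best_env,
            "abs_corr": best_r,
        }
    )
    per_block: dict[str, int] = {}
    if blocks:
        for b in blocks:
            inside = (table["chrom"] == b.chrom) & (
                (table["position"] > b.start) & (table["position"] <= b.end)
            )
            per_block[b.label or f"{b.chrom}:{b.start}-{b.end}"] = int(inside.sum())
    return table, per_block
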