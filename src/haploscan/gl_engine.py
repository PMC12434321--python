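"""Genotype-likelihood machinery for low-coverage (~3x) data.

Everything downstream of read counts runs on per-site likelihood triplets
L(g) for g in {0, 1, 2} copies of the minor allele, never on hard calls:

* the symmetric-error likelihood model turning allele read counts into
  triplets;
* depth filtering around the mean of the per-site total-depth histogram;
* EM estimation of the minor-allele frequency f under the HWE prior
  P(g | f) = Binom(2, f), with the likelihood-ratio SNP test against f = 0;
* PCA of the posterior-dosage covariance matrix;
* unconstrained trinomial EM for per-group genotype frequencies, whose
  heterozygote class is the observed heterozygosity H_obs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .gtio import GLDataset

__all__ = [
    "genotype_likelihoods_from_counts",
    "DepthFilter",
    "depth_filter",
    "em_maf",
    "em_maf_sites",
    "call_snps",
    "PcaResult",
    "covariance_pca",
    "group_genotype_freq",
]

EM_TOL = 1e-8
EM_MAX_ITER = 200


def genotype_likelihoods_from_counts(n_major, n_minor, eps: float):
    """Likelihood triplet for (major, het, minor) genotypes from read counts.

    With g minor-allele copies a read reports the minor allele with
    probability (g/2)(1-eps) + (1-g/2)eps, so

        L(g) = [(1-g/2)(1-eps) + (g/2)eps]^n_major
             * [(1-g/2)eps + (g/2)(1-eps)]^n_minor

    returned normalized to sum to one.  Zero total depth yields the uniform
    triplet (missing data, not an error).  Accepts scalars or aligned arrays.
    """
    if not 0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    n_major = np.asarray(n_major)
    n_minor = np.asarray(n_minor)
    if np.any(n_major < 0) or np.any(n_minor < 0):
        raise ValueError("negative read counts")
    scalar = n_major.ndim == 0 and n_minor.ndim == 0
    n_major, n_minor = np.broadcast_arrays(np.atleast_1d(n_major), np.atleast_1d(n_minor))
    # per-genotype probability that a read shows the major allele
    p_major = np.array([1.0 - eps, 0.5, eps])
    with np.errstate(divide="ignore", invalid="ignore"):
        logl = (
            n_major[..., None] * np.log(p_major)
            + n_minor[..., None] * np.log(1.0 - p_major)
        )
    logl -= logl.max(axis=-1, keepdims=True)
    tri = np.exp(logl)
    tri /= tri.sum(axis=-1, keepdims=True)
    return tri[0] if scalar else tri


@dataclass
class DepthFilter:
    """Per-site total-depth bounds mean +/- c * sd, plus a min-individuals gate."""

    mean: float
    sd: float
    multiplier: float
    min_depth: float
    max_depth: float
    min_ind: int
    histogram: np.ndarray

    def __post_init__(self):
        if self.min_depth >= self.max_depth and self.sd > 0:
            raise ValueError("min_depth must be below max_depth")


def depth_filter(depth: np.ndarray, c: float = 1.0, min_ind: int = 1):
    """Site mask from the total-depth histogram.

    A site passes iff its total depth (summed over individuals) lies within
    [mean - c*sd, mean + c*sd] of the per-site total-depth distribution and
    at least ``min_ind`` individuals have >= 1 read there.  With sd = 0
    (uniform depth) every site passes the depth band.
    """
    depth = np.asarray(depth)
    total = depth.sum(axis=1)
    mu = float(total.mean())
    sd = float(total.std())
    lo, hi = mu - c * sd, mu + c * sd
    n_covered = (depth > 0).sum(axis=1)
    mask = (total >= lo) & (total <= hi) & (n_covered >= min_ind)
    if not mask.any():
        warnings.warn("depth filter removed every site", stacklevel=2)
    filt = DepthFilter(
        mean=mu,
        sd=sd,
        multiplier=c,
        min_depth=lo,
        max_depth=hi,
        min_ind=int(min_ind),
        histogram=np.bincount(total.astype(int)) if total.size else np.zeros(0, int),
    )
    return filt, mask


def _hwe_prior(f):
    """P(g | f) under Hardy-Weinberg, stacked on the last axis."""
    f = np.asarray(f, dtype=float)
    return np.stack(
        [(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f**2], axis=-1
    )


def em_maf_sites(gl: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER,
                 trace: bool = False):
    """Vectorized EM minor-allele frequency over many sites at once.

    ``gl`` has shape (S, N, 3).  Returns (f_hat, loglik) arrays of shape (S,).
    Individuals with uninformative (uniform) triplets have posterior equal to
    the prior, so they pull the update toward the current f and do not bias
    it.  With ``trace=True`` additionally returns the per-iteration
    log-likelihood matrix (for monotonicity checks).
    """
    gl = np.asarray(gl, dtype=float)
    squeeze = gl.ndim == 2
    if squeeze:
        gl = gl[None]
    S, N, _ = gl.shape
    f = np.full(S, 0.25)
    traces = []
    for _ in range(max_iter):
        prior = _hwe_prior(f)  # (S, 3)
        w = gl * prior[:, None, :]  # (S, N, 3)
        tot = w.sum(axis=2)
        eg = (w[:, :, 1] + 2.0 * w[:, :, 2]) / tot
        f_new = eg.mean(axis=1) / 2.0
        if trace:
            traces.append(np.log(tot).sum(axis=1))
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    prior = _hwe_prior(f)
    loglik = np.log((gl * prior[:, None, :]).sum(axis=2)).sum(axis=1)
    if trace:
        traces.append(loglik)
        tr = np.asarray(traces).T
        return (f[0], loglik[0], tr[0]) if squeeze else (f, loglik, tr)
    return (f[0], loglik[0]) if squeeze else (f, loglik)


def em_maf(gl: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER):
    """EM minor-allele frequency at one site: (f_hat, log-likelihood)."""
    f, ll = em_maf_sites(np.asarray(gl), tol=tol, max_iter=max_iter)
    return float(f), float(ll)


def _loglik_at(gl: np.ndarray, f) -> np.ndarray:
    prior = _hwe_prior(np.asarray(f, dtype=float))
    if prior.ndim == 1:
        prior = np.broadcast_to(prior, (gl.shape[0], 3))
    with np.errstate(divide="ignore"):  # hard triplets can have zero likelihood
        return np.log((gl * prior[:, None, :]).sum(axis=2)).sum(axis=1)


def call_snps(
    ds: GLDataset,
    p_threshold: float = 1e-6,
    min_maf: float = 0.05,
    site_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio SNP calling with a minor-allele-frequency floor.

    LRT = 2[l(f_hat) - l(0)] against chi-square with 1 df (no boundary
    correction, matching common practice in the upstream ecosystem; this is
    conservative).  Sites are oriented so f_hat <= 0.5; sites with
    p < p_threshold and f_hat >= min_maf are kept.  Returns a site table with
    columns chromo, position, major, minor, freq_em, lrt, pvalue, n_ind.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    gl = ds.gl
    if site_mask is not None:
        idx = np.flatnonzero(np.asarray(site_mask))
    else:
        idx = np.arange(ds.n_sites)
    gl = gl[idx]
    f, _ = em_maf_sites(gl)
    # orient to the minor allele
    flip = f > 0.5
    major = ds.sites["major"].to_numpy()[idx].copy()
    minor = ds.sites["minor"].to_numpy()[idx].copy()
    if flip.any():
        gl = gl.copy()
        gl[flip] = gl[flip][:, :, ::-1]
        major[flip], minor[flip] = minor[flip].copy(), major[flip].copy()
        f = np.where(flip, 1.0 - f, f)
    ll_hat = _loglik_at(gl, f)
    ll_0 = _loglik_at(gl, np.zeros_like(f))
    lrt = np.maximum(2.0 * (ll_hat - ll_0), 0.0)
    pval = chi2.sf(lrt, df=1)
    informative = ~np.all(np.isclose(gl, gl[:, :, :1]), axis=2)
    n_ind = informative.sum(axis=1)
    keep = (pval < p_threshold) & (f >= min_maf)
    table = pd.DataFrame(
        {
            "chromo": ds.sites["chrom"].to_numpy()[idx],
            "position": ds.sites["pos"].to_numpy()[idx],
            "major": major,
            "minor": minor,
            "freq_em": f,
            "lrt": lrt,
            "pvalue": pval,
            "n_ind": n_ind,
        }
    )
    table["site_index"] = idx
    return table.loc[keep].reset_index(drop=True)


@dataclass
class PcaResult:
    """Eigendecomposition of the individual x individual GL covariance."""

    cov: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray  # individuals x axes (eigenvectors, descending)
    percent_variance: np.ndarray

    def pc(self, k: int) -> np.ndarray:
        """Scores on axis k (1-based)."""
        return self.scores[:, k - 1]


def posterior_dosages(gl: np.ndarray, f: np.ndarray) -> np.ndarray:
    """E[g | data, f] per site x individual under the HWE prior."""
    prior = _hwe_prior(f)
    w = gl * prior[:, None, :]
    return (w[:, :, 1] + 2.0 * w[:, :, 2]) / w.sum(axis=2)


def covariance_pca(ds: GLDataset, site_table: pd.DataFrame) -> PcaResult:
    """PCA of the standardized posterior-dosage covariance matrix.

    Per SNP s, posterior dosages g_hat are centered on their empirical mean
    across individuals and standardized by sqrt(2 f_s (1 - f_s)); the
    covariance between individuals averages the product over SNPs.
    Empirical centering (rather than the model mean 2 f_s) cancels the
    rank-one common mode that frequency-estimation error would otherwise
    inject into every entry -- at low depth that mode can dominate the lead
    eigenvector.  Individuals with no reads at a site carry the prior-mean
    dosage 2 f_s, i.e. approximately zero after centering.
    """
    if ds.n_individuals < 2:
        raise ValueError("need >= 2 individuals for PCA")
    if "site_index" in site_table.columns:
        idx = site_table["site_index"].to_numpy()
    else:
        key = ds.sites.reset_index().set_index(["chrom", "pos"])["index"]
        idx = key.loc[
            list(zip(site_table["chromo"], site_table["position"]))
        ].to_numpy()
    f = site_table["freq_em"].to_numpy(dtype=float)
    ok = (f > 0) & (f < 1)
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} monomorphic SNPs from PCA", stacklevel=2
        )
        idx, f = idx[ok], f[ok]
    if len(idx) < 2:
        raise ValueError("need >= 2 polymorphic SNPs for PCA")
    gl = ds.gl[idx]
    dose = posterior_dosages(gl, f)
    z = (dose - dose.mean(axis=1, keepdims=True)) / np.sqrt(2.0 * f * (1.0 - f))[:, None]
    cov = (z.T @ z) / len(idx)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0.0, None)
    pct = 100.0 * pos / pos.sum() if pos.sum() > 0 else np.zeros_like(pos)
    return PcaResult(cov=cov, eigenvalues=evals, scores=evecs, percent_variance=pct)


def group_genotype_freq(
    gl: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
) -> np.ndarray:
    """Unconstrained trinomial EM genotype frequencies for one group.

    ``gl`` is (N, 3) for one site or (S, N, 3) for many; returns (p0, p1, p2)
    per site.  No HWE constraint: the heterozygote frequency p1 is the
    observed heterozygosity H_obs.  Reduces to empirical genotype counting
    when the triplets are hard calls.
    """
    gl = np.asarray(gl, dtype=float)
    squeeze = gl.ndim == 2
    if squeeze:
        gl = gl[None]
    S, N, _ = gl.shape
    if N < 2:
        raise ValueError("group size must be >= 2")
    p = np.full((S, 3), 1.0 / 3.0)
    for _ in range(max_iter):
        w = gl * p[:, None, :]
        w /= w.sum(axis=2, keepdims=True)
        p_new = w.mean(axis=1)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    return p[0] if squeeze else p
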