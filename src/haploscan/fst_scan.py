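"""Sample-allele-frequency likelihoods, folded 2D-SFS EM, and windowed FST.

The chain mirrors the standard low-coverage workflow: per-site likelihood
vectors over the population minor-allele count (SAF, computed by a dynamic
program over individuals), an EM estimate of the joint two-population site
frequency spectrum used as a prior, per-site Reynolds (1983) variance
components from the posterior over joint allele counts, and ratio-of-sums
FST in sliding windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "site_saf",
    "saf_matrix",
    "Sfs2D",
    "sfs_em_2d",
    "reynolds_components",
    "site_fst_components",
    "windowed_fst",
]

EM_TOL = 1e-9
EM_MAX_ITER = 500


def _log_binom(n, k):
    n = np.asarray(n, float)
    k = np.asarray(k, float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def saf_matrix(gl: np.ndarray) -> np.ndarray:
    """SAF vectors for every site of one population.

    ``gl`` is (S, N, 3).  The dynamic program accumulates individuals one at
    a time: with V_i[j] the likelihood that the first i individuals carry j
    minor alleles,

        V_i[j] = sum_g V_{i-1}[j-g] L_i(g) C(2,g) C(2(i-1), j-g) / C(2i, j),

    the combinatorial weights being the hypergeometric probability of the
    split.  Rows are normalized to sum to one.
    """
    gl = np.asarray(gl, float)
    S, N, _ = gl.shape
    V = np.ones((S, 1))
    choose2 = np.array([1.0, 2.0, 1.0])  # C(2, g)
    for i in range(1, N + 1):
        prev_m = 2 * (i - 1)
        m = 2 * i
        j = np.arange(m + 1)
        newV = np.zeros((S, m + 1))
        log_cm = _log_binom(m, j)
        for g in range(3):
            jj = j - g
            ok = (jj >= 0) & (jj <= prev_m)
            w = np.zeros(m + 1)
            w[ok] = np.exp(_log_binom(prev_m, jj[ok]) - log_cm[ok]) * choose2[g]
            newV[:, ok] += V[:, jj[ok]] * gl[:, i - 1, g][:, None] * w[ok]
        norm = newV.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        V = newV / norm
    return V


def site_saf(gl: np.ndarray) -> np.ndarray:
    """SAF vector (length 2N+1) for a single site; ``gl`` is (N, 3)."""
    return saf_matrix(np.asarray(gl, float)[None])[0]


@dataclass
class Sfs2D:
    """Joint two-population SFS over (2N1+1) x (2N2+1) allele counts."""

    phi: np.ndarray
    folded: bool
    n_dropped: int = 0

    def fold(self) -> "Sfs2D":
        """Merge (j, k) with its complement (2N1-j, 2N2-k).

        Mass moves onto orbit representatives (the lexicographically smaller
        member); the central fixed point is left unhalved.
        """
        if self.folded:
            return self
        phi = self.phi.copy()
        J, K = phi.shape
        out = np.zeros_like(phi)
        for j in range(J):
            for k in range(K):
                cj, ck = J - 1 - j, K - 1 - k
                if (j, k) < (cj, ck):
                    out[j, k] = phi[j, k] + phi[cj, ck]
                elif (j, k) == (cj, ck):
                    out[j, k] = phi[j, k]
        return Sfs2D(out, folded=True, n_dropped=self.n_dropped)


def sfs_em_2d(
    saf1: np.ndarray,
    saf2: np.ndarray,
    fold: bool = False,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> Sfs2D:
    """EM estimate of the joint SFS from per-site SAF vectors.

    E-step: gamma_s(j,k) proportional to phi(j,k) saf1_s(j) saf2_s(k);
    M-step: phi is the mean of gamma over sites.  Sites with zero likelihood
    under every (j, k) are dropped and counted.  With ``fold=True`` the
    estimate is folded after convergence.
    """
    A = np.asarray(saf1, float)
    B = np.asarray(saf2, float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("SAF sets must cover the same sites")
    usable = (A.sum(axis=1) > 0) & (B.sum(axis=1) > 0)
    n_dropped = int((~usable).sum())
    A, B = A[usable], B[usable]
    S = A.shape[0]
    J, K = A.shape[1], B.shape[1]
    phi = np.full((J, K), 1.0 / (J * K))
    for _ in range(max_iter):
        AP = A @ phi  # (S, K)
        denom = np.einsum("sk,sk->s", AP, B)
        bad = denom <= 0
        if bad.any():
            denom = np.where(bad, 1.0, denom)
        W = B / denom[:, None]  # (S, K)
        M = A.T @ W  # (J, K): sum_s outer(A_s, B_s)/denom_s
        phi_new = phi * M / S
        phi_new /= phi_new.sum()
        if np.max(np.abs(phi_new - phi)) < tol:
            phi = phi_new
            break
        phi = phi_new
    out = Sfs2D(phi, folded=False, n_dropped=n_dropped)
    return out.fold() if fold else out


def reynolds_components(m1: int, m2: int) -> tuple[np.ndarray, np.ndarray]:
    """Reynolds (1983) between-population (alpha) and total (beta) variance
    components on the grid of joint sample allele counts.

    ``m1``/``m2`` are the haploid sample sizes (2N alleles); entry (j, k)
    evaluates the moment estimator at sample frequencies p1 = j/m1,
    p2 = k/m2, with the Reynolds weights taken at the diploid sizes
    n_i = m_i / 2.  Under equal population frequencies E[alpha] = 0 (the
    correction removes exactly the binomial sampling variance of both
    frequency estimates).  Both grids are symmetric under simultaneous
    allele relabeling, so they apply unchanged to folded spectra.
    """
    n1, n2 = m1 / 2.0, m2 / 2.0
    p1 = np.arange(m1 + 1) / m1
    p2 = np.arange(m2 + 1) / m2
    P1, P2 = np.meshgrid(p1, p2, indexing="ij")
    h1 = 2.0 * P1 * (1.0 - P1)
    h2 = 2.0 * P2 * (1.0 - P2)
    shared = (n1 * h1 + n2 * h2) / (4.0 * n1 * n2 * (n1 + n2 - 1.0))
    d2 = (P1 - P2) ** 2
    alpha = d2 - (n1 + n2) * shared
    beta = d2 + (4.0 * n1 * n2 - n1 - n2) * shared
    return alpha, beta


def site_fst_components(
    saf1: np.ndarray, saf2: np.ndarray, sfs: Sfs2D
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-expected Reynolds components per site.

    The posterior over joint counts is phi(j,k) saf1(j) saf2(k) normalized
    per site; alpha and beta are its expectations of the Reynolds grids.
    Sites with a degenerate (all-zero) posterior return NaN and should be
    skipped by the caller.
    """
    A = np.atleast_2d(np.asarray(saf1, float))
    B = np.atleast_2d(np.asarray(saf2, float))
    phi = sfs.phi
    if sfs.folded:
        # split each orbit's mass over both members so the posterior can
        # follow the data to either side of the fold; alpha and beta are
        # orbit-invariant so expectations are unchanged in distribution
        phi = 0.5 * (phi + phi[::-1, ::-1])
    m1, m2 = A.shape[1] - 1, B.shape[1] - 1
    agrid, bgrid = reynolds_components(m1, m2)
    pa = phi * agrid
    pb = phi * bgrid
    denom = np.einsum("sj,jk,sk->s", A, phi, B)
    num_a = np.einsum("sj,jk,sk->s", A, pa, B)
    num_b = np.einsum("sj,jk,sk->s", A, pb, B)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(denom > 0, num_a / np.where(denom > 0, denom, 1.0), np.nan)
        beta = np.where(denom > 0, num_b / np.where(denom > 0, denom, 1.0), np.nan)
    return alpha, beta


def windowed_fst(
    positions: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    window: int = 10_000,
    slide: int = 10_000,
    chrom: str = "chr",
    min_sites: int = 5,
) -> pd.DataFrame:
    """Ratio-of-sums FST in sliding windows anchored at position 0.

    Windows are half-open [start, start + window); the last partial window
    is kept.  Windows with fewer than ``min_sites`` usable sites are
    flagged.  Returns columns chrom, start, end, n_sites, sum_alpha,
    sum_beta, fst, flagged.
    """
    if window <= 0 or slide <= 0:
        raise ValueError("window and slide must be positive")
    positions = np.asarray(positions)
    alpha = np.asarray(alpha, float)
    beta = np.asarray(beta, float)
    ok = np.isfinite(alpha) & np.isfinite(beta)
    rows = []
    if positions.size:
        last = int(positions.max())
        starts = np.arange(0, last, slide)
    else:
        starts = np.zeros(0, int)
    for start in starts:
        m = ok & (positions > start) & (positions <= start + window)
        n = int(m.sum())
        sa = float(alpha[m].sum())
        sb = float(beta[m].sum())
        fst = sa / sb if (n and sb != 0) else np.nan
        rows.append(
            {
                "chrom": chrom,
                "start": int(start),
                "end": int(start + window),
                "n_sites": n,
                "sum_alpha": sa,
                "sum_beta": sb,
                "fst": fst,
                "flagged": n < min_sites,
            }
        )
    return pd.DataFrame(rows)
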