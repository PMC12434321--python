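"""Pairwise linkage disequilibrium from genotype likelihoods and the
haploblock (candidate inversion) caller built on it.

r^2 between two sites is estimated by EM over the four two-locus haplotype
frequencies, assuming random union of gametes, with each individual's
contribution the product of its two genotype-likelihood triplets.  On top of
the pair engine sit: an exponential LD-decay fit, greedy graph-based
pruning, a windowed heatmap statistic (a configurable high quantile of
cross-window pair r^2 in 250 kb windows), and a density-based square-growing
scan that turns the heatmap into candidate inversion intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import curve_fit

from .gtio import GLDataset, RegionRecord

__all__ = [
    "PairLD",
    "pair_r2_em",
    "pair_r2_batch",
    "ld_decay",
    "prune_linked",
    "WindowPairMatrix",
    "window_pair_matrix",
    "detect_haploblocks",
    "ld_window_scan",
]

EM_TOL = 1e-8
EM_MAX_ITER = 500

# haplotype index x = 2*a1 + a2 with a = 1 meaning the minor allele
_HAP_NAMES = ("AB", "Ab", "aB", "ab")  # A/B major at site 1/2


@dataclass
class PairLD:
    """Two-locus haplotype frequencies and LD summaries for one site pair."""

    site_a: int
    site_b: int
    distance: int
    hap_freq: np.ndarray  # (h_AB, h_Ab, h_aB, h_ab)
    D: float
    D_prime: float
    r2: float
    monomorphic: bool = False


@njit(cache=True)
def _pair_em_kernel(gl, pairs, tol, max_iter):  # pragma: no cover - numba
    P = pairs.shape[0]
    N = gl.shape[1]
    out = np.empty((P, 8))
    g1_of = np.empty((4, 4), np.int64)
    g2_of = np.empty((4, 4), np.int64)
    for x in range(4):
        for y in range(4):
            g1_of[x, y] = (x >> 1) + (y >> 1)
            g2_of[x, y] = (x & 1) + (y & 1)
    L12 = np.empty((N, 3, 3))
    for p in range(P):
        a = pairs[p, 0]
        b = pairs[p, 1]
        n_used = 0
        for i in range(N):
            for u in range(3):
                for v in range(3):
                    L12[i, u, v] = gl[a, i, u] * gl[b, i, v]
        h = np.full(4, 0.25)
        for _ in range(max_iter):
            cnt = np.zeros(4)
            n_used = 0
            for i in range(N):
                norm = 0.0
                w = np.zeros((4, 4))
                for x in range(4):
                    hx = h[x]
                    for y in range(4):
                        val = hx * h[y] * L12[i, g1_of[x, y], g2_of[x, y]]
                        w[x, y] = val
                        norm += val
                if norm <= 0.0:
                    continue
                n_used += 1
                for x in range(4):
                    sx = 0.0
                    for y in range(4):
                        sx += w[x, y] + w[y, x]
                    cnt[x] += sx / norm
            if n_used == 0:
                break
            tot = cnt.sum()
            delta = 0.0
            for x in range(4):
                hn = cnt[x] / tot
                if abs(hn - h[x]) > delta:
                    delta = abs(hn - h[x])
                h[x] = hn
            if delta < tol:
                break
        f1 = h[2] + h[3]
        f2 = h[1] + h[3]
        D = h[3] - f1 * f2
        denom = f1 * (1.0 - f1) * f2 * (1.0 - f2)
        if denom <= 1e-12:
            r2 = 0.0
            dprime = 0.0
            mono = 1.0
        else:
            r2 = D * D / denom
            if D >= 0:
                dmax = min(f1 * (1.0 - f2), (1.0 - f1) * f2)
            else:
                dmax = min(f1 * f2, (1.0 - f1) * (1.0 - f2))
            dprime = D / dmax if dmax > 1e-12 else 0.0
            mono = 0.0
        out[p, 0] = h[0]
        out[p, 1] = h[1]
        out[p, 2] = h[2]
        out[p, 3] = h[3]
        out[p, 4] = D
        out[p, 5] = dprime
        out[p, 6] = r2
        out[p, 7] = mono
    return out


def pair_r2_batch(
    gl: np.ndarray,
    pairs: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> np.ndarray:
    """EM haplotype frequencies and r^2 for many site pairs at once.

    ``gl`` is the (S, N, 3) likelihood array; ``pairs`` an integer (P, 2)
    array of site row indices.  Returns a (P, 8) array of columns
    (h_AB, h_Ab, h_aB, h_ab, D, D', r^2, monomorphic_flag).
    """
    gl = np.ascontiguousarray(gl, dtype=np.float64)
    pairs = np.ascontiguousarray(pairs, dtype=np.int64)
    if pairs.size == 0:
        return np.zeros((0, 8))
    return _pair_em_kernel(gl, pairs, tol, max_iter)


def pair_r2_em(gl_a: np.ndarray, gl_b: np.ndarray, distance: int = 0,
               site_a: int = 0, site_b: int = 1) -> PairLD:
    """Two-locus EM for a single site pair (convenience wrapper)."""
    gl = np.stack([np.asarray(gl_a, float), np.asarray(gl_b, float)])
    gl /= gl.sum(axis=2, keepdims=True)
    row = pair_r2_batch(gl, np.array([[0, 1]]))[0]
    return PairLD(
        site_a=site_a,
        site_b=site_b,
        distance=distance,
        hap_freq=row[:4].copy(),
        D=row[4],
        D_prime=row[5],
        r2=row[6],
        monomorphic=bool(row[7]),
    )


# ---------------------------------------------------------------------------
# LD decay


@dataclass
class LdDecayFit:
    """Least-squares fit of r^2(d) = r2_0 exp(-d / tau) + c on binned data."""

    tau: float
    r2_0: float
    c: float
    half_decay_bp: float
    bins: pd.DataFrame
    degenerate: bool = False


def ld_decay(distances, r2, max_dist: float = 100_000, bin_bp: float = 1_000) -> LdDecayFit:
    """Bin r^2 by distance and fit an exponential decay.

    The half-decay distance is where the fitted curve falls halfway from its
    intercept r2_0 + c to its asymptote c, i.e. tau * ln 2.  A flat profile
    (vanishing fitted amplitude or unidentifiable tau) is flagged degenerate.
    """
    distances = np.asarray(distances, float)
    r2 = np.asarray(r2, float)
    keep = distances <= max_dist
    distances, r2 = distances[keep], r2[keep]
    idx = (distances // bin_bp).astype(int)
    df = pd.DataFrame({"bin": idx, "r2": r2})
    bins = df.groupby("bin")["r2"].agg(["mean", "count"]).reset_index()
    bins["dist"] = (bins["bin"] + 0.5) * bin_bp
    if len(bins) < 3:
        raise ValueError("need >= 3 non-empty distance bins to fit decay")
    d = bins["dist"].to_numpy()
    y = bins["mean"].to_numpy()

    def model(d, r0, tau, c):
        return r0 * np.exp(-d / tau) + c

    spread = y.max() - y.min()
    if spread < 1e-4:
        return LdDecayFit(np.nan, 0.0, float(y.mean()), np.nan, bins, degenerate=True)
    try:
        popt, _ = curve_fit(
            model,
            d,
            y,
            p0=[max(spread, 1e-3), max_dist / 5.0, max(y.min(), 0.0)],
            bounds=([0.0, 1.0, 0.0], [1.0, 1e9, 1.0]),
            maxfev=10_000,
        )
    except RuntimeError:
        return LdDecayFit(np.nan, np.nan, np.nan, np.nan, bins, degenerate=True)
    r0, tau, c = popt
    degenerate = r0 < 1e-3 or tau > 50 * max_dist
    return LdDecayFit(
        tau=float(tau),
        r2_0=float(r0),
        c=float(c),
        half_decay_bp=float(tau * np.log(2.0)),
        bins=bins,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Graph pruning


def prune_linked(
    positions: np.ndarray,
    pairs: np.ndarray,
    weights: np.ndarray,
    min_weight: float = 0.4,
    max_dist: float = 15_000,
) -> np.ndarray:
    """Greedy LD pruning: repeatedly drop the most-connected site.

    Edges join site pairs within ``max_dist`` whose r^2 >= ``min_weight``.
    The node with the largest sum of incident edge weights is deleted (ties:
    the lowest genomic position is deleted first) until no edges remain.
    Returns indices of surviving sites in their original order.
    """
    positions = np.asarray(positions)
    pairs = np.asarray(pairs, dtype=int)
    weights = np.asarray(weights, float)
    n = len(positions)
    if pairs.size:
        dist = np.abs(positions[pairs[:, 0]] - positions[pairs[:, 1]])
        keep = (weights >= min_weight) & (dist <= max_dist)
        pairs, weights = pairs[keep], weights[keep]
    adj: list[dict[int, float]] = [dict() for _ in range(n)]
    for (a, b), w in zip(pairs, weights):
        adj[a][b] = adj[a].get(b, 0.0) + w
        adj[b][a] = adj[b].get(a, 0.0) + w
    strength = np.array([sum(d.values()) for d in adj])
    alive = np.ones(n, bool)
    while True:
        active = np.flatnonzero(alive & (strength > 1e-12))
        if active.size == 0:
            break
        sub = strength[active]
        best = sub.max()
        cand = active[np.isclose(sub, best, rtol=0, atol=1e-12)]
        victim = cand[np.argmin(positions[cand])]
        alive[victim] = False
        for nb, w in adj[victim].items():
            if alive[nb]:
                strength[nb] -= w
        strength[victim] = 0.0
        adj[victim] = {}
    return np.flatnonzero(alive)


# ---------------------------------------------------------------------------
# Windowed heatmap statistic and block detection


@dataclass
class WindowPairMatrix:
    """Quantile-of-r^2 statistic for every window pair on one chromosome."""

    chrom: str
    window: int
    q: float
    stat: np.ndarray  # (W, W), NaN where no pairs
    n_pairs: np.ndarray  # (W, W) int

    @property
    def n_windows(self) -> int:
        return self.stat.shape[0]


def window_pair_matrix(
    positions_a: np.ndarray,
    positions_b: np.ndarray,
    r2: np.ndarray,
    window: int = 250_000,
    q: float = 0.98,
    chrom: str = "chr",
    n_windows: int | None = None,
) -> WindowPairMatrix:
    """Aggregate SNP-pair r^2 into a symmetric window-pair quantile matrix.

    ``positions_a/b`` are the 1-based positions of each pair's two SNPs.
    Cell (i, j) holds the q-quantile (linear interpolation) of r^2 over
    pairs with one SNP in window i and one in window j; empty cells are NaN.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    pa = (np.asarray(positions_a) - 1) // window
    pb = (np.asarray(positions_b) - 1) // window
    r2 = np.asarray(r2, float)
    W = n_windows if n_windows is not None else (int(max(pa.max(), pb.max())) + 1 if r2.size else 0)
    stat = np.full((W, W), np.nan)
    n_pairs = np.zeros((W, W), dtype=int)
    lo = np.minimum(pa, pb)
    hi = np.maximum(pa, pb)
    order = np.lexsort((hi, lo))
    lo, hi, r2s = lo[order], hi[order], r2[order]
    key = lo * W + hi
    starts = np.flatnonzero(np.r_[True, np.diff(key) != 0])
    bounds = np.r_[starts, len(key)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        i, j = int(lo[s]), int(hi[s])
        v = float(np.quantile(r2s[s:e], q))
        stat[i, j] = stat[j, i] = v
        n_pairs[i, j] = n_pairs[j, i] = e - s
    return WindowPairMatrix(chrom=chrom, window=window, q=q, stat=stat, n_pairs=n_pairs)


@dataclass
class HaploblockRegion:
    """A candidate inversion interval with its LD evidence and status."""

    chrom: str
    start: int
    end: int
    mean_stat: float = np.nan
    n_windows: int = 0
    detected: bool = True
    refined: bool = False
    oriented: bool = False
    orientation: str | None = None  # which homokaryotype side is inverted
    ld_interval: tuple[int, int] | None = None
    group_hobs_means: dict | None = None

    @property
    def region(self) -> RegionRecord:
        return RegionRecord(self.chrom, self.start, self.end, label="haploblock")

    @property
    def span(self) -> int:
        return self.end - self.start


def _square_density(B, V, s, e):
    """(n_on, n_valid, n_cells) among cells i<j in [s,e] with j - i >= 2."""
    n_on = n_valid = n_cells = 0
    for i in range(s, e - 1):
        for j in range(i + 2, e + 1):
            n_cells += 1
            if V[i, j]:
                n_valid += 1
                if B[i, j]:
                    n_on += 1
    return n_on, n_valid, n_cells


def detect_haploblocks(
    matrix: WindowPairMatrix,
    r2_min: float = 0.6,
    density: float = 0.6,
    min_span: int = 1_000_000,
    min_valid_frac: float = 0.5,
) -> list[HaploblockRegion]:
    """Call high-LD squares along the diagonal of the window-pair matrix.

    Cells are binarized at ``r2_min``; from each start window the end is
    extended while, among non-missing cells with window separation >= 2
    inside the square, at least ``min_valid_frac`` of cells are non-missing
    and the ON fraction stays >= ``density``.  Maximal non-nested intervals
    with span >= ``min_span`` are emitted, merging intervals that overlap by
    at least one window.
    """
    stat = matrix.stat
    W = matrix.n_windows
    V = ~np.isnan(stat)
    B = V & (stat >= r2_min)
    candidates = []
    for s in range(W):
        e = s
        best_e = None
        # incremental growth; recompute counts by delta on the added column
        n_on = n_valid = n_cells = 0
        while e + 1 < W:
            e += 1
            for i in range(s, e - 1):
                n_cells += 1
                if V[i, e]:
                    n_valid += 1
                    if B[i, e]:
                        n_on += 1
            if n_cells == 0:
                continue
            if n_valid == 0 or n_valid < min_valid_frac * n_cells:
                break
            if n_on < density * n_valid:
                break
            best_e = e
        if best_e is not None and (best_e - s + 1) * matrix.window >= min_span:
            candidates.append((s, best_e))
    # maximal, non-nested
    candidates.sort()
    kept: list[list[int]] = []
    for s, e in candidates:
        if any(s >= ks and e <= ke for ks, ke in kept):
            continue
        kept = [[ks, ke] for ks, ke in kept if not (ks >= s and ke <= e)]
        kept.append([s, e])
    kept.sort()
    # merge intervals overlapping by >= 1 window
    merged: list[list[int]] = []
    for s, e in kept:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    def _edge_on_frac(col, lo, hi):
        cells = [i for i in range(lo, hi + 1) if abs(i - col) >= 2]
        valid = [i for i in cells if V[min(i, col), max(i, col)]]
        if not valid:
            return 0.0
        return sum(B[min(i, col), max(i, col)] for i in valid) / len(valid)

    # trim boundary windows whose own cross-column is mostly OFF: the greedy
    # growth can smear past a sharp edge before the square density drops
    trimmed = []
    for s, e in merged:
        while e - s >= 2 and _edge_on_frac(e, s, e) < density:
            e -= 1
        while e - s >= 2 and _edge_on_frac(s, s, e) < density:
            s += 1
        if (e - s + 1) * matrix.window >= min_span:
            trimmed.append([s, e])
    merged = trimmed
    blocks = []
    for s, e in merged:
        n_on, n_valid, _ = _square_density(B, V, s, e)
        sub = stat[s : e + 1, s : e + 1]
        blocks.append(
            HaploblockRegion(
                chrom=matrix.chrom,
                start=s * matrix.window,
                end=(e + 1) * matrix.window,
                mean_stat=float(np.nanmean(sub)) if np.isfinite(sub).any() else np.nan,
                n_windows=e - s + 1,
            )
        )
    return blocks


def ld_window_scan(
    ds: GLDataset,
    site_table: pd.DataFrame,
    window: int = 250_000,
    q: float = 0.98,
    subsample: float = 0.5,
    seed: int = 0,
    max_pairs_per_cell: int = 36,
    chrom: str | None = None,
    chrom_length: int | None = None,
) -> WindowPairMatrix:
    """Full-chromosome window-pair LD scan from a called SNP table.

    SNPs are subsampled at the given fraction (seeded), and within every
    window pair at most ``max_pairs_per_cell`` SNP pairs are drawn for the
    EM r^2 kernel; the quantile statistic is insensitive to this cap while
    keeping the pair count desk-scale.
    """
    rng = np.random.default_rng(seed)
    if chrom is None:
        chrom = site_table["chromo"].iloc[0]
    tab = site_table[site_table["chromo"] == chrom]
    idx = tab["site_index"].to_numpy()
    pos = tab["position"].to_numpy()
    if subsample < 1.0:
        keep = rng.uniform(size=len(idx)) < subsample
        idx, pos = idx[keep], pos[keep]
    win = (pos - 1) // window
    length = chrom_length if chrom_length is not None else int(pos.max())
    W = int((length - 1) // window) + 1
    members = [np.flatnonzero(win == w) for w in range(W)]
    chunks = []
    for i in range(W):
        mi = members[i]
        if mi.size == 0:
            continue
        for j in range(i, W):
            mj = members[j]
            if mj.size == 0:
                continue
            if i == j:
                if mi.size < 2:
                    continue
                a, b = np.triu_indices(mi.size, k=1)
                total = a.size
                if total > max_pairs_per_cell:
                    sel = rng.choice(total, size=max_pairs_per_cell, replace=False)
                    a, b = a[sel], b[sel]
                chunks.append(np.column_stack([mi[a], mi[b]]))
            else:
                total = mi.size * mj.size
                if total > max_pairs_per_cell:
                    flat = rng.choice(total, size=max_pairs_per_cell, replace=False)
                else:
                    flat = np.arange(total)
                chunks.append(
                    np.column_stack([mi[flat // mj.size], mj[flat % mj.size]])
                )
    pairs_local = (
        np.concatenate(chunks).astype(np.int64) if chunks else np.zeros((0, 2), np.int64)
    )
    if pairs_local.size == 0:
        return WindowPairMatrix(chrom, window, q, np.full((W, W), np.nan),
                                np.zeros((W, W), int))
    res = pair_r2_batch(ds.gl, idx[pairs_local])
    return window_pair_matrix(
        pos[pairs_local[:, 0]],
        pos[pairs_local[:, 1]],
        res[:, 6],
        window=window,
        q=q,
        chrom=chrom,
        n_windows=W,
    )
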