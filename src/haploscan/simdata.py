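"""Synthetic cohorts with a planted inversion polymorphism.

The generator emulates the data structure of a low-coverage (~3x) whole-
genome study of small, isolated stream populations in which a subset of
demes segregates a large chromosomal inversion:

* standard (STD) haplotypes are recombinant mosaics of a small founder pool,
  giving linkage disequilibrium that decays exponentially with distance;
* inverted (INV) haplotypes descend from a single founder carrying a set of
  private marker mutations inside the inversion interval.  Recombination
  with STD backgrounds is suppressed inside the interval (hard rejection,
  no gene flux) and free outside it, so the derived arrangement carries
  essentially no diversity inside the interval -- the signature by which the
  derived homokaryotype is recognized;
* per-site read counts are Poisson with a symmetric per-read error, and
  genotype-likelihood triplets are computed by the same likelihood model the
  analysis uses;
* deme-level environmental covariates are partially coupled to the deme's
  arrangement frequency;
* mitochondrial haplotypes form a star radiating from a central node by a
  small number of mutational steps, with carrier individuals deliberately
  seeded into haplotypes shared with non-carriers.

Ground truth for every downstream stage is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gl_engine
from .gtio import GLDataset, RegionRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_env",
    "simulate_mito",
    "recomb_rate_for_ld_scale",
]

_BASES = np.array(list("ACGT"))

#: e-folding distance (bp) of the r^2 decay the default preset reproduces.
DEFAULT_LD_SCALE_BP = 15_000


def recomb_rate_for_ld_scale(ld_scale_bp: float, chrom_length: int) -> float:
    """Mosaic breakpoint count per chromosome giving an r^2 e-folding scale.

    Two sites at distance d share a founder segment with probability
    exp(-lambda d), and r^2 inherits the square of that factor, so the
    e-folding scale of r^2 is 1/(2 lambda); the expected number of
    breakpoints per chromosome is lambda * L.
    """
    return chrom_length / (2.0 * ld_scale_bp)


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic cohort."""

    n_demes: int = 9
    n_per_deme: int = 22
    chrom_length: int = 40_000_000
    n_sites: int = 20_000
    chrom: str = "chr1"
    inversion_interval: tuple[int, int] = (14_000_000, 32_000_000)
    inversion_freq_per_deme: tuple[float, ...] = (
        0.35, 0.3, 0.25, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
    )
    n_std_founders: int = 8
    n_inv_founder_mutations: int = 2500
    #: Dirichlet concentration of per-deme founder sampling weights; smaller
    #: values mean stronger drift between demes (genome-wide background FST),
    #: None for a panmictic founder pool.
    founder_weight_concentration: float | None = 1.0
    recomb_rate: float | None = None  # default derived from the 15 kb LD scale
    mean_depth: float = 3.0
    seq_error: float = 0.01
    env_effect: float = 1.0
    mito_length: int = 16_624
    n_mito_haplotypes: int = 30
    mito_step_range: tuple[int, int] = (1, 7)
    seed: int = 0

    def __post_init__(self):
        if self.recomb_rate is None:
            self.recomb_rate = recomb_rate_for_ld_scale(
                DEFAULT_LD_SCALE_BP, self.chrom_length
            )
        start, end = self.inversion_interval
        if not (0 <= start < end <= self.chrom_length):
            raise ValueError("inversion_interval must lie within [0, chrom_length)")
        if len(self.inversion_freq_per_deme) != self.n_demes:
            raise ValueError("inversion_freq_per_deme length must equal n_demes")
        if any(not 0 <= q <= 1 for q in self.inversion_freq_per_deme):
            raise ValueError("inversion frequencies must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 < self.seq_error < 0.5:
            raise ValueError("seq_error must lie in (0, 0.5)")

    @property
    def n_individuals(self) -> int:
        return self.n_demes * self.n_per_deme

    @property
    def inversion_region(self) -> RegionRecord:
        s, e = self.inversion_interval
        return RegionRecord(self.chrom, s, e, label="inversion_truth")


@dataclass
class SimTruth:
    """Generator ground truth for every downstream stage."""

    true_genotypes: np.ndarray  # sites x individuals, minor(=allele 1) copies
    arrangement_labels: np.ndarray  # individuals x 2, "STD"/"INV"
    karyotype: np.ndarray  # individuals, "STD/STD"/"STD/INV"/"INV/INV"
    deme: np.ndarray  # individuals, deme index
    inversion_interval: tuple[int, int]
    positions: np.ndarray  # 1-based site positions
    site_freq: np.ndarray  # founder-pool allele-1 frequency per site
    inv_marker_sites: np.ndarray  # row indices of INV private-marker sites
    env_table: pd.DataFrame | None = None
    env_effects: dict | None = None
    mito_assignment: np.ndarray | None = None

    @property
    def carrier(self) -> np.ndarray:
        """Individuals carrying at least one INV arrangement."""
        return (self.arrangement_labels == "INV").any(axis=1)

    def deme_inv_freq(self) -> np.ndarray:
        """Realized INV arrangement frequency per deme."""
        inv_count = (self.arrangement_labels == "INV").sum(axis=1)
        demes = np.unique(self.deme)
        return np.array(
            [inv_count[self.deme == d].sum() / (2.0 * (self.deme == d).sum())
             for d in demes]
        )


def _mosaic_haplotypes(rng, founders, positions, n_hap, rate, weights=None):
    """STD haplotypes as founder mosaics with Poisson breakpoints.

    ``weights`` optionally gives per-haplotype founder sampling weights
    (n_hap x n_founders), modelling deme-specific drift in founder makeup.
    """
    n_founders, _ = founders.shape
    length = positions[-1]
    haps = np.empty((n_hap, positions.size), dtype=np.int8)
    for h in range(n_hap):
        n_bp = rng.poisson(rate)
        cuts = np.sort(rng.uniform(0, length, size=n_bp))
        seg_of_site = np.searchsorted(cuts, positions)
        p = None if weights is None else weights[h]
        fids = rng.choice(n_founders, size=n_bp + 1, p=p)
        haps[h] = founders[fids[seg_of_site], np.arange(positions.size)]
    return haps


def simulate_cohort(config: SimConfig) -> tuple[GLDataset, SimTruth]:
    """Generate the cohort: GL dataset with depth layer, plus ground truth."""
    rng = np.random.default_rng(config.seed)
    S, N = config.n_sites, config.n_individuals
    start, end = config.inversion_interval

    positions = np.sort(
        rng.choice(np.arange(1, config.chrom_length + 1), size=S, replace=False)
    )
    inside = (positions > start) & (positions <= end)
    any_inv = any(q > 0 for q in config.inversion_freq_per_deme)
    if any_inv and not inside.any():
        raise ValueError("inversion interval contains no sites")

    # founder pool: per-site allele-1 frequency, then Bernoulli founder alleles
    site_freq = rng.uniform(0.1, 0.9, size=S)
    founders = (
        rng.uniform(size=(config.n_std_founders, S)) < site_freq
    ).astype(np.int8)

    # INV founder: one draw from the pool distribution plus private markers
    inv_founder = (rng.uniform(size=S) < site_freq).astype(np.int8)
    n_mark = min(config.n_inv_founder_mutations, int(inside.sum()))
    marker_sites = np.sort(
        rng.choice(np.flatnonzero(inside), size=n_mark, replace=False)
    ) if any_inv else np.zeros(0, dtype=int)
    if marker_sites.size:
        founders[:, marker_sites] = 0  # monomorphic ancestral in the STD pool
        inv_founder[marker_sites] = 1
        site_freq[marker_sites] = 0.0

    deme = np.repeat(np.arange(config.n_demes), config.n_per_deme)
    freq = np.asarray(config.inversion_freq_per_deme)[deme]
    arr_inv = rng.uniform(size=(N, 2)) < freq[:, None]

    hap_weights = None
    if config.founder_weight_concentration is not None:
        alpha = config.founder_weight_concentration
        deme_w = rng.dirichlet(
            np.full(config.n_std_founders, alpha), size=config.n_demes
        )
        hap_weights = np.repeat(deme_w[deme], 2, axis=0)
    haps = _mosaic_haplotypes(
        rng, founders, positions, 2 * N, config.recomb_rate, hap_weights
    )
    haps = haps.reshape(N, 2, S)
    # inside the interval INV copies are clones of the single INV founder;
    # outside it they recombine freely with the STD pool (already mosaics)
    haps[:, :, inside] = np.where(
        arr_inv[:, :, None], inv_founder[inside][None, None, :], haps[:, :, inside]
    )
    genotypes = haps.sum(axis=1).T.astype(np.int8)  # sites x individuals

    depth = rng.poisson(config.mean_depth, size=(S, N))
    eps = config.seq_error
    p_read1 = np.array([eps, 0.5, 1.0 - eps])[genotypes]
    n1 = rng.binomial(depth, p_read1)
    n0 = depth - n1
    gl = gl_engine.genotype_likelihoods_from_counts(n0, n1, eps)

    ref_idx = rng.integers(0, 4, size=S)
    alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4
    sites = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "major": _BASES[ref_idx],
            "minor": _BASES[alt_idx],
        }
    )
    individuals = [f"d{d}_i{i}" for d, i in zip(deme, np.arange(N) % config.n_per_deme)]
    ds = GLDataset(sites=sites, individuals=individuals, gl=gl, depth=depth)

    karyo = np.array(
        ["INV/INV" if a and b else ("STD/INV" if a or b else "STD/STD")
         for a, b in arr_inv]
    )
    labels = np.where(arr_inv, "INV", "STD")
    truth = SimTruth(
        true_genotypes=genotypes,
        arrangement_labels=labels,
        karyotype=karyo,
        deme=deme,
        inversion_interval=(start, end),
        positions=positions,
        site_freq=site_freq,
        inv_marker_sites=marker_sites,
    )
    return ds, truth


# deme covariates: (base, signed coupling to INV frequency, noise sd)
_ENV_MODEL = {
    "temperature": (14.0, +3.0, 1.2),
    "pH": (7.0, -0.4, 0.25),
    "streamflow": (0.8, -0.5, 0.35),
}

_MAX_ENV_CORR = 0.70
_ENV_ATTEMPTS = 100


def simulate_env(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Deme-level covariates coupled to the deme inversion frequency.

    Each covariate is base + env_effect * coupling * freq + Gaussian noise,
    with signs chosen so inversion demes run warmer and slower-flowing.
    Noise is redrawn (up to 100 attempts) until all pairwise Pearson
    correlations among covariates are < 0.70, mirroring the collinearity
    screen applied before the redundancy analysis.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    freq = truth.deme_inv_freq()
    n = len(freq)
    for _ in range(_ENV_ATTEMPTS):
        cols = {}
        for name, (base, coupling, sd) in _ENV_MODEL.items():
            cols[name] = (
                base
                + config.env_effect * coupling * freq
                + rng.normal(0.0, sd, size=n)
            )
        table = pd.DataFrame(cols)
        corr = table.corr().to_numpy()
        # with < 3 demes every pair of covariates correlates at exactly +-1,
        # so the collinearity screen is only meaningful from 3 demes up
        if n < 3 or np.all(
            np.abs(corr[np.triu_indices(len(cols), k=1)]) < _MAX_ENV_CORR
        ):
            table.insert(0, "deme", np.arange(n))
            truth.env_table = table
            truth.env_effects = {
                name: config.env_effect * coupling
                for name, (_, coupling, _) in _ENV_MODEL.items()
            }
            return table
    raise RuntimeError(
        f"could not satisfy pairwise |r| < {_MAX_ENV_CORR} in {_ENV_ATTEMPTS} attempts"
    )


def env_per_individual(table: pd.DataFrame, truth: SimTruth) -> pd.DataFrame:
    """Broadcast deme-level covariates to individuals (deme membership)."""
    rows = table.set_index("deme").loc[truth.deme].reset_index()
    rows.insert(0, "individual", np.arange(len(truth.deme)))
    return rows


def simulate_mito(config: SimConfig, truth: SimTruth):
    """Star-like mitochondrial haplotypes and per-individual sequences.

    One central haplotype; every other haplotype differs from it by
    u ~ Uniform{mito_step_range} substitutions at globally distinct
    positions (so the radiation is additive).  Haplotype membership is
    assigned with geometrically decaying weights, then adjusted so that at
    least two haplotypes contain both inversion carriers and non-carriers
    whenever both classes exist.

    Returns (records, assignment) where records is a list of
    (individual_id, sequence) and assignment maps individuals to haplotype
    indices (0 = central).
    """
    if config.n_mito_haplotypes < 2:
        raise ValueError("need at least 2 mitochondrial haplotypes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    H = config.n_mito_haplotypes
    lo, hi = config.mito_step_range
    steps = rng.integers(lo, hi + 1, size=H - 1)
    if steps.sum() > config.mito_length:
        raise ValueError("mito_length too short for the requested mutational steps")

    central = rng.integers(0, 4, size=config.mito_length)
    mut_pos = rng.choice(config.mito_length, size=int(steps.sum()), replace=False)
    seqs = [central]
    k = 0
    for u in steps:
        s = central.copy()
        for p in mut_pos[k : k + u]:
            s[p] = (s[p] + rng.integers(1, 4)) % 4
        seqs.append(s)
        k += u
    hap_strings = ["".join(_BASES[s]) for s in seqs]

    N = len(truth.karyotype)
    # harmonic frequency profile: one dominant haplotype, a long tail of
    # rare ones, so most configured haplotypes are realized in a ~200-fish
    # cohort
    weights = 1.0 / (1.0 + np.arange(H))
    assignment = rng.choice(H, size=N, p=weights / weights.sum())

    carrier = truth.carrier
    if carrier.any() and (~carrier).any():
        shared = [
            h for h in range(H)
            if carrier[assignment == h].any() and (~carrier[assignment == h]).any()
        ]
        need = 2 - len(shared)
        if need > 0:
            c_idx = np.flatnonzero(carrier)
            n_idx = np.flatnonzero(~carrier)
            rng.shuffle(c_idx)
            rng.shuffle(n_idx)
            for j in range(need):
                h = [h for h in range(H) if h not in shared][j]
                assignment[c_idx[j]] = h
                assignment[n_idx[j]] = h
                shared.append(h)

    individuals = [f"ind{i}" for i in range(N)]
    records = [(individuals[i], hap_strings[assignment[i]]) for i in range(N)]
    truth.mito_assignment = assignment
    return records, assignment


def write_mito_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
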