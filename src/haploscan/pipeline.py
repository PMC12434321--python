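"""End-to-end inversion scan: SNP calling -> LD heatmap -> block calling ->
karyotype clustering -> H_obs orientation and breakpoint refinement.

This is the driver the command line uses; each stage delegates to its
module and all intermediate results are returned for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gl_engine, karyotype, ld_blocks
from .gtio import GLDataset

__all__ = ["InversionScan", "scan_chromosome"]


@dataclass
class InversionScan:
    site_table: pd.DataFrame
    matrix: ld_blocks.WindowPairMatrix
    blocks: list[ld_blocks.HaploblockRegion]
    karyotypes: dict[int, list[karyotype.KaryotypeAssignment]] = field(
        default_factory=dict
    )
    diagnostics: dict[int, dict] = field(default_factory=dict)
    refined: list[ld_blocks.HaploblockRegion] = field(default_factory=list)


def scan_chromosome(
    ds: GLDataset,
    chrom: str | None = None,
    chrom_length: int | None = None,
    snp_pval: float = 1e-6,
    min_maf: float = 0.05,
    min_ind_frac: float = 0.5,
    depth_sd_mult: float = 1.0,
    window: int = 250_000,
    q: float = 0.98,
    subsample: float = 0.5,
    r2_min: float = 0.6,
    density: float = 0.6,
    min_span: int = 1_000_000,
    hobs_window: int = 10_000,
    seed: int = 0,
) -> InversionScan:
    """Run the full indirect inversion-detection chain on one chromosome."""
    if chrom is None:
        chrom = ds.sites["chrom"].iloc[0]
    if ds.depth is not None:
        _filt, mask = gl_engine.depth_filter(
            ds.depth, c=depth_sd_mult,
            min_ind=int(np.ceil(min_ind_frac * ds.n_individuals)),
        )
    else:
        mask = None
    table = gl_engine.call_snps(ds, snp_pval, min_maf, site_mask=mask)
    matrix = ld_blocks.ld_window_scan(
        ds, table, window=window, q=q, subsample=subsample, seed=seed,
        chrom=chrom, chrom_length=chrom_length,
    )
    blocks = ld_blocks.detect_haploblocks(
        matrix, r2_min=r2_min, density=density, min_span=min_span
    )
    scan = InversionScan(site_table=table, matrix=matrix, blocks=blocks)
    for bi, block in enumerate(blocks):
        pca = karyotype.block_pca(ds, table, block)
        assigns, diag = karyotype.cluster_karyotypes(pca.pc(1), ds.individuals)
        scan.karyotypes[bi] = assigns
        scan.diagnostics[bi] = diag
        if not diag["structure"]:
            scan.refined.append(block)
            continue
        profiles = karyotype.hobs_profiles(
            ds, assigns, chrom, site_table=table, window=hobs_window
        )
        if len(profiles) < 3:
            scan.refined.append(block)
            continue
        refined, assigns, _means = karyotype.orient_and_refine(
            block, profiles, assigns
        )
        scan.karyotypes[bi] = assigns
        scan.refined.append(refined)
    return scan
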