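"""Published candidate-inversion regions of the Brook Trout study system.

Four large LD blocks on chromosomes 12, 19, 27 and 31 of the 2.5 Gbp Brook
Trout genome (ASM2944872v1), with the inversion sizes inferred from raw
heterozygosity.  These serve as reference inputs for genome-fraction
arithmetic and for annotating outputs at study scale.
"""

from __future__ import annotations

import pandas as pd

from .gtio import RegionRecord

__all__ = ["candidate_inversions", "genome_fraction_pct", "GENOME_SIZE_MB"]

#: Brook Trout chromosome-level assembly size, in Mb.
GENOME_SIZE_MB = 2500.0

_TABLE = [
    # chromosome, accession, LD block (Mb), inversion size (Mb)
    ("12", "CM055694.1", 14, 35, 18),
    ("19", "CM055701.1", 22, 39, 12),
    ("27", "CM055709.1", 13, 35, 12),
    ("31", "CM055713.1", 15, 40, 26),
]


def candidate_inversions() -> pd.DataFrame:
    """LD-block intervals and inversion sizes, one row per chromosome."""
    return pd.DataFrame(
        _TABLE,
        columns=["chromosome", "accession", "block_start_mb", "block_end_mb",
                 "inversion_size_mb"],
    )


def block_records() -> list[RegionRecord]:
    return [
        RegionRecord(f"chr{c}", int(s * 1e6), int(e * 1e6), label=f"block_chr{c}")
        for c, _acc, s, e, _size in _TABLE
    ]


def genome_fraction_pct(sizes_mb=None, genome_mb: float = GENOME_SIZE_MB) -> float:
    """Percentage of the genome covered by the candidate inversions."""
    if sizes_mb is None:
        sizes_mb = candidate_inversions()["inversion_size_mb"]
    return 100.0 * float(sum(sizes_mb)) / genome_mb
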