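"""Readers and writers for the text formats the pipeline touches.

Three formats are supported, each in its native coordinate convention:

* BEAGLE genotype-likelihood files (one row per site, three likelihood
  columns per individual) with 1-based positions encoded in the marker name;
* site tables (TSV, ``.mafs``-style, 1-based positions);
* BED intervals (0-based, half-open).

All readers validate and reject malformed input rather than repairing it
silently.  Gzip compression is sniffed from the ``.gz`` extension.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GLDataset",
    "RegionRecord",
    "read_beagle",
    "write_beagle",
    "read_sitetable",
    "write_sitetable",
    "read_bed",
    "write_bed",
]

_VALID_ALLELES = frozenset("ACGT")
_ALLELE_CODES = {"0": "A", "1": "C", "2": "G", "3": "T"}

SITETABLE_COLUMNS = ["chromo", "position", "major", "minor", "freq_em", "pvalue", "n_ind"]


class FormatError(ValueError):
    """Malformed input file."""


def _open(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


@dataclass
class RegionRecord:
    """A genomic interval in 0-based, half-open coordinates."""

    chrom: str
    start: int
    end: int
    label: str | None = None
    score: float | None = None

    def __post_init__(self):
        self.start = int(self.start)
        self.end = int(self.end)
        if not 0 <= self.start < self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def contains(self, pos_1based: int) -> bool:
        """Whether a 1-based site position falls inside this interval."""
        return self.start < pos_1based <= self.end

    def jaccard(self, other: "RegionRecord") -> float:
        """Jaccard overlap of two intervals on the same chromosome."""
        if self.chrom != other.chrom:
            return 0.0
        inter = max(0, min(self.end, other.end) - max(self.start, other.start))
        union = self.span + other.span - inter
        return inter / union if union else 0.0


@dataclass
class GLDataset:
    """Genotype-likelihood triplets for every site x individual.

    ``gl[s, i]`` holds the likelihoods of the three genotypes
    (major/major, major/minor, minor/minor), normalized to sum to one: the
    normalization constant cancels in every downstream likelihood ratio.
    ``sites`` is a DataFrame with columns ``chrom, pos, major, minor``
    (positions 1-based).  ``depth`` is an optional per-site, per-individual
    read-count layer.
    """

    sites: pd.DataFrame
    individuals: list[str]
    gl: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self):
        self.gl = np.asarray(self.gl, dtype=float)
        n_sites = len(self.sites)
        n_ind = len(self.individuals)
        if self.gl.shape != (n_sites, n_ind, 3):
            raise ValueError(
                f"gl shape {self.gl.shape} != ({n_sites}, {n_ind}, 3)"
            )
        if np.any(self.gl < 0):
            raise ValueError("negative genotype likelihood")
        tot = self.gl.sum(axis=2)
        if np.any(tot <= 0):
            raise ValueError("all-zero likelihood triplet")
        self.gl = self.gl / tot[:, :, None]
        for col in ("chrom", "pos", "major", "minor"):
            if col not in self.sites.columns:
                raise ValueError(f"sites missing column {col!r}")
        bad = ~self.sites["major"].isin(_VALID_ALLELES) | ~self.sites["minor"].isin(
            _VALID_ALLELES
        )
        if bad.any():
            raise ValueError("alleles must be one of A,C,G,T")
        for _, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions not strictly increasing within chromosome")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != (n_sites, n_ind):
                raise ValueError("depth layer shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def subset_sites(self, index) -> "GLDataset":
        """New dataset restricted to the given site row indices (in order)."""
        index = np.asarray(index)
        return GLDataset(
            sites=self.sites.iloc[index].reset_index(drop=True),
            individuals=list(self.individuals),
            gl=self.gl[index],
            depth=None if self.depth is None else self.depth[index],
        )

    def subset_individuals(self, which) -> "GLDataset":
        which = np.asarray(which)
        if which.dtype == bool:
            which = np.flatnonzero(which)
        return GLDataset(
            sites=self.sites.copy(),
            individuals=[self.individuals[i] for i in which],
            gl=self.gl[:, which],
            depth=None if self.depth is None else self.depth[:, which],
        )

    def sites_in(self, region: RegionRecord) -> np.ndarray:
        """Row indices of sites inside a region (0-based half-open bp)."""
        m = (
            (self.sites["chrom"] == region.chrom)
            & (self.sites["pos"] > region.start)
            & (self.sites["pos"] <= region.end)
        )
        return np.flatnonzero(m.to_numpy())


# ---------------------------------------------------------------------------
# BEAGLE genotype-likelihood files


def _parse_allele(tok: str, lineno: int) -> str:
    tok = tok.upper()
    if tok in _ALLELE_CODES:
        return _ALLELE_CODES[tok]
    if tok in _VALID_ALLELES:
        return tok
    raise FormatError(f"line {lineno}: invalid allele {tok!r}")


def read_beagle(path, depth_path=None) -> GLDataset:
    """Read a BEAGLE GL file (optionally gzipped).

    Header: ``marker allele1 allele2 Ind0 Ind0 Ind0 ...`` with one marker
    per row formatted ``chrom_pos`` and three likelihood columns per
    individual.  Alleles may be letters or the 0-3 numeric encoding.
    """
    with _open(path, "r") as fh:
        header = fh.readline().split()
        if len(header) < 6 or header[0] != "marker":
            raise FormatError("line 1: not a BEAGLE header")
        body = (len(header) - 3)
        if body % 3:
            raise FormatError("line 1: individual columns not a multiple of 3")
        individuals = header[3::3]
        chroms, positions, majors, minors, rows = [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != len(header):
                raise FormatError(
                    f"line {lineno}: ragged row ({len(tok)} fields, expected {len(header)})"
                )
            marker = tok[0]
            chrom, _, pos = marker.rpartition("_")
            if not chrom or not pos.isdigit():
                raise FormatError(f"line {lineno}: malformed marker {marker!r}")
            chroms.append(chrom)
            positions.append(int(pos))
            majors.append(_parse_allele(tok[1], lineno))
            minors.append(_parse_allele(tok[2], lineno))
            try:
                rows.append([float(x) for x in tok[3:]])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric likelihood") from exc
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "major": majors, "minor": minors}
    )
    gl = np.asarray(rows, dtype=float).reshape(len(rows), len(individuals), 3)
    try:
        ds = GLDataset(sites=sites, individuals=list(individuals), gl=gl)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc
    if depth_path is not None:
        ds.depth = read_depth(depth_path, ds)
    return ds


def write_beagle(ds: GLDataset, path) -> None:
    with _open(path, "w") as fh:
        cols = ["marker", "allele1", "allele2"]
        for ind in ds.individuals:
            cols += [ind] * 3
        fh.write("\t".join(cols) + "\n")
        flat = ds.gl.reshape(ds.n_sites, -1)
        for s in range(ds.n_sites):
            row = ds.sites.iloc[s]
            fields = [f"{row.chrom}_{row.pos}", row.major, row.minor]
            fields += [f"{v:.9g}" for v in flat[s]]
            fh.write("\t".join(fields) + "\n")


def read_depth(path, ds: GLDataset | None = None) -> np.ndarray:
    """Per-site, per-individual read depth TSV (marker + one column each)."""
    df = pd.read_csv(path, sep="\t")
    depth = df.iloc[:, 1:].to_numpy(dtype=int)
    if ds is not None and depth.shape != (ds.n_sites, ds.n_individuals):
        raise FormatError("depth table does not match GL dataset dimensions")
    return depth


def write_depth(ds: GLDataset, path) -> None:
    if ds.depth is None:
        raise ValueError("dataset has no depth layer")
    markers = ds.sites["chrom"].astype(str) + "_" + ds.sites["pos"].astype(str)
    df = pd.DataFrame(ds.depth, columns=ds.individuals)
    df.insert(0, "marker", markers.to_numpy())
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Site tables (.mafs-style TSV)


def read_sitetable(path) -> pd.DataFrame:
    df = pd.read_csv(_open(path, "r"), sep="\t")
    missing = [c for c in SITETABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"site table missing columns {missing}")
    bad = (df["freq_em"] < 0) | (df["freq_em"] > 0.5)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(
            f"line {line}: freq_em outside [0, 0.5] after minor-allele orientation"
        )
    return df


def write_sitetable(table: pd.DataFrame, path) -> None:
    cols = [c for c in SITETABLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    with _open(path, "w") as fh:
        table[cols].to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals


def read_bed(path) -> list[RegionRecord]:
    records = []
    with _open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0].startswith(("#", "track", "browser")):
                continue
            if len(tok) < 3 or len(tok) > 5:
                raise FormatError(f"line {lineno}: expected 3-5 BED columns")
            try:
                start, end = int(tok[1]), int(tok[2])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            label = tok[3] if len(tok) > 3 else None
            score = float(tok[4]) if len(tok) > 4 else None
            try:
                records.append(RegionRecord(tok[0], start, end, label, score))
            except FormatError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return records


def write_bed(records: Sequence[RegionRecord], path) -> None:
    records = sorted(records, key=lambda r: (r.chrom, r.start))
    with _open(path, "w") as fh:
        for r in records:
            fields = [r.chrom, str(r.start), str(r.end)]
            if r.label is not None or r.score is not None:
                fields.append(r.label if r.label is not None else ".")
            if r.score is not None:
                fields.append(f"{r.score:.6g}")
            fh.write("\t".join(fields) + "\n")
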