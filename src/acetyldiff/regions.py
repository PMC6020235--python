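"""Interval algebra for consensus-region construction from per-sample peak calls.

Coordinates are 0-based, half-open (BED convention) throughout.  The consensus
procedure stretches every per-sample peak to at least ``min_len`` bp, merges
the pooled peaks by their outermost coordinates, and keeps only regions
supported by at least ``min_support`` independent samples on autosomes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_AUTOSOME_RE = re.compile(r"^chr([1-9]|1[0-9]|2[0-2])$")


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"malformed region {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        """True iff the two regions share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class RegionSet:
    """An ordered collection of regions backed by a DataFrame.

    The frame always has columns ``chrom``, ``start``, ``end`` and is kept
    sorted by (chrom, start, end); extra per-region attribute columns
    (``sample_support``, ``status``, ``region_id``, ...) ride along.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=["chrom", "start", "end"])
        missing = {"chrom", "start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"RegionSet frame missing columns: {sorted(missing)}")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and not ((df["start"] >= 0) & (df["start"] < df["end"])).all():
            bad = df[~((df["start"] >= 0) & (df["start"] < df["end"]))]
            raise ValueError(f"malformed regions (start<0 or start>=end):\n{bad.head()}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    @classmethod
    def from_regions(cls, regions: Iterable[GenomicRegion]) -> "RegionSet":
        rows = [(r.chrom, r.start, r.end) for r in regions]
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicRegion(row.chrom, int(row.start), int(row.end))

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]]
        b = other.df[["chrom", "start", "end"]]
        return a.equals(b)

    # ---------------------------------------------------------------- I/O
    @classmethod
    def read_bed(cls, path: str | Path) -> "RegionSet":
        """Read a BED3+ file (tab-separated, header-less; track lines skipped)."""
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
                try:
                    rows.append((parts[0], int(parts[1]), int(parts[2])))
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from None
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def write_bed(self, path: str | Path, extra_cols: Sequence[str] = ()) -> None:
        cols = ["chrom", "start", "end", *extra_cols]
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column (chrom, length) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ------------------------------------------------------------------ algebra
def stretch_region(
    r: GenomicRegion, min_len: int = 2000, chrom_length: int | None = None
) -> GenomicRegion:
    """Extend ``r`` symmetrically about its midpoint to at least ``min_len`` bp.

    Regions already >= min_len are returned unchanged.  If the symmetric
    window would cross a chromosome boundary it is shifted inside
    [0, chrom_length] preserving length; it is truncated only when the
    chromosome itself is shorter than min_len.
    """
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    if r.length >= min_len:
        return r
    mid2 = r.start + r.end  # 2 * midpoint, avoids fractional arithmetic
    start = (mid2 - min_len) // 2
    end = start + min_len
    if start < 0:
        start, end = 0, min_len
    if chrom_length is not None:
        if chrom_length < min_len:
            return GenomicRegion(r.chrom, 0, chrom_length)
        if end > chrom_length:
            start, end = chrom_length - min_len, chrom_length
        if start < 0:
            start, end = 0, min_len
    return GenomicRegion(r.chrom, start, end)


def stretch_regions(
    rs: RegionSet, min_len: int, chrom_sizes: Mapping[str, int] | None = None
) -> RegionSet:
    """Vectorized :func:`stretch_region` over a whole RegionSet."""
    df = rs.df.copy()
    if not len(df):
        return RegionSet(df)
    length = df["end"] - df["start"]
    short = length < min_len
    mid2 = df["start"] + df["end"]
    new_start = np.where(short, (mid2 - min_len) // 2, df["start"])
    new_end = np.where(short, new_start + min_len, df["end"])
    neg = new_start < 0
    new_end = np.where(neg, new_end - new_start, new_end)
    new_start = np.where(neg, 0, new_start)
    if chrom_sizes is not None:
        clen = df["chrom"].map(chrom_sizes).to_numpy()
        over = short & (new_end > clen)
        new_start = np.where(over, np.maximum(clen - min_len, 0), new_start)
        new_end = np.where(over, clen, new_end)
    df["start"], df["end"] = new_start, new_end
    return RegionSet(df)


def merge_regions(rs: RegionSet) -> RegionSet:
    """Collapse overlapping regions into maximal intervals by outermost coordinates.

    Two regions merge iff they share >= 1 bp; book-ended regions
    (end == start) stay separate under half-open semantics.
    """
    df = rs.df
    if not len(df):
        return RegionSet()
    out: list[tuple[str, int, int]] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if chrom == cur_chrom and start < cur_end:
            cur_end = max(cur_end, end)
        else:
            if cur_chrom is not None:
                out.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = chrom, start, end
    out.append((cur_chrom, cur_start, cur_end))
    return RegionSet(pd.DataFrame(out, columns=["chrom", "start", "end"]))


def support_count(merged: RegionSet, per_sample: Sequence[RegionSet]) -> RegionSet:
    """Count, per merged region, how many samples contribute an overlapping peak.

    ``per_sample`` must hold the same (stretched) peak sets whose union was
    merged, so every merged region has support >= 1.
    """
    counts = np.zeros(len(merged), dtype=np.int64)
    mdf = merged.df
    by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(), sub.index.to_numpy())
        for chrom, sub in mdf.groupby("chrom", sort=False)
    }
    for sample_rs in per_sample:
        seen = np.zeros(len(merged), dtype=bool)
        for chrom, sub in sample_rs.df.groupby("chrom", sort=False):
            if chrom not in by_chrom:
                continue
            m_start, m_end, m_idx = by_chrom[chrom]
            # merged regions are disjoint & sorted: each peak hits the ones
            # whose start < peak.end and end > peak.start
            lo = np.searchsorted(m_end, sub["start"].to_numpy(), side="right")
            hi = np.searchsorted(m_start, sub["end"].to_numpy(), side="left")
            for a, b in zip(lo, hi):
                if b > a:
                    seen[m_idx[a:b]] = True
        counts += seen
    if len(merged) and counts.min() < 1:
        raise RuntimeError(
            "internal consistency error: merged region with zero sample support"
        )
    out = mdf.copy()
    out["sample_support"] = counts
    return RegionSet(out)


def filter_autosomes(rs: RegionSet) -> RegionSet:
    """Keep regions on chr1..chr22 only."""
    keep = rs.df["chrom"].map(lambda c: bool(_AUTOSOME_RE.match(c)))
    return RegionSet(rs.df[keep])


def build_consensus(
    peak_files: Sequence[str | Path],
    chrom_sizes: Mapping[str, int] | None = None,
    min_len: int = 2000,
    min_support: int = 2,
    autosomes_only: bool = True,
) -> RegionSet:
    """Build the common consensus region list from per-sample peak BEDs.

    Pipeline: stretch each sample's peaks to >= ``min_len`` bp, pool, merge
    by outermost coordinates, keep regions supported by >= ``min_support``
    samples, and (optionally) keep autosomes (chr1..chr22) only.  Region ids
    ``region_00001`` ... are assigned in genomic order.
    """
    if len(peak_files) < 2:
        raise ValueError("build_consensus needs at least two peak files")
    stretched = [
        stretch_regions(RegionSet.read_bed(p), min_len, chrom_sizes) for p in peak_files
    ]
    pooled = RegionSet(pd.concat([s.df for s in stretched], ignore_index=True))
    merged = merge_regions(pooled)
    supported = support_count(merged, stretched)
    keep = supported.df["sample_support"] >= min_support
    result = RegionSet(supported.df[keep])
    if autosomes_only:
        result = filter_autosomes(result)
    df = result.df.copy()
    width = max(5, len(str(max(len(df), 1))))
    df["region_id"] = [f"region_{i+1:0{width}d}" for i in range(len(df))]
    return RegionSet(df)
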