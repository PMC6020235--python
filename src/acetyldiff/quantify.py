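"""Region x sample count matrices: construction from read positions and TSV I/O.

Reads are reduced to their 5' positions; a read is counted for a region when
that position falls inside the half-open interval [start, end).  Consensus
regions are disjoint, so each read is counted at most once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import RegionSet

logger = logging.getLogger(__name__)

VALID_GROUPS = ("case", "control")


@dataclass
class CountMatrix:
    """Non-negative integer counts (features x samples) with group labels."""

    counts: pd.DataFrame  # index = feature ids, columns = sample ids
    groups: pd.Series  # sample id -> "case" | "control"

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            raise ValueError("duplicate feature ids in count matrix")
        if df.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        arr = df.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError("count matrix contains non-integer values")
                df = df.round().astype(np.int64)
                self.counts = df
                arr = df.to_numpy()
            if arr.min() < 0:
                bad = df.columns[(df < 0).any(axis=0)].tolist()
                raise ValueError(f"negative counts in samples {bad}")
        groups = pd.Series(self.groups)
        missing = [s for s in df.columns if s not in groups.index]
        if missing:
            raise ValueError(f"samples missing a group label: {missing}")
        bad = set(groups.loc[df.columns]) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {VALID_GROUPS}")
        self.groups = groups.loc[df.columns]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == "control"]

    def group_indicator(self) -> np.ndarray:
        """1 for case samples, 0 for control, in column order."""
        return (self.groups.to_numpy() == "case").astype(float)

    def write_tsv(self, path: str | Path, feature_col: str = "feature_id") -> None:
        out = self.counts.copy()
        out.index.name = feature_col
        out.to_csv(path, sep="\t")


def count_reads_in_regions(
    regions: RegionSet,
    read_positions: Mapping[str, Sequence[tuple[str, int]]],
    groups: Mapping[str, str],
) -> CountMatrix:
    """Count per-sample 5' read positions falling in each (disjoint) region.

    ``read_positions`` maps sample id -> iterable of (chrom, pos).  Reads on
    chromosomes absent from the region list are ignored (tally logged).
    """
    rdf = regions.df
    feature_ids = (
        rdf["region_id"].tolist()
        if "region_id" in rdf.columns
        else [f"region_{i+1:05d}" for i in range(len(rdf))]
    )
    by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(), sub.index.to_numpy())
        for chrom, sub in rdf.groupby("chrom", sort=False)
    }
    mat = np.zeros((len(rdf), len(read_positions)), dtype=np.int64)
    for j, (sample, reads) in enumerate(read_positions.items()):
        skipped = 0
        reads_df = pd.DataFrame(list(reads), columns=["chrom", "pos"])
        for chrom, sub in reads_df.groupby("chrom", sort=False):
            if chrom not in by_chrom:
                skipped += len(sub)
                continue
            starts, ends, idx = by_chrom[chrom]
            pos = sub["pos"].to_numpy()
            # regions disjoint & sorted: position p is inside region k iff
            # starts[k] <= p < ends[k]
            k = np.searchsorted(starts, pos, side="right") - 1
            ok = (k >= 0) & (pos < ends[np.clip(k, 0, None)])
            hit_idx, hit_counts = np.unique(idx[k[ok]], return_counts=True)
            mat[hit_idx, j] += hit_counts
        if skipped:
            logger.info("sample %s: %d reads on chromosomes outside region list", sample, skipped)
    counts = pd.DataFrame(mat, index=feature_ids, columns=list(read_positions))
    return CountMatrix(counts, pd.Series(dict(groups)))


def read_positions_tsv(path: str | Path) -> list[tuple[str, int]]:
    """Read a 2-column (chrom, pos) TSV of 5' read positions."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"])
    return list(zip(df["chrom"], df["pos"].astype(int)))


def load_count_matrix(
    path: str | Path, groups: Mapping[str, str], feature_col: str | None = None
) -> CountMatrix:
    """Load a TSV count matrix (first column = feature id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if feature_col is not None and df.index.name != feature_col:
        raise ValueError(
            f"{path}: expected feature column {feature_col!r}, found {df.index.name!r}"
        )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric values in sample column {col!r}")
    dup_frac = df.duplicated().mean() if len(df) else 0.0
    if dup_frac > 0.10:
        logger.warning("%.0f%% of rows are exact duplicates", 100 * dup_frac)
    return CountMatrix(df, pd.Series(dict(groups)))
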