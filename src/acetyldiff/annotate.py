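"""Region-gene annotation by TSS proximity and ChIP/RNA integration.

A gene is linked to a region when the region overlaps the +/- ``window``
(default 20 kb) interval around the gene's TSS — equivalently, when the
minimum distance from the TSS to any base of the region is <= window.
Strand is ignored for distance and retained for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegionSet

logger = logging.getLogger(__name__)


@dataclass
class TssCatalog:
    """gene_id -> (chrom, tss, strand); one transcription start per gene."""

    df: pd.DataFrame  # columns: gene_id, chrom, tss, strand

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "tss", "strand"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"TSS catalog missing columns: {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            dup = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids in TSS catalog: {dup[:5]}")
        self.df = self.df.reset_index(drop=True)
        self.df["tss"] = self.df["tss"].astype(np.int64)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TssCatalog":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def annotate_regions(
    regions: RegionSet, tss: TssCatalog, window: int = 20_000
) -> pd.DataFrame:
    """Emit one (region, gene) link per pair with TSS within ``window`` bp.

    Distance is 0 when the TSS lies inside the region, else the gap to the
    nearest region edge.  Regions are expected to carry ``region_id`` and a
    ``direction`` call; genes on chromosomes absent from the region universe
    are skipped (count logged).
    """
    rdf = regions.df
    if "region_id" not in rdf.columns:
        rdf = rdf.copy()
        rdf["region_id"] = [f"region_{i+1:05d}" for i in range(len(rdf))]
    links: list[dict] = []
    region_chroms = set(rdf["chrom"])
    skipped = 0
    by_chrom = {chrom: sub for chrom, sub in rdf.groupby("chrom", sort=False)}
    for chrom, genes in tss.df.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            skipped += len(genes)
            continue
        sub = by_chrom[chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for g in genes.itertuples(index=False):
            # distance from TSS point to [start, end): 0 inside, else edge gap
            d = np.maximum(starts - g.tss, 0) + np.maximum(g.tss - (ends - 1), 0)
            hit = np.flatnonzero(d <= window)
            for k in hit:
                row = sub.iloc[k]
                links.append(
                    {
                        "region_id": row["region_id"],
                        "gene_id": g.gene_id,
                        "distance": int(d[k]),
                        "region_direction": row.get("direction", "ns"),
                        "strand": g.strand,
                    }
                )
    if skipped:
        logger.info("%d TSS on chromosomes outside the region universe skipped", skipped)
    cols = ["region_id", "gene_id", "distance", "region_direction", "strand"]
    return pd.DataFrame(links, columns=cols)


def annotated_gene_sets(links: pd.DataFrame) -> tuple[set, set]:
    """Deduplicated gene sets near hyper- and hypoacetylated regions.

    A gene near both region classes lands in both sets; the conflict list is
    logged.
    """
    near_hyper = set(links.loc[links["region_direction"] == "hyper", "gene_id"])
    near_hypo = set(links.loc[links["region_direction"] == "hypo", "gene_id"])
    conflict = near_hyper & near_hypo
    if conflict:
        logger.info("%d genes link to both hyper and hypo regions: %s",
                    len(conflict), sorted(conflict)[:10])
    return near_hyper, near_hypo


def concordance_analysis(links: pd.DataFrame, rna: pd.DataFrame) -> dict:
    """Compare RNA log2 fold changes of genes near hyper/hypo regions vs all genes.

    Returns the three LFC vectors (all, near hyper, near hypo), their
    medians, and one-sided Wilcoxon rank-sum p-values in the expected
    directions (near-hyper shifted up, near-hypo shifted down).  Linked
    genes missing from the RNA results are logged and excluded.
    """
    near_hyper, near_hypo = annotated_gene_sets(links)
    missing = (near_hyper | near_hypo) - set(rna.index)
    if missing:
        logger.info("%d linked genes missing from RNA results", len(missing))
    all_lfc = rna["log2fc"].dropna()
    hyper_lfc = all_lfc.loc[all_lfc.index.intersection(sorted(near_hyper))]
    hypo_lfc = all_lfc.loc[all_lfc.index.intersection(sorted(near_hypo))]
    def _test(sub: pd.Series, alternative: str) -> float:
        if len(sub) == 0:
            return float("nan")
        return float(
            stats.mannwhitneyu(sub, all_lfc, alternative=alternative).pvalue
        )
    return {
        "all_lfc": all_lfc,
        "near_hyper_lfc": hyper_lfc,
        "near_hypo_lfc": hypo_lfc,
        "median_all": float(all_lfc.median()) if len(all_lfc) else float("nan"),
        "median_near_hyper": float(hyper_lfc.median()) if len(hyper_lfc) else float("nan"),
        "median_near_hypo": float(hypo_lfc.median()) if len(hypo_lfc) else float("nan"),
        "p_hyper_shift_up": _test(hyper_lfc, "greater"),
        "p_hypo_shift_down": _test(hypo_lfc, "less"),
    }


def overlap_gene_lists(
    gene_sets: tuple[set, set], rna_calls: pd.DataFrame
) -> tuple[list, list]:
    """Genes both near a differential region and differentially expressed.

    Returns (hyper & up, hypo & down), each sorted by gene id.
    """
    near_hyper, near_hypo = gene_sets
    up = set(rna_calls.index[rna_calls["direction"] == "up"])
    down = set(rna_calls.index[rna_calls["direction"] == "down"])
    return sorted(near_hyper & up), sorted(near_hypo & down)
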