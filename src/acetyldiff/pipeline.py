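"""End-to-end orchestration: consensus -> differential -> explore -> integrate -> motifs.

`run_all` mirrors the full study workflow on real or simulated inputs and
writes every tabular output plus a summary of the headline counts (total
consensus regions; differential regions hyper/hypo; DE genes up/down;
annotated genes per direction; overlap list sizes; enriched motifs per
direction; linked TFs) and a MANIFEST with sha256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, differential, explore, motifs, quantify, regions
from .simulate import SimulationConfig, simulate_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    peaks: list[str] = field(default_factory=list)
    chip_counts: str | None = None
    rna_counts: str | None = None
    tss: str | None = None
    pwms: str | None = None
    foreground: str | None = None
    background: str | None = None
    chrom_sizes: str | None = None
    groups: dict[str, str] = field(default_factory=dict)
    outdir: str = "acetyldiff_out"
    min_len: int = 2000
    min_support: int = 2
    window: int = 20_000
    alpha: float = 0.05
    use_padj: bool = True
    n_top_pca: int = 500
    score_fraction: float = 0.8
    motif_gene_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for p in [*self.peaks, self.chip_counts, self.rna_counts, self.tss,
                  self.pwms, self.foreground, self.background, self.chrom_sizes]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, complete: bool) -> None:
    entries = []
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "MANIFEST.json":
            entries.append({"path": str(p.relative_to(outdir)), "sha256": _sha256(p)})
    manifest = {"complete": complete, "files": entries}
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1) + "\n")


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage present in the config; returns the summary dict.

    Stages with missing inputs are skipped and marked so in the summary.
    Any stage failure aborts with the stage name; partial outputs stay on
    disk with the MANIFEST marked incomplete.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, object] = {}
    stage = "setup"
    try:
        chrom_sizes = (
            regions.read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
        )

        # ---- consensus ------------------------------------------------
        consensus = None
        if config.peaks:
            stage = "consensus"
            logger.info("[consensus] %d peak files, min_len=%d, min_support=%d",
                        len(config.peaks), config.min_len, config.min_support)
            consensus = regions.build_consensus(
                config.peaks, chrom_sizes, config.min_len, config.min_support
            )
            if not len(consensus):
                logger.warning("consensus region set is empty")
            consensus.write_bed(outdir / "consensus.bed",
                                extra_cols=["region_id", "sample_support"])
            summary["consensus_regions"] = len(consensus)

        # ---- ChIP differential ---------------------------------------
        chip_res = None
        if config.chip_counts:
            stage = "diff-chip"
            cm = quantify.load_count_matrix(config.chip_counts, config.groups)
            est = differential.NBWaldTest(
                p_threshold=config.alpha, use_padj=config.use_padj, arm="chip"
            ).fit(cm)
            chip_res = est.results_
            chip_res.to_csv(outdir / "chip_differential.tsv", sep="\t")
            summary["differential_regions"] = int((chip_res["direction"] != "ns").sum())
            summary["hyper_regions"] = int((chip_res["direction"] == "hyper").sum())
            summary["hypo_regions"] = int((chip_res["direction"] == "hypo").sum())

            # ---- explore ---------------------------------------------
            stage = "explore"
            norm = explore.QuantileNormalizer().fit_transform(cm.counts)
            norm.to_csv(outdir / "normalized_matrix.tsv", sep="\t")
            diff_ids = chip_res.index[chip_res["direction"] != "ns"]
            cluster_input = norm.loc[diff_ids] if len(diff_ids) >= 2 else norm
            clust = explore.hierarchical_cluster(cluster_input)
            pd.Series(clust["two_cut"], name="cluster").rename_axis("sample_id").to_csv(
                outdir / "cluster_two_cut.tsv", sep="\t"
            )
            pca = explore.TopVariablePCA(n_top=config.n_top_pca).fit(norm)
            scores = pca.transform(norm)
            scores.rename_axis("sample_id").to_csv(outdir / "pca_scores.tsv", sep="\t")
            outliers = explore.detect_outlier_samples(scores, cm.groups)
            (outdir / "pca_outliers.txt").write_text("\n".join(outliers) + "\n")
            summary["pca_variance_pc1"] = float(pca.variance_explained_[0])
            summary["flagged_outlier_samples"] = len(outliers)
            if consensus is not None and chrom_sizes is not None:
                cdf = consensus.df
                common = cdf[cdf["region_id"].isin(chip_res.index)]
                mtab = explore.manhattan_table(
                    chip_res, common, chrom_sizes
                )
                mtab.to_csv(outdir / "manhattan.tsv", sep="\t", index=False)

        # ---- RNA differential ----------------------------------------
        rna_res = None
        if config.rna_counts:
            stage = "diff-rna"
            rna_cm = quantify.load_count_matrix(config.rna_counts, config.groups)
            rna_res = differential.NBWaldTest(
                p_threshold=config.alpha, use_padj=config.use_padj, arm="rna"
            ).fit(rna_cm).results_
            rna_res.to_csv(outdir / "rna_differential.tsv", sep="\t")
            summary["de_genes_up"] = int((rna_res["direction"] == "up").sum())
            summary["de_genes_down"] = int((rna_res["direction"] == "down").sum())

        # ---- annotation & integration --------------------------------
        if consensus is not None and chip_res is not None and config.tss:
            stage = "annotate"
            tss = annotate.TssCatalog.read_tsv(config.tss)
            cdf = consensus.df.merge(
                chip_res["direction"].rename_axis("region_id").reset_index(),
                on="region_id", how="inner",
            )
            diff_regions = regions.RegionSet(cdf[cdf["direction"] != "ns"])
            links = annotate.annotate_regions(diff_regions, tss, config.window)
            links.to_csv(outdir / "region_gene_links.tsv", sep="\t", index=False)
            near_hyper, near_hypo = annotate.annotated_gene_sets(links)
            summary["annotated_genes_hyper"] = len(near_hyper)
            summary["annotated_genes_hypo"] = len(near_hypo)

            if rna_res is not None:
                stage = "integrate"
                conc = annotate.concordance_analysis(links, rna_res)
                flat = {k: v for k, v in conc.items() if not isinstance(v, pd.Series)}
                pd.Series(flat).rename_axis("metric").to_frame("value").to_csv(
                    outdir / "concordance.tsv", sep="\t"
                )
                hyper_up, hypo_down = annotate.overlap_gene_lists(
                    (near_hyper, near_hypo), rna_res
                )
                pd.Series(hyper_up, dtype=object).to_csv(
                    outdir / "overlap_hyper_up.tsv", sep="\t", index=False, header=["gene_id"]
                )
                pd.Series(hypo_down, dtype=object).to_csv(
                    outdir / "overlap_hypo_down.tsv", sep="\t", index=False, header=["gene_id"]
                )
                summary["overlap_hyper_up"] = len(hyper_up)
                summary["overlap_hypo_down"] = len(hypo_down)
                summary["median_lfc_near_hyper"] = conc["median_near_hyper"]
                summary["median_lfc_near_hypo"] = conc["median_near_hypo"]
        else:
            if config.tss is None:
                summary["annotation"] = "skipped (no TSS catalog)"
        if config.rna_counts is None:
            summary["integration"] = "skipped (no RNA input)"

        # ---- motif enrichment ----------------------------------------
        if config.pwms and config.foreground and config.background:
            stage = "motifs"
            pwm_list = motifs.read_meme(config.pwms)
            fg = motifs.read_fasta(config.foreground)
            bg = motifs.read_fasta(config.background)
            enr = motifs.MotifEnrichment(score_fraction=config.score_fraction).fit(
                pwm_list, fg, bg
            ).results_
            enr.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
            summary["enriched_motifs"] = int((enr["padj"] < config.alpha).sum())
            if rna_res is not None and config.motif_gene_map:
                linked = motifs.link_motifs_to_de_tfs(
                    {"hyper": enr}, rna_res, config.motif_gene_map, config.alpha
                )
                linked.to_csv(outdir / "linked_tfs.tsv", sep="\t", index=False)
                summary["linked_tfs"] = len(linked)
    except Exception:
        logger.exception("pipeline aborted in stage %r", stage)
        _write_manifest(outdir, complete=False)
        raise RuntimeError(f"pipeline failed in stage {stage!r}") from None

    pd.Series(summary).rename_axis("metric").to_frame("value").to_csv(
        outdir / "summary.tsv", sep="\t"
    )
    _write_manifest(outdir, complete=True)
    return summary


def simulate_command(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic input bundle (plus ground truth) on disk."""
    bundle = simulate_all(config)
    return bundle.write(outdir)


def run_synthetic(
    sim_config: SimulationConfig | None = None,
    outdir: str | Path = "acetyldiff_out",
    **pipeline_params,
) -> dict:
    """Simulate a study and run the full pipeline on it; returns the summary."""
    sim_config = sim_config or SimulationConfig()
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    paths = simulate_command(sim_config, inputs)
    # planted motifs map onto genes of the simulated catalog so the TF-link
    # stage has something to join; motif_XX -> gene_000XX is the convention
    name_map = {
        f"motif_{i+1:02d}": f"gene_{i+1:05d}" for i in range(sim_config.n_motifs)
    }
    pconf = PipelineConfig(
        peaks=[str(p) for k, p in paths.items() if k.startswith("peaks/")],
        chip_counts=str(paths["chip_counts"]),
        rna_counts=str(paths["rna_counts"]),
        tss=str(paths["tss"]),
        pwms=str(paths["pwms"]),
        foreground=str(paths["foreground"]),
        background=str(paths["background"]),
        chrom_sizes=str(paths["chrom_sizes"]),
        groups=sim_config.groups,
        outdir=str(outdir / "results"),
        motif_gene_map=name_map,
        seed=sim_config.seed,
        **pipeline_params,
    )
    return run_all(pconf)
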