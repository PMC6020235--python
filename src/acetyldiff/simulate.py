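"""Synthetic study generator: every pipeline input with known ground truth.

Emulates the study design the pipeline targets: two groups (5 case vs 4
control samples), a few thousand consensus-scale H3K27ac regions of which a
small fraction carry a planted log2 fold change (hyper- or hypoacetylated),
negative-binomially distributed region and gene counts, gene expression
changes coupled to nearby (within 20 kb of TSS) differential regions, and
foreground/background sequence sets with motifs planted at different rates.

Determinism: a fixed (config, seed) pair yields byte-identical output files;
each stage draws from its own child of a single SeedSequence so stages stay
reproducible independently of one another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import TssCatalog
from .motifs import BASES, PWM, write_fasta, write_meme
from .quantify import CountMatrix
from .regions import RegionSet, build_consensus, write_chrom_sizes

_STAGES = ("genome", "regions", "peaks", "counts", "expression", "sequences")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the emulated conditions."""

    n_case: int = 5
    n_control: int = 4
    n_chromosomes: int = 5
    chrom_length: int = 10_000_000
    n_true_regions: int = 3000
    frac_hyper: float = 0.015
    frac_hypo: float = 0.015
    planted_lfc: float = 2.0
    base_mean_range: tuple[int, int] = (20, 500)
    dispersion: float = 0.05
    peak_dropout: float = 0.2
    n_genes: int = 5000
    coupling_prob: float = 0.7
    background_de_rate: float = 0.02
    coupling_window: int = 20_000
    region_width_range: tuple[int, int] = (400, 1200)
    min_region_gap: int = 5000
    n_motifs: int = 10
    motif_plant_rate_fg: float = 0.5
    motif_plant_rate_bg: float = 0.05
    tf_gene_coupling: bool = True  # planted motifs' TF genes are upregulated
    n_sequences: int = 200
    sequence_length: int = 500
    mask_n_runs: int = 0  # optional masked-N runs per sequence
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "frac_hyper": self.frac_hyper,
            "frac_hypo": self.frac_hypo,
            "peak_dropout": self.peak_dropout,
            "coupling_prob": self.coupling_prob,
            "background_de_rate": self.background_de_rate,
            "motif_plant_rate_fg": self.motif_plant_rate_fg,
            "motif_plant_rate_bg": self.motif_plant_rate_bg,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_hyper + self.frac_hypo >= 1:
            raise ValueError("frac_hyper + frac_hypo must be < 1")
        for name in ("n_case", "n_control", "n_chromosomes", "chrom_length",
                     "n_true_regions", "n_motifs", "n_sequences", "sequence_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return [f"case_{i+1}" for i in range(self.n_case)] + [
            f"control_{i+1}" for i in range(self.n_control)
        ]

    @property
    def groups(self) -> dict[str, str]:
        return {s: ("case" if s.startswith("case") else "control") for s in self.sample_ids}

    def rng(self, stage: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return np.random.default_rng(children[_STAGES.index(stage)])


@dataclass
class GroundTruth:
    """Planted effects: per-region status/LFC, per-gene status/LFC, per-motif flag."""

    regions: pd.DataFrame  # chrom, start, end, status (null/hyper/hypo), planted_lfc
    genes: pd.DataFrame | None = None  # gene_id, status (null/up/down), planted_lfc
    motifs: pd.DataFrame | None = None  # motif_name, planted (bool)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.regions.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)
        if self.genes is not None:
            self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        if self.motifs is not None:
            self.motifs.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)


def simulate_genome(config: SimulationConfig) -> tuple[dict[str, int], TssCatalog]:
    """Chromosome sizes (chr1..chrN, equal length) and a uniform TSS catalog.

    No TSS is placed within 1 kb of a chromosome end.
    """
    chrom_sizes = {f"chr{i+1}": config.chrom_length for i in range(config.n_chromosomes)}
    rng = config.rng("genome")
    chroms = list(chrom_sizes)
    if config.n_genes == 0:
        df = pd.DataFrame(columns=["gene_id", "chrom", "tss", "strand"])
        return chrom_sizes, TssCatalog(df)
    gene_chrom = rng.choice(chroms, size=config.n_genes)
    tss = rng.integers(1000, config.chrom_length - 1000, size=config.n_genes)
    strand = rng.choice(["+", "-"], size=config.n_genes)
    df = pd.DataFrame(
        {
            "gene_id": [f"gene_{i+1:05d}" for i in range(config.n_genes)],
            "chrom": gene_chrom,
            "tss": tss,
            "strand": strand,
        }
    )
    return chrom_sizes, TssCatalog(df)


def simulate_true_regions(config: SimulationConfig) -> GroundTruth:
    """Place non-overlapping true regions (>= min gap apart) and plant effects.

    Regions are spread across chromosomes proportionally to length; a
    frac_hyper / frac_hypo split receives +/- planted_lfc, the rest are null.
    """
    rng = config.rng("regions")
    n = config.n_true_regions
    per_chrom = np.full(config.n_chromosomes, n // config.n_chromosomes)
    per_chrom[: n % config.n_chromosomes] += 1
    lo, hi = config.region_width_range
    rows = []
    margin = 2000  # leave room for stretching/jitter at chromosome ends
    for c in range(config.n_chromosomes):
        k = int(per_chrom[c])
        if k == 0:
            continue
        widths = rng.integers(lo, hi + 1, size=k)
        gap = config.min_region_gap
        required = widths.sum() + gap * (k - 1) + 2 * margin
        slack = config.chrom_length - required
        if slack < 0:
            raise ValueError(
                "chromosomes too short for the requested region count/gap"
            )
        offsets = np.sort(rng.uniform(0, slack, size=k)).astype(np.int64)
        starts = margin + offsets + np.concatenate([[0], np.cumsum(widths[:-1] + gap)])
        for s, w in zip(starts, widths):
            rows.append((f"chr{c+1}", int(s), int(s + w)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    n_hyper = int(round(config.frac_hyper * n))
    n_hypo = int(round(config.frac_hypo * n))
    status = np.array(["null"] * n, dtype=object)
    picked = rng.choice(n, size=n_hyper + n_hypo, replace=False)
    status[picked[:n_hyper]] = "hyper"
    status[picked[n_hyper:]] = "hypo"
    df["status"] = status
    df["planted_lfc"] = np.select(
        [status == "hyper", status == "hypo"],
        [config.planted_lfc, -config.planted_lfc],
        0.0,
    )
    return GroundTruth(regions=df)


def simulate_peaks(config: SimulationConfig, truth: GroundTruth) -> dict[str, RegionSet]:
    """Per-sample peak calls: true regions minus dropouts, edges jittered +/-200 bp."""
    rng = config.rng("peaks")
    peaks: dict[str, RegionSet] = {}
    tdf = truth.regions
    n = len(tdf)
    for sample in config.sample_ids:
        keep = rng.random(n) >= config.peak_dropout
        sub = tdf.loc[keep, ["chrom", "start", "end"]].copy()
        jitter = rng.integers(-200, 201, size=(n, 2))[keep]
        sub["start"] = np.maximum(sub["start"].to_numpy() + jitter[:, 0], 0)
        sub["end"] = np.minimum(
            sub["end"].to_numpy() + jitter[:, 1], config.chrom_length
        )
        sub = sub[sub["start"] < sub["end"]]
        peaks[sample] = RegionSet(sub)
    return peaks


def _map_regions_to_truth(regions: RegionSet, truth: GroundTruth) -> pd.DataFrame:
    """Per input region: status and LFC of the overlapping true region (or null).

    True regions are >= 5 kb apart so each consensus region overlaps at most
    one; ties (should not occur) resolve to the larger overlap.
    """
    rdf = regions.df
    out_status = np.array(["null"] * len(rdf), dtype=object)
    out_lfc = np.zeros(len(rdf))
    tdf = truth.regions
    for chrom, tsub in tdf.groupby("chrom", sort=False):
        mask = rdf["chrom"] == chrom
        if not mask.any():
            continue
        rs = rdf.loc[mask, "start"].to_numpy()
        re_ = rdf.loc[mask, "end"].to_numpy()
        idx = np.flatnonzero(mask.to_numpy())
        ts = tsub["start"].to_numpy()
        te = tsub["end"].to_numpy()
        best_ov = np.zeros(len(idx), dtype=np.int64)
        best_k = np.full(len(idx), -1)
        for k in range(len(tsub)):
            ov = np.minimum(re_, te[k]) - np.maximum(rs, ts[k])
            better = ov > best_ov
            best_ov[better] = ov[better]
            best_k[better] = k
        hit = best_k >= 0
        out_status[idx[hit]] = tsub["status"].to_numpy()[best_k[hit]]
        out_lfc[idx[hit]] = tsub["planted_lfc"].to_numpy()[best_k[hit]]
    mapped = rdf.copy()
    mapped["status"] = out_status
    mapped["planted_lfc"] = out_lfc
    return mapped


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, alpha) with Var = mu + alpha*mu^2 (shape n = 1/alpha)."""
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    config: SimulationConfig, truth: GroundTruth, regions: RegionSet
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB region x sample counts on ``regions`` with the planted ChIP effects.

    Sample size factors are log-uniform in [0.5, 2]; regions not overlapping
    any true region get a background mean from the low end of the base-mean
    range.  Returns the matrix and the region-to-truth map used.
    """
    rng = config.rng("counts")
    mapped = _map_regions_to_truth(regions, truth)
    n_reg = len(mapped)
    lo, hi = config.base_mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_reg))
    no_truth = ~_overlaps_any_truth(mapped, truth)
    mu[no_truth] = rng.uniform(lo, lo + 0.1 * (hi - lo), size=no_truth.sum())
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(config.sample_ids)))
    is_case = np.array([g == "case" for g in config.groups.values()])
    lfc = mapped["planted_lfc"].to_numpy()
    mean = mu[:, None] * sf[None, :] * np.power(2.0, lfc[:, None] * is_case[None, :])
    counts = _nb_draw(rng, mean, config.dispersion)
    ids = (
        mapped["region_id"].tolist()
        if "region_id" in mapped.columns
        else [f"region_{i+1:05d}" for i in range(n_reg)]
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=ids, columns=config.sample_ids),
        pd.Series(config.groups),
    )
    mapped = mapped.assign(feature_id=ids)
    return cm, mapped


def _overlaps_any_truth(mapped: pd.DataFrame, truth: GroundTruth) -> np.ndarray:
    """Boolean per row of ``mapped``: overlaps some true region (any status)."""
    out = np.zeros(len(mapped), dtype=bool)
    tdf = truth.regions
    for chrom, tsub in tdf.groupby("chrom", sort=False):
        mask = (mapped["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        rs = mapped.loc[mask, "start"].to_numpy()
        re_ = mapped.loc[mask, "end"].to_numpy()
        ts = tsub["start"].to_numpy()
        te = tsub["end"].to_numpy()
        hit = np.zeros(mask.sum(), dtype=bool)
        for k in range(len(tsub)):
            hit |= (rs < te[k]) & (ts[k] < re_)
        out[np.flatnonzero(mask)] = hit
    return out


def simulate_expression(
    config: SimulationConfig, truth: GroundTruth, tss: TssCatalog
) -> tuple[CountMatrix, GroundTruth]:
    """NB gene x sample counts with expression coupled to nearby planted regions.

    A gene whose TSS lies within the coupling window of a hyper (hypo) region
    receives +planted_lfc (-planted_lfc) with probability coupling_prob; a
    further background fraction of unlinked genes is made DE with random sign.
    """
    rng = config.rng("expression")
    tdf = truth.regions
    diff = tdf[tdf["status"] != "null"]
    gene_status = np.array(["null"] * len(tss.df), dtype=object)
    gene_lfc = np.zeros(len(tss.df))
    w = config.coupling_window
    for i, g in enumerate(tss.df.itertuples(index=False)):
        sub = diff[diff["chrom"] == g.chrom]
        if not len(sub):
            continue
        d = np.maximum(sub["start"].to_numpy() - g.tss, 0) + np.maximum(
            g.tss - (sub["end"].to_numpy() - 1), 0
        )
        near = d <= w
        if near.any():
            nearest = sub.iloc[int(np.argmin(np.where(near, d, np.inf)))]
            if rng.random() < config.coupling_prob:
                gene_status[i] = "up" if nearest["status"] == "hyper" else "down"
                gene_lfc[i] = nearest["planted_lfc"]
    # planted motifs emulate TF binding sites in hyperacetylated regions;
    # with tf_gene_coupling the corresponding TF transcripts (first
    # ceil(n_motifs/2) genes by the motif_i -> gene_i convention) are
    # upregulated so the motif/expression linkage is recoverable end to end
    if config.tf_gene_coupling:
        n_planted = (config.n_motifs + 1) // 2
        tf_genes = {f"gene_{i+1:05d}" for i in range(n_planted)}
        for i, gid in enumerate(tss.df["gene_id"]):
            if gid in tf_genes:
                gene_status[i] = "up"
                gene_lfc[i] = config.planted_lfc
    # independent background DE among still-null genes
    null_idx = np.flatnonzero(gene_status == "null")
    n_bg = int(round(config.background_de_rate * len(null_idx)))
    if n_bg:
        bg = rng.choice(null_idx, size=n_bg, replace=False)
        signs = rng.choice([1.0, -1.0], size=n_bg)
        gene_status[bg] = np.where(signs > 0, "up", "down")
        gene_lfc[bg] = signs * config.planted_lfc
    lo, hi = config.base_mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(tss.df)))
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(config.sample_ids)))
    is_case = np.array([g == "case" for g in config.groups.values()])
    mean = mu[:, None] * sf[None, :] * np.power(2.0, gene_lfc[:, None] * is_case[None, :])
    counts = _nb_draw(rng, mean, config.dispersion)
    cm = CountMatrix(
        pd.DataFrame(counts, index=tss.df["gene_id"].tolist(), columns=config.sample_ids),
        pd.Series(config.groups),
    )
    genes = pd.DataFrame(
        {
            "gene_id": tss.df["gene_id"],
            "status": gene_status,
            "planted_lfc": gene_lfc,
        }
    )
    return cm, dataclasses.replace(truth, genes=genes)


def _random_pwm(rng: np.random.Generator, name: str, config: SimulationConfig) -> PWM:
    """A sharpened random profile: consensus base probability 0.85, width 8-12."""
    width = int(rng.integers(8, 13))
    consensus = rng.integers(0, 4, size=width)
    matrix = np.full((width, 4), 0.05)
    matrix[np.arange(width), consensus] = 0.85
    return PWM(name, matrix)


def simulate_sequences(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[dict[str, str], dict[str, str], list[PWM], GroundTruth]:
    """Foreground/background sequence sets with motif consensi planted at
    different rates, plus the PWM set and motif ground truth.

    The first ceil(n_motifs / 2) PWMs are planted (at rate fg/bg in each
    set); the rest appear nowhere beyond chance.  Optional masked runs of N
    exercise the scanner's mask handling.
    """
    rng = config.rng("sequences")
    pwms = [_random_pwm(rng, f"motif_{i+1:02d}", config) for i in range(config.n_motifs)]
    n_planted = (config.n_motifs + 1) // 2
    planted = [p.name for p in pwms[:n_planted]]
    base_arr = np.array(list(BASES))

    def _make_set(n_seqs: int, plant_rate: float, prefix: str) -> dict[str, str]:
        seqs = {}
        for i in range(n_seqs):
            chars = base_arr[rng.integers(0, 4, size=config.sequence_length)]
            for pwm in pwms[:n_planted]:
                if rng.random() < plant_rate:
                    cons = list(pwm.consensus)
                    pos = int(rng.integers(0, config.sequence_length - pwm.width + 1))
                    chars[pos : pos + pwm.width] = cons
            for _ in range(config.mask_n_runs):
                run = int(rng.integers(5, 20))
                pos = int(rng.integers(0, config.sequence_length - run + 1))
                chars[pos : pos + run] = "N"
            seqs[f"{prefix}_{i+1:04d}"] = "".join(chars)
        return seqs

    fg = _make_set(config.n_sequences, config.motif_plant_rate_fg, "fg")
    bg = _make_set(config.n_sequences, config.motif_plant_rate_bg, "bg")
    motifs_df = pd.DataFrame(
        {"motif_name": [p.name for p in pwms], "planted": [p.name in planted for p in pwms]}
    )
    if truth is None:
        truth = GroundTruth(regions=pd.DataFrame(columns=["chrom", "start", "end", "status", "planted_lfc"]))
    return fg, bg, pwms, dataclasses.replace(truth, motifs=motifs_df)


@dataclass
class SimulatedBundle:
    """Everything one synthetic study run produces, in memory."""

    config: SimulationConfig
    chrom_sizes: dict[str, int]
    tss: TssCatalog
    truth: GroundTruth
    peaks: dict[str, RegionSet]
    consensus: RegionSet
    chip_counts: CountMatrix
    region_truth_map: pd.DataFrame
    rna_counts: CountMatrix
    foreground: dict[str, str]
    background: dict[str, str]
    pwms: list[PWM]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the whole bundle as plain-text files; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        write_chrom_sizes(self.chrom_sizes, outdir / "chrom.sizes")
        paths["chrom_sizes"] = outdir / "chrom.sizes"
        self.tss.write_tsv(outdir / "tss.tsv")
        paths["tss"] = outdir / "tss.tsv"
        peaks_dir = outdir / "peaks"
        peaks_dir.mkdir(exist_ok=True)
        for sample, rs in self.peaks.items():
            p = peaks_dir / f"{sample}.bed"
            rs.write_bed(p)
            paths[f"peaks/{sample}"] = p
        self.consensus.write_bed(
            outdir / "consensus.bed", extra_cols=["region_id", "sample_support"]
        )
        paths["consensus"] = outdir / "consensus.bed"
        self.chip_counts.write_tsv(outdir / "chip_counts.tsv")
        paths["chip_counts"] = outdir / "chip_counts.tsv"
        self.rna_counts.write_tsv(outdir / "rna_counts.tsv", feature_col="gene_id")
        paths["rna_counts"] = outdir / "rna_counts.tsv"
        write_fasta(self.foreground, outdir / "foreground.fasta")
        write_fasta(self.background, outdir / "background.fasta")
        paths["foreground"] = outdir / "foreground.fasta"
        paths["background"] = outdir / "background.fasta"
        write_meme(self.pwms, outdir / "motifs.meme")
        paths["pwms"] = outdir / "motifs.meme"
        groups = pd.Series(self.config.groups, name="group")
        groups.rename_axis("sample_id").to_csv(outdir / "groups.tsv", sep="\t")
        paths["groups"] = outdir / "groups.tsv"
        self.truth.write(outdir)
        paths["truth_regions"] = outdir / "truth_regions.tsv"
        return paths


def simulate_all(config: SimulationConfig) -> SimulatedBundle:
    """Run every simulation stage and assemble a full in-memory bundle.

    The ChIP count matrix is generated on the consensus regions built from
    the simulated per-sample peaks, exactly as the real pipeline would see
    them.
    """
    chrom_sizes, tss = simulate_genome(config)
    truth = simulate_true_regions(config)
    peaks = simulate_peaks(config, truth)
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        files = []
        for sample, rs in peaks.items():
            p = Path(tmp) / f"{sample}.bed"
            rs.write_bed(p)
            files.append(p)
        consensus = build_consensus(files, chrom_sizes)
    chip_counts, region_map = simulate_counts(config, truth, consensus)
    rna_counts, truth = simulate_expression(config, truth, tss)
    fg, bg, pwms, truth = simulate_sequences(config, truth)
    return SimulatedBundle(
        config=config,
        chrom_sizes=chrom_sizes,
        tss=tss,
        truth=truth,
        peaks=peaks,
        consensus=consensus,
        chip_counts=chip_counts,
        region_truth_map=region_map,
        rna_counts=rna_counts,
        foreground=fg,
        background=bg,
        pwms=pwms,
    )
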