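"""PWM motif enrichment: log-odds scanning of foreground vs background FASTA.

Scanning scores every offset on both strands with log2(p_base / bg_base)
summed over the motif window (probabilities floored at 1e-4); a sequence is
a hit when its best window reaches ``score_fraction`` (default 0.8) of the
PWM's maximum attainable score.  Enrichment is a one-sided Fisher's exact
test of foreground vs background hit counts, BH-adjusted across motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats
from sklearn.base import BaseEstimator

from .differential import bh_adjust

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
PROB_FLOOR = 1e-4


@dataclass
class PWM:
    """Position probability matrix (width x 4, columns A C G T)."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.name}: matrix must be width x 4")
        if self.width < 4:
            raise ValueError(f"PWM {self.name}: width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """log2 odds vs background, with probabilities floored at 1e-4."""
        p = np.maximum(self.matrix, PROB_FLOOR)
        bg = np.maximum(self.background, PROB_FLOOR)
        return np.log2(p / bg)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1], self.background[::-1])


# ------------------------------------------------------------- MEME format
def read_meme(path: str | Path) -> list[PWM]:
    """Parse a minimal MEME motif file (MOTIF blocks with probability rows)."""
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    pwms.append(PWM(name, np.array(rows)))
                name = line.split()[1]
                rows = []
            elif line.startswith("letter-probability"):
                continue
            elif name is not None and line and line[0] in "0123456789.":
                vals = [float(v) for v in line.split()]
                if len(vals) == 4:
                    rows.append(vals)
    if name is not None and rows:
        pwms.append(PWM(name, np.array(rows)))
    if not pwms:
        raise ValueError(f"{path}: no MOTIF blocks found")
    return pwms


def write_meme(pwms: list[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; any other symbol (N, masked) -> -1."""
    return np.array([_BASE_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int64)


def _best_window_score(lods: np.ndarray, idx: np.ndarray) -> float:
    w = lods.shape[0]
    n = idx.size
    if n < w:
        return -np.inf
    valid = idx >= 0
    scores = np.zeros(n - w + 1)
    ok = np.ones(n - w + 1, dtype=bool)
    safe = np.where(valid, idx, 0)
    for off in range(w):
        scores += lods[off, safe[off : off + n - w + 1]]
        ok &= valid[off : off + n - w + 1]
    scores[~ok] = -np.inf  # windows containing N never score
    return float(scores.max()) if scores.size else -np.inf


def scan_sequence(pwm: PWM, seq: str, score_fraction: float = 0.8) -> bool:
    """True iff the sequence's best log-odds window (either strand) reaches
    ``score_fraction`` of the PWM's maximum attainable score."""
    idx = encode_sequence(seq)
    if idx.size < pwm.width:
        logger.debug("sequence shorter than PWM %s width; no hit", pwm.name)
        return False
    threshold = score_fraction * pwm.max_score()
    fwd = _best_window_score(pwm.log_odds(), idx)
    if fwd >= threshold:
        return True
    rev = _best_window_score(pwm.reverse_complement().log_odds(), idx)
    return rev >= threshold


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


class MotifEnrichment(BaseEstimator):
    """Foreground-vs-background motif enrichment with one-sided Fisher tests.

    Parameters
    ----------
    score_fraction : float
        Hit threshold as a fraction of each PWM's maximum log-odds score.
    background_from_sequences : bool
        Estimate the scanning background from the background set's base
        composition rather than uniform 0.25.

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : pd.DataFrame sorted by padj with columns motif_name, fg_hits,
        fg_total, bg_hits, bg_total, odds_ratio, p, padj.
    """

    def __init__(self, score_fraction: float = 0.8, background_from_sequences: bool = False):
        self.score_fraction = score_fraction
        self.background_from_sequences = background_from_sequences

    def fit(
        self, pwms: list[PWM], foreground: dict[str, str], background: dict[str, str]
    ) -> "MotifEnrichment":
        if not pwms:
            raise ValueError("empty motif list")
        if not foreground or not background:
            raise ValueError("foreground and background sets must be non-empty")
        if self.background_from_sequences:
            bg_freq = _base_composition(background.values())
            pwms = [PWM(p.name, p.matrix, bg_freq) for p in pwms]
        rows = []
        for pwm in pwms:
            fg_hits = sum(
                scan_sequence(pwm, s, self.score_fraction) for s in foreground.values()
            )
            bg_hits = sum(
                scan_sequence(pwm, s, self.score_fraction) for s in background.values()
            )
            table = [
                [fg_hits, len(foreground) - fg_hits],
                [bg_hits, len(background) - bg_hits],
            ]
            odds, p = stats.fisher_exact(table, alternative="greater")
            rows.append(
                {
                    "motif_name": pwm.name,
                    "fg_hits": fg_hits,
                    "fg_total": len(foreground),
                    "bg_hits": bg_hits,
                    "bg_total": len(background),
                    "odds_ratio": odds,
                    "p": p,
                }
            )
        res = pd.DataFrame(rows)
        res["padj"] = bh_adjust(res["p"].to_numpy())
        self.results_ = res.sort_values("padj", kind="mergesort").reset_index(drop=True)
        return self


def _base_composition(seqs) -> np.ndarray:
    counts = np.zeros(4)
    for s in seqs:
        idx = encode_sequence(s)
        for i in range(4):
            counts[i] += (idx == i).sum()
    total = counts.sum()
    return counts / total if total else np.full(4, 0.25)


def enrichment_test(
    pwms: list[PWM],
    foreground: dict[str, str],
    background: dict[str, str],
    score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Functional wrapper around :class:`MotifEnrichment`."""
    return MotifEnrichment(score_fraction=score_fraction).fit(
        pwms, foreground, background
    ).results_


def link_motifs_to_de_tfs(
    enrichment_by_direction: dict[str, pd.DataFrame],
    rna: pd.DataFrame,
    name_map: dict[str, str],
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Join enriched motifs to differentially expressed TF transcripts.

    ``enrichment_by_direction`` maps "hyper"/"hypo" to enrichment tables;
    a TF is emitted when its motif is enriched in the hyper-region
    foreground AND its transcript is called up (mirror for hypo/down).
    Motif names absent from ``name_map`` are logged and skipped.
    """
    if name_map is None:
        raise ValueError("a motif-name -> gene-id map is required")
    expected = {"hyper": "up", "hypo": "down"}
    rows = []
    for region_dir, table in enrichment_by_direction.items():
        want = expected.get(region_dir)
        if want is None:
            raise ValueError(f"unknown region direction {region_dir!r}")
        enriched = table[table["padj"] < padj_threshold]
        for motif in enriched["motif_name"]:
            gene = name_map.get(motif)
            if gene is None:
                logger.info("motif %s has no gene mapping; skipped", motif)
                continue
            if gene in rna.index and rna.loc[gene, "direction"] == want:
                rows.append(
                    {
                        "motif_name": motif,
                        "gene_id": gene,
                        "region_direction": region_dir,
                        "rna_direction": want,
                    }
                )
    return pd.DataFrame(
        rows, columns=["motif_name", "gene_id", "region_direction", "rna_direction"]
    )
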