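"""The synthetic study generator: determinism, planted structure, distributions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acetyldiff.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_expression,
    simulate_genome,
    simulate_peaks,
    simulate_sequences,
    simulate_true_regions,
)
from acetyldiff.regions import RegionSet


class TestConfig:
    def test_defaults_valid(self):
        cfg = SimulationConfig()
        assert cfg.n_case == 5 and cfg.n_control == 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_hyper": 1.2},
            {"peak_dropout": -0.1},
            {"n_true_regions": 0},
            {"dispersion": 0.0},
            {"frac_hyper": 0.6, "frac_hypo": 0.6},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestGenome:
    def test_default_catalog(self):
        cfg = SimulationConfig(seed=1)
        sizes, tss = simulate_genome(cfg)
        assert len(tss) == 5000
        assert set(tss.df["chrom"]) <= {f"chr{i}" for i in range(1, 6)}
        assert (tss.df["tss"] >= 1000).all()
        assert (tss.df["tss"] <= cfg.chrom_length - 1000).all()

    def test_no_genes(self):
        _, tss = simulate_genome(SimulationConfig(seed=1, n_genes=0))
        assert len(tss) == 0

    def test_same_seed_identical(self):
        _, a = simulate_genome(SimulationConfig(seed=9))
        _, b = simulate_genome(SimulationConfig(seed=9))
        assert a.df.equals(b.df)


class TestTrueRegions:
    def test_non_overlapping_with_min_gap(self):
        cfg = SimulationConfig(seed=2)
        tdf = simulate_true_regions(cfg).regions
        for _, sub in tdf.groupby("chrom"):
            s = sub.sort_values("start")
            gaps = s["start"].to_numpy()[1:] - s["end"].to_numpy()[:-1]
            assert (gaps >= cfg.min_region_gap).all()

    def test_planted_lfc_magnitudes(self):
        cfg = SimulationConfig(seed=2)
        tdf = simulate_true_regions(cfg).regions
        nonnull = tdf[tdf["status"] != "null"]
        assert np.allclose(nonnull["planted_lfc"].abs(), cfg.planted_lfc)
        assert (tdf.loc[tdf["status"] == "null", "planted_lfc"] == 0).all()
        assert len(nonnull) == round(0.03 * cfg.n_true_regions)


class TestPeaks:
    def test_zero_dropout_keeps_all(self):
        cfg = SimulationConfig(seed=3, peak_dropout=0.0)
        truth = simulate_true_regions(cfg)
        peaks = simulate_peaks(cfg, truth)
        assert all(len(rs) == cfg.n_true_regions for rs in peaks.values())

    def test_full_dropout_empties_all(self):
        cfg = SimulationConfig(seed=3, peak_dropout=1.0)
        truth = simulate_true_regions(cfg)
        peaks = simulate_peaks(cfg, truth)
        assert all(len(rs) == 0 for rs in peaks.values())

    def test_default_dropout_within_binomial_bounds(self):
        cfg = SimulationConfig(seed=7)
        truth = simulate_true_regions(cfg)
        peaks = simulate_peaks(cfg, truth)
        lo = stats.binom.ppf(0.0005, cfg.n_true_regions, 1 - cfg.peak_dropout)
        hi = stats.binom.ppf(0.9995, cfg.n_true_regions, 1 - cfg.peak_dropout)
        for rs in peaks.values():
            assert lo <= len(rs) <= hi


class TestCounts:
    def test_same_seed_identical_matrix(self):
        cfg = SimulationConfig(seed=4)
        truth = simulate_true_regions(cfg)
        rs = RegionSet(truth.regions[["chrom", "start", "end"]])
        cm1, _ = simulate_counts(cfg, truth, rs)
        cm2, _ = simulate_counts(cfg, truth, rs)
        assert cm1.counts.equals(cm2.counts)

    def test_poisson_limit_variance_matches_mean(self):
        cfg = SimulationConfig(seed=5, dispersion=1e-8, planted_lfc=0.0,
                               n_true_regions=1000)
        truth = simulate_true_regions(cfg)
        rs = RegionSet(truth.regions[["chrom", "start", "end"]])
        cm, _ = simulate_counts(cfg, truth, rs)
        # undo per-sample size factors by working per-sample: pooled
        # variance-to-mean ratio across regions should sit near 1
        norm = cm.counts.div(cm.counts.sum(axis=0) / cm.counts.sum(axis=0).mean(), axis=1)
        ratio = (norm.var(axis=1) / norm.mean(axis=1)).median()
        assert 0.7 < ratio < 1.4

    def test_null_config_groups_exchangeable(self):
        cfg = SimulationConfig(seed=6, planted_lfc=0.0)
        truth = simulate_true_regions(cfg)
        rs = RegionSet(truth.regions[["chrom", "start", "end"]])
        cm, _ = simulate_counts(cfg, truth, rs)
        from acetyldiff.differential import estimate_size_factors

        sf = estimate_size_factors(cm)
        norm = cm.counts / sf
        case = norm[cm.case_samples].to_numpy().mean()
        ctrl = norm[cm.control_samples].to_numpy().mean()
        assert abs(np.log2(case / ctrl)) < 0.1  # depth removed, groups exchangeable


class TestExpression:
    def _setup(self, **kwargs):
        cfg = SimulationConfig(seed=8, **kwargs)
        truth = simulate_true_regions(cfg)
        _, tss = simulate_genome(cfg)
        return cfg, truth, tss

    def test_no_coupling_no_background_no_de(self):
        cfg, truth, tss = self._setup(coupling_prob=0.0, background_de_rate=0.0,
                                      tf_gene_coupling=False)
        _, t2 = simulate_expression(cfg, truth, tss)
        assert (t2.genes["status"] == "null").all()

    def test_full_coupling_signs_match_regions(self):
        cfg, truth, tss = self._setup(coupling_prob=1.0, background_de_rate=0.0,
                                      tf_gene_coupling=False)
        _, t2 = simulate_expression(cfg, truth, tss)
        genes = t2.genes.set_index("gene_id")
        diff = truth.regions[truth.regions["status"] != "null"]
        # every gene within the window of a differential region is DE with
        # sign matching the region direction
        for g in tss.df.itertuples(index=False):
            sub = diff[diff["chrom"] == g.chrom]
            d = np.maximum(sub["start"] - g.tss, 0) + np.maximum(
                g.tss - (sub["end"] - 1), 0
            )
            near = sub[d <= cfg.coupling_window]
            if len(near):
                nearest = near.iloc[np.argmin(d[d <= cfg.coupling_window].to_numpy())]
                expected = "up" if nearest["status"] == "hyper" else "down"
                assert genes.loc[g.gene_id, "status"] == expected

    def test_planted_gene_lfc_magnitude(self):
        cfg, truth, tss = self._setup()
        _, t2 = simulate_expression(cfg, truth, tss)
        de = t2.genes[t2.genes["status"] != "null"]
        assert np.allclose(de["planted_lfc"].abs(), cfg.planted_lfc)
        up = t2.genes[t2.genes["status"] == "up"]
        assert up["planted_lfc"].median() == pytest.approx(cfg.planted_lfc)


class TestSequences:
    def test_pwm_rows_normalized(self):
        fg, bg, pwms, truth = simulate_sequences(SimulationConfig(seed=9))
        for p in pwms:
            assert np.allclose(p.matrix.sum(axis=1), 1.0, atol=1e-9)
            assert 8 <= p.width <= 12

    def test_full_fg_plant_rate(self):
        cfg = SimulationConfig(seed=9, motif_plant_rate_fg=1.0, motif_plant_rate_bg=0.0)
        fg, bg, pwms, truth = simulate_sequences(cfg)
        planted = truth.motifs[truth.motifs["planted"]]["motif_name"].tolist()
        last = [p for p in pwms if p.name == planted[-1]][0]
        # the last-planted motif's consensus survives later insertions
        assert all(last.consensus in s for s in fg.values())

    def test_determinism(self):
        a = simulate_sequences(SimulationConfig(seed=10))
        b = simulate_sequences(SimulationConfig(seed=10))
        assert a[0] == b[0] and a[1] == b[1]

    def test_masked_runs_injected(self):
        cfg = SimulationConfig(seed=11, mask_n_runs=2)
        fg, _, _, _ = simulate_sequences(cfg)
        assert all("N" in s for s in fg.values())


def test_bundle_files_byte_identical(tmp_path, default_bundle):
    """Writing the same bundle twice produces byte-identical files."""
    d1, d2 = tmp_path / "a", tmp_path / "b"
    default_bundle.write(d1)
    default_bundle.write(d2)
    files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
    files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
    assert files1 == files2
    for rel in files1:
        assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
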