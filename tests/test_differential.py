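"""The NB Wald engine: normalization, dispersion, testing, BH, direction calls."""

import numpy as np
import pandas as pd
import pytest

from acetyldiff.differential import (
    NBWaldTest,
    bh_adjust,
    call_differential,
    estimate_dispersions,
    estimate_size_factors,
)
from acetyldiff.quantify import CountMatrix

from conftest import make_nb_matrix


def _cm(array, n_case, n_control):
    samples = [f"case_{i}" for i in range(n_case)] + [
        f"control_{i}" for i in range(n_control)
    ]
    groups = pd.Series({s: s.split("_")[0] for s in samples})
    df = pd.DataFrame(array, columns=samples,
                      index=[f"f{i}" for i in range(len(array))])
    return CountMatrix(df, groups)


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        cm = _cm([[5, 5, 5, 5], [9, 9, 9, 9]], 2, 2)
        assert np.allclose(estimate_size_factors(cm), 1.0)

    def test_hand_computed_two_sample_example(self):
        cm = _cm([[2, 4], [4, 8], [6, 12]], 1, 1)
        sf = estimate_size_factors(cm).to_numpy()
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_scale_equivariance_of_factor_ratios(self):
        # overall scale of size factors is arbitrary; the identified quantity
        # is the ratio between samples, which doubling one column doubles
        rng = np.random.default_rng(0)
        counts = rng.poisson(100, size=(50, 4)) + 1
        sf1 = estimate_size_factors(_cm(counts, 2, 2))
        doubled = counts.copy()
        doubled[:, 0] *= 2
        sf2 = estimate_size_factors(_cm(doubled, 2, 2))
        assert np.isclose(sf2.iloc[0] / sf2.iloc[1], 2 * sf1.iloc[0] / sf1.iloc[1])
        assert np.allclose(sf2.iloc[1:] / sf2.iloc[1], sf1.iloc[1:] / sf1.iloc[1])

    def test_no_all_positive_feature_raises(self):
        cm = _cm([[0, 1, 1, 1], [1, 0, 1, 1]], 2, 2)
        with pytest.raises(ValueError, match="filter"):
            estimate_size_factors(cm)


class TestDispersions:
    def test_poisson_data_small_alpha(self):
        rng = np.random.default_rng(1)
        mu = rng.uniform(100, 500, size=5000)
        counts = rng.poisson(mu[:, None], size=(5000, 9))
        cm = _cm(counts, 5, 4)
        sf = estimate_size_factors(cm)
        alpha = estimate_dispersions(cm, sf)
        assert alpha.median() <= 0.01

    def test_constant_feature_floored(self):
        counts = np.vstack([np.full(9, 50), np.full(9, 80), np.full(9, 120)])
        cm = _cm(counts, 5, 4)
        sf = estimate_size_factors(cm)
        alpha = estimate_dispersions(cm, sf)
        assert (alpha >= 1e-8).all()

    def test_nb_alpha_recovery(self):
        rng = np.random.default_rng(2)
        cm = make_nb_matrix(rng, 5000, lfc=0.0, mu_range=(50, 500), alpha=0.05)
        sf = estimate_size_factors(cm)
        alpha = estimate_dispersions(cm, sf)
        assert 0.03 <= alpha.median() <= 0.08

    def test_too_few_samples_raises(self):
        cm = _cm([[1, 2]], 1, 1)
        with pytest.raises(ValueError, match="3 samples"):
            estimate_dispersions(cm, pd.Series([1.0, 1.0], index=cm.sample_ids))


class TestWald:
    def test_constant_counts_null(self):
        counts = np.tile([[100], [40], [7]], (1, 9))
        res = NBWaldTest().fit(_cm(counts, 5, 4)).results_
        assert np.allclose(res["log2fc"], 0.0, atol=1e-9)
        assert np.allclose(res["p"], 1.0)
        assert (res["direction"] == "ns").all()

    def test_group_swap_negates_lfc_preserves_p(self):
        rng = np.random.default_rng(3)
        cm = make_nb_matrix(rng, 200, lfc=1.0)
        res = NBWaldTest().fit(cm).results_
        swapped_groups = cm.groups.map({"case": "control", "control": "case"})
        res2 = NBWaldTest().fit(CountMatrix(cm.counts, swapped_groups)).results_
        assert np.allclose(res2["log2fc"], -res["log2fc"], atol=1e-6)
        assert np.allclose(res2["p"], res["p"], atol=1e-9)

    def test_sample_scaling_leaves_lfc_invariant(self):
        rng = np.random.default_rng(4)
        lfc = np.where(np.arange(100) < 20, 1.5, 0.0)
        cm = make_nb_matrix(rng, 100, lfc=lfc, mu_range=(50, 200))
        res = NBWaldTest().fit(cm).results_
        scaled = cm.counts.copy()
        scaled.iloc[:, 0] *= 3
        cm2 = CountMatrix(scaled, cm.groups)
        sf1 = estimate_size_factors(cm)
        sf2 = estimate_size_factors(cm2)
        assert np.isclose(sf2.iloc[0] / sf2.iloc[1], 3 * sf1.iloc[0] / sf1.iloc[1],
                          rtol=1e-9)
        # size-factor ratios absorb the rescaling exactly; the pooled GLM
        # group estimate is only near-invariant (rescaling one sample of a
        # group does not commute with offset-weighted pooling)
        res2 = NBWaldTest().fit(cm2).results_
        assert np.allclose(res2["log2fc"], res["log2fc"], atol=0.05)
        assert np.corrcoef(res2["log2fc"], res["log2fc"])[0, 1] > 0.999

    def test_matches_statsmodels_glm_oracle(self):
        """IRLS fit agrees per-feature with statsmodels NB GLM at the same alpha."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        cm = make_nb_matrix(rng, 20, lfc=1.5)
        est = NBWaldTest().fit(cm)
        sf = est.size_factors_.to_numpy()
        x = cm.group_indicator()
        X = np.column_stack([np.ones(9), x])
        for i, fid in enumerate(cm.feature_ids):
            alpha = est.dispersions_[fid]
            y = cm.counts.loc[fid].to_numpy()
            model = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(sf),
            ).fit()
            row = est.results_.loc[fid]
            assert np.isclose(row["log2fc"], model.params[1] / np.log(2), atol=1e-4)
            assert np.isclose(row["se"], model.bse[1] / np.log(2), rtol=1e-3)

    def test_requires_two_per_group(self):
        cm = _cm([[1, 2, 3]], 1, 2)
        with pytest.raises(ValueError, match="2 samples"):
            NBWaldTest().fit(cm)

    def test_all_zero_features_dropped(self):
        rng = np.random.default_rng(6)
        cm = make_nb_matrix(rng, 10, lfc=0.0)
        with_zero = pd.concat(
            [cm.counts, pd.DataFrame(0, index=["zero"], columns=cm.sample_ids)]
        )
        res = NBWaldTest().fit(CountMatrix(with_zero, cm.groups)).results_
        assert "zero" not in res.index


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_order_equivariance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_propagated_and_excluded(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # m = 2: adj = min(0.01*2/1, 0.04*2/2) monotone -> [0.02, 0.04]
        assert np.allclose(out[[0, 2]], [0.02, 0.04])

    def test_matches_statsmodels_reference(self):
        multi = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            ref = multi.multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)


class TestDirectionCalls:
    def test_zero_lfc_never_called(self):
        res = pd.DataFrame(
            {"log2fc": [0.0, 1.0], "p": [1e-9, 1e-9], "padj": [1e-8, 1e-8]},
            index=["a", "b"],
        )
        out = call_differential(res)
        assert out.loc["a", "direction"] == "ns"
        assert out.loc["b", "direction"] == "hyper"

    def test_raw_p_flag(self):
        res = pd.DataFrame(
            {"log2fc": [-1.0], "p": [0.01], "padj": [0.2]}, index=["a"]
        )
        assert call_differential(res, use_padj=True).loc["a", "direction"] == "ns"
        assert call_differential(res, use_padj=False).loc["a", "direction"] == "hypo"

    def test_rna_vocabulary(self):
        res = pd.DataFrame(
            {"log2fc": [1.0, -1.0], "p": [1e-9] * 2, "padj": [1e-8] * 2},
            index=["a", "b"],
        )
        out = call_differential(res, arm="rna")
        assert out["direction"].tolist() == ["up", "down"]
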