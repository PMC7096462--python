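import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import regen_signature as rs
from regen_signature.de import (
    DISPERSION_FLOOR,
    NormalizationError,
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    wald_de_test,
)

from conftest import brute_force_bh


def two_condition_sheet(pair="S1", n=3):
    ids = [f"{pair}_wt{i}" for i in range(1, n + 1)] + [
        f"{pair}_mut{i}" for i in range(1, n + 1)
    ]
    return pd.DataFrame(
        {"pair_id": pair, "condition": ["wt"] * n + ["mut"] * n},
        index=pd.Index(ids, name="sample_id"),
    )


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame([[10, 20], [30, 60], [50, 100]], columns=["a", "b"])
        sf = estimate_size_factors(counts)
        assert sf["a"] == pytest.approx(0.7071, abs=1e-4)
        assert sf["b"] == pytest.approx(1.4142, abs=1e-4)

    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 80, 13, 200])
        counts = pd.DataFrame({s: col for s in "abcd"})
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 4)), columns=list("abcd"))
        sf = estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 3
        sf2 = estimate_size_factors(scaled)
        # factors are defined up to a common constant, so compare ratios
        assert sf2["c"] / sf2["a"] == pytest.approx(3 * sf["c"] / sf["a"], rel=1e-9)
        assert sf2["b"] / sf2["a"] == pytest.approx(sf["b"] / sf["a"], rel=1e-9)

    def test_no_universally_expressed_gene_raises(self):
        counts = pd.DataFrame([[0, 5], [3, 0]], columns=["a", "b"])
        with pytest.raises(NormalizationError, match="nonzero"):
            estimate_size_factors(counts)

    def test_idempotence_after_dividing_out(self):
        rng = np.random.default_rng(1)
        depth = np.array([0.5, 1.0, 2.0, 1.5])
        counts = pd.DataFrame(
            rng.poisson(rng.lognormal(4, 1, 200)[:, None] * depth), columns=list("abcd")
        )
        sf = estimate_size_factors(counts)
        renorm = counts / sf
        sf2 = estimate_size_factors(renorm)
        assert np.allclose(sf2 / np.exp(np.mean(np.log(sf2))), 1.0, atol=1e-6)


class TestDispersion:
    def test_constant_counts_hit_floor(self):
        sheet = two_condition_sheet(n=3)
        counts = pd.DataFrame(
            np.full((10, 6), 50), columns=sheet.index, index=[f"g{i}" for i in range(10)]
        )
        sf = pd.Series(1.0, index=sheet.index)
        disp = estimate_dispersions(counts, sf, sheet, "S1")
        assert (disp == DISPERSION_FLOOR).all()

    def test_poisson_counts_estimate_near_zero(self):
        """Under Poisson noise (alpha=0) gene-wise estimates of well-expressed
        genes concentrate near zero, far below a real overdispersion level."""
        rng = np.random.default_rng(2)
        sheet = two_condition_sheet(n=50)
        counts = pd.DataFrame(
            rng.poisson(1000.0, size=(300, 100)),
            columns=sheet.index,
            index=[f"g{i}" for i in range(300)],
        )
        sf = pd.Series(1.0, index=sheet.index)
        disp = estimate_dispersions(counts, sf, sheet, "S1")
        assert np.mean(disp < 0.01) >= 0.90

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(3)
        alpha, mu = 0.2, 500.0
        shape = 1 / alpha
        sheet = two_condition_sheet(n=50)
        counts = pd.DataFrame(
            rng.negative_binomial(shape, shape / (shape + mu), size=(400, 100)),
            columns=sheet.index,
            index=[f"g{i}" for i in range(400)],
        )
        sf = pd.Series(1.0, index=sheet.index)
        disp = estimate_dispersions(counts, sf, sheet, "S1")
        assert np.median(disp) == pytest.approx(alpha, rel=0.25)

    def test_unknown_pair_raises(self, default_run):
        _, cm, _, _ = default_run
        sf = pd.Series(1.0, index=cm.counts.columns)
        with pytest.raises(KeyError, match="ZZ"):
            estimate_dispersions(cm.counts, sf, cm.sample_sheet, "ZZ")


class TestWaldTest:
    def test_condition_swap_negates_log2fc(self):
        rng = np.random.default_rng(4)
        sheet = two_condition_sheet(n=4)
        counts = pd.DataFrame(
            rng.poisson(rng.lognormal(4, 1, 80)[:, None], size=(80, 8)),
            columns=sheet.index,
            index=[f"g{i}" for i in range(80)],
        )
        res = wald_de_test(counts, sheet, "S1")
        swapped_sheet = sheet.copy()
        swapped_sheet["condition"] = sheet["condition"].map({"wt": "mut", "mut": "wt"})
        res_sw = wald_de_test(counts, swapped_sheet, "S1")
        tested = res.table["p_value"].notna()
        np.testing.assert_allclose(
            res_sw.table.loc[tested, "log2fc"], -res.table.loc[tested, "log2fc"], atol=1e-10
        )
        np.testing.assert_allclose(
            res_sw.table.loc[tested, "p_value"], res.table.loc[tested, "p_value"], atol=1e-12
        )

    def test_all_zero_genes_reported_untested(self):
        sheet = two_condition_sheet(n=3)
        mat = np.vstack([np.full(6, 30), np.zeros(6), np.full(6, 10)])
        counts = pd.DataFrame(mat, columns=sheet.index, index=["g0", "gz", "g1"])
        res = wald_de_test(counts, sheet, "S1")
        assert np.isnan(res.table.loc["gz", "p_value"])
        assert np.isnan(res.table.loc["gz", "fdr"])
        assert res.table.loc[["g0", "g1"], "p_value"].notna().all()

    def test_null_pvalues_approximately_uniform_at_large_n(self):
        """With many replicates and small dispersion the Wald p-values under
        the null pass a pooled KS test against uniformity at the 1% level."""
        pooled = []
        for seed in range(3):
            cfg = rs.SimConfig(
                n_genes=400,
                n_replicates=30,
                pair_ids=("S1", "G3", "G5"),
                n_shared_up=0,
                n_shared_down=0,
                n_specific_per_pair=0,
                effect_log2fc=0.0,
                dispersion=0.01,
                seed=100 + seed,
            )
            cm, _ = rs.simulate_counts(cfg)
            res = wald_de_test(cm.counts, cm.sample_sheet, "S1")
            pooled.append(res.table["p_value"].dropna().to_numpy())
        from scipy.stats import kstest

        stat = kstest(np.concatenate(pooled), "uniform")
        assert stat.pvalue > 0.01

    def test_recovers_planted_log2fc(self):
        # DE genes must stay a minority or median-of-ratios normalization
        # absorbs part of the planted effect
        cfg = rs.SimConfig(
            n_genes=2000,
            n_replicates=5,
            n_shared_up=200,
            n_shared_down=0,
            n_specific_per_pair=0,
            effect_log2fc=2.0,
            dispersion=0.05,
            seed=9,
        )
        cm, truth = rs.simulate_counts(cfg)
        res = wald_de_test(cm.counts, cm.sample_sheet, "S1")
        up = truth.genes_in_category("shared_up")
        assert res.table.loc[up, "log2fc"].mean() == pytest.approx(2.0, abs=0.2)

    def test_power_increases_with_effect_size(self):
        """Detection of |log2FC| = 1.5 beats |log2FC| = 0.5 under the same seed."""
        rates = {}
        for effect in (0.5, 1.5):
            cfg = rs.SimConfig(
                n_genes=500, n_shared_up=50, n_shared_down=0, n_specific_per_pair=0,
                effect_log2fc=effect, dispersion=0.1, seed=21,
            )
            cm, truth = rs.simulate_counts(cfg)
            res = wald_de_test(cm.counts, cm.sample_sheet, "S1")
            up = truth.genes_in_category("shared_up")
            rates[effect] = (res.table.loc[up, "fdr"] < 0.05).mean()
        assert rates[1.5] > rates[0.5]

    def test_agrees_with_pydeseq2_on_fold_changes(self):
        """Independent cross-check: mutant/wildtype log2FCs track DESeq2's
        estimates on the same counts (different dispersion machinery, so
        agreement is correlational, not exact)."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = rs.SimConfig(
            n_genes=300, n_shared_up=30, n_shared_down=30, n_specific_per_pair=0,
            effect_log2fc=1.5, dispersion=0.1, seed=2,
        )
        cm, _ = rs.simulate_counts(cfg)
        rows = cm.sample_sheet[cm.sample_sheet["pair_id"] == "S1"]
        mine = wald_de_test(cm.counts, cm.sample_sheet, "S1").table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=cm.counts[rows.index].T, metadata=rows[["condition"]],
                design="~condition", quiet=True,
            )
            dds.deseq2()
            stats = DeseqStats(dds, contrast=["condition", "mut", "wt"], quiet=True)
            stats.summary()
        theirs = stats.results_df["log2FoldChange"].reindex(mine.index)
        ok = mine["log2fc"].notna() & theirs.notna()
        r = np.corrcoef(mine.loc[ok, "log2fc"], theirs[ok])[0, 1]
        assert r > 0.95


class TestBHAdjust:
    def test_step_up_ties_to_largest_bound(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(bh_adjust(p), 0.05)

    def test_all_ones(self):
        assert np.allclose(bh_adjust(np.ones(4)), 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_permutation_equivariance(self, p, rnd):
        p = np.asarray(p)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30))
    def test_dominates_p_and_stays_in_unit_interval(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])
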