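import numpy as np
import pandas as pd
import pytest

from scipy import stats as sps

from helixscape.fitness import (
    combine_replicates,
    fitness_table,
    log2_foldchange,
    replicate_fitness,
    size_factors,
    test_differential as differential_test,
)
from helixscape.genotype_space import MASTER


def _table(rows, cols, rng=None, lam=200):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        rng.poisson(lam, size=(rows, cols)),
        index=pd.Index([f"g{i}" for i in range(rows)], name="genotype"),
        columns=[f"s{j}" for j in range(cols)],
    )


class TestSizeFactors:
    def test_identical_columns_all_one(self):
        t = _table(50, 4)
        t = pd.concat([t[["s0"]]] * 4, axis=1)
        t.columns = list("abcd")
        assert np.allclose(size_factors(t), 1.0)

    def test_doubled_column_has_double_factor(self):
        t = _table(200, 3) + 1
        t["dbl"] = 2 * t["s0"]
        f = size_factors(t)
        assert f["dbl"] / f["s0"] == pytest.approx(2.0, rel=1e-9)

    def test_matches_brute_force_median_of_ratios(self):
        t = _table(300, 5, rng=np.random.default_rng(4))
        f = size_factors(t)
        # independent re-derivation with pandas semantics
        pos = t[(t > 0).all(axis=1)]
        geo = np.exp(np.log(pos).mean(axis=1))
        brute = (pos.div(geo, axis=0)).median()
        assert np.allclose(f, brute)

    def test_no_common_genotype_falls_back_to_totals(self, caplog):
        t = pd.DataFrame({"a": [5, 0], "b": [0, 7]},
                         index=pd.Index(["g0", "g1"], name="genotype"))
        with caplog.at_level("WARNING"):
            f = size_factors(t)
        assert (f > 0).all()
        assert any("total-count" in m for m in caplog.messages)


class TestReplicateFitness:
    def _counts(self, mapping, reps=1):
        return pd.DataFrame(
            {f"r{i}": pd.Series(mapping) for i in range(reps)}
        ).rename_axis("genotype")

    def test_unchanged_pool_gives_zero(self):
        pre = self._counts({MASTER: 1000, "g": 100}, reps=3)
        s, var = replicate_fitness(pre, pre.copy())
        assert np.allclose(s, 0.0)
        assert (var > 0).all().all()

    def test_doubling_vs_stable_master_gives_ln2(self):
        pre = self._counts({MASTER: 10_000, "g": 500})
        post = self._counts({MASTER: 10_000, "g": 1000})
        s, _ = replicate_fitness(pre, post, pseudocount=0.0)
        assert s.loc["g", "rep1"] == pytest.approx(np.log(2))

    def test_plug_in_arithmetic(self):
        """s = ln(50.5/2000.5) - ln(100.5/1000.5) for the worked counts."""
        pre = self._counts({MASTER: 1000, "g": 100})
        post = self._counts({MASTER: 2000, "g": 50})
        s, var = replicate_fitness(pre, post, pseudocount=0.5)
        expected = np.log(50.5 / 2000.5) - np.log(100.5 / 1000.5)
        assert s.loc["g", "rep1"] == pytest.approx(expected)
        assert expected == pytest.approx(-1.3811, abs=1e-4)
        assert var.loc["g", "rep1"] == pytest.approx(
            1 / 100.5 + 1 / 50.5 + 1 / 1000.5 + 1 / 2000.5
        )

    def test_replicate_structure_mismatch(self):
        pre = self._counts({MASTER: 10, "g": 5}, reps=2)
        post = self._counts({MASTER: 10, "g": 5}, reps=3)
        with pytest.raises(ValueError):
            replicate_fitness(pre, post)

    def test_missing_master_rejected(self):
        pre = self._counts({"g": 5})
        with pytest.raises(ValueError, match="master"):
            replicate_fitness(pre, pre)


class TestCombineReplicates:
    def test_equal_variances_reduce_to_simple_mean(self):
        s = pd.DataFrame({"r1": [0.1, -0.4], "r2": [0.3, -0.2]}, index=["a", "b"])
        var = pd.DataFrame(1.0, index=s.index, columns=s.columns)
        out = combine_replicates(s, var)
        assert np.allclose(out["s"], s.mean(axis=1))

    def test_infinite_variance_replicate_ignored(self):
        s = pd.DataFrame({"r1": [0.5], "r2": [99.0]}, index=["a"])
        var = pd.DataFrame({"r1": [0.04], "r2": [np.inf]}, index=["a"])
        out = combine_replicates(s, var)
        assert out.loc["a", "s"] == pytest.approx(0.5)

    def test_all_infinite_flagged_unestimable(self):
        s = pd.DataFrame({"r1": [0.5], "r2": [1.0]}, index=["a"])
        var = pd.DataFrame(np.inf, index=s.index, columns=s.columns)
        out = combine_replicates(s, var)
        assert np.isnan(out.loc["a", "s"]) and np.isnan(out.loc["a", "se"])

    def test_se_inflated_when_scatter_exceeds_poisson(self):
        tight = pd.DataFrame({"r1": [0.0], "r2": [0.0], "r3": [0.0]}, index=["a"])
        loose = pd.DataFrame({"r1": [-2.0], "r2": [0.0], "r3": [2.0]}, index=["a"])
        var = pd.DataFrame(0.01, index=["a"], columns=tight.columns)
        se_tight = combine_replicates(tight, var).loc["a", "se"]
        se_loose = combine_replicates(loose, var).loc["a", "se"]
        assert se_loose > 10 * se_tight


class TestDifferential:
    def test_zero_effect_has_p_one(self):
        comb = pd.DataFrame({"s": [0.0, 2.0], "se": [0.5, 0.1]}, index=["a", "b"])
        p = differential_test(comb)
        assert p["a"] == pytest.approx(1.0)
        assert p["b"] < 1e-10

    def test_bh_is_monotone_in_raw_p(self):
        rng = np.random.default_rng(8)
        comb = pd.DataFrame({"s": rng.normal(0, 1, 100), "se": np.ones(100)})
        p_adj = differential_test(comb)
        raw = 2 * sps.norm.sf(np.abs(comb["s"]))
        order = np.argsort(raw)
        assert (np.diff(p_adj.to_numpy()[order]) >= -1e-12).all()


class TestLog2FoldChange:
    def test_unchanged_pool_is_zero(self):
        pre = _table(20, 2)
        post = pre.copy()
        post.columns = ["p0", "p1"]
        l2 = log2_foldchange(pre, post, factors=pd.Series(1.0, index=list(pre) + list(post)))
        assert np.allclose(l2, 0.0)

    def test_fourfold_increase_is_two(self):
        pre = _table(20, 2) + 1
        post = 4 * pre
        post.columns = ["p0", "p1"]
        l2 = log2_foldchange(pre, post,
                             factors=pd.Series(1.0, index=list(pre) + list(post)),
                             pseudocount=0.0)
        assert np.allclose(l2, 2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        pre, post = _table(50, 3, rng), _table(50, 3, rng)
        post.columns = ["p0", "p1", "p2"]
        both = pd.concat([pre, post], axis=1)
        f = size_factors(both)
        l2 = log2_foldchange(pre, post, factors=f)
        brute = np.log2((post / f[post.columns]).sum(axis=1) + 0.5) - np.log2(
            (pre / f[pre.columns]).sum(axis=1) + 0.5
        )
        assert np.allclose(l2, brute)


@pytest.fixture(scope="module")
def small_fitness(small_experiment):
    exp = small_experiment
    return fitness_table(exp.counts, exp.sample_sheet, "30C"), exp


class TestFitnessTable:
    def test_master_fitness_exactly_one(self, small_fitness):
        ft, _ = small_fitness
        assert ft.loc[MASTER, "f"] == 1.0

    def test_all_zero_pre_genotypes_missing_not_zero(self, small_fitness):
        ft, exp = small_fitness
        pre_cols = [c for c in exp.counts if "30C_pre" in c]
        zero_pre = exp.counts.index[exp.counts[pre_cols].sum(axis=1) == 0]
        assert len(zero_pre) > 0
        assert not ft.index.isin(zero_pre).any()
        assert not (ft["f"] == 0).any()

    def test_rescaling_leaves_ratios_unchanged(self, small_fitness):
        """f is exp of master-normalized s, so ratios are scale-free."""
        ft, exp = small_fitness
        sub = ft.dropna(subset=["f"]).head(100)
        pre_cols = [c for c in exp.counts if "30C_pre" in c]
        post_cols = [c for c in exp.counts if "30C_post" in c]
        pre = exp.counts.loc[sub.index, pre_cols]
        post = exp.counts.loc[sub.index, post_cols]
        # recompute with a different (arbitrary) reference scaling
        s, var = replicate_fitness(
            exp.counts[pre_cols], exp.counts[post_cols], master=MASTER
        )
        comb = combine_replicates(s.loc[sub.index], var.loc[sub.index])
        assert np.allclose(np.exp(comb["s"]), sub["f"], rtol=1e-10, equal_nan=True)

    def test_estimator_error_shrinks_with_depth(self):
        """Consistency: median log-fitness error over the master's immediate
        neighbourhood falls as sequencing depth grows."""
        from helixscape.synthetic_data import (
            SimConfig, TwoStateParams, canonical_space, simulate_experiment,
        )

        master_seq = MASTER.replace("-", "")
        errs = []
        for depth in (10_000, 100_000, 1_000_000):
            cfg = SimConfig(seed=3, depth=depth, params=TwoStateParams(sigma=0.0))
            exp = simulate_experiment(cfg, temperatures=("30C",))
            ft = fitness_table(exp.counts, exp.sample_sheet, "30C")
            truth = pd.Series(exp.truth["30C"].w, index=canonical_space())
            d1 = [g for g in ft.index
                  if sum(a != b for a, b in zip(g.replace("-", ""), master_seq)) <= 1]
            errs.append(float(np.median(
                np.abs(np.log(ft.loc[d1, "f"]) - np.log(truth.loc[d1]))
            )))
        assert errs[0] > errs[1] > errs[2]

    def test_agrees_with_pydeseq2_on_small_fixture(self, small_experiment):
        """Independent oracle: DESeq2-style fold-changes rank identically."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats
        from scipy import stats

        exp = small_experiment
        counts = exp.counts[[c for c in exp.counts if "30C" in c]]
        keep = [g for g in counts.index[counts.sum(axis=1) >= 300] if g != MASTER]
        rng = np.random.default_rng(1)
        sub = counts.loc[[MASTER] + list(rng.choice(keep, 200, replace=False))]
        sheet = exp.sample_sheet[exp.sample_sheet.temperature == "30C"]
        ft = fitness_table(sub, sheet, "30C")

        meta = sheet.set_index("sample").loc[sub.columns]
        meta["condition"] = np.where(meta["selected"], "kan", "nokan")
        dds = DeseqDataSet(counts=sub.T, metadata=meta[["condition"]],
                           design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "kan", "nokan"], quiet=True)
        ds.summary()
        merged = ft.join(ds.results_df["log2FoldChange"]).dropna(
            subset=["log2fc", "log2FoldChange"]
        )
        rho, _ = stats.spearmanr(merged["log2fc"], merged["log2FoldChange"])
        assert rho > 0.95
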