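import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methrestore.dmr import (GenomicWindow, call_dmrs, dmr_summary,
                             filter_cpgs, likelihood_ratio_test, tile_windows)
from methrestore.dmr import test_window as window_test
from methrestore.io import SampleSheet
from methrestore.simulate import SimulationConfig, simulate_methylome


def make_tables(meth, depth, samples):
    """Per-sample CpG tables from (n_cpgs, n_samples) count arrays."""
    meth = np.atleast_2d(meth)
    depth = np.atleast_2d(depth)
    pos = np.arange(1, meth.shape[0] + 1) * 10
    return {
        sid: pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+",
                           "meth": meth[:, j],
                           "unmeth": depth[:, j] - meth[:, j]})
        for j, sid in enumerate(samples)}


class TestTileWindows:
    def test_enumeration_with_clipping(self):
        wins = tile_windows({"chr1": 2000})
        assert [(w.start, w.end) for w in wins] == [
            (1, 1000), (501, 1500), (1001, 2000), (1501, 2000)]

    def test_exact_length(self):
        wins = tile_windows({"chr1": 1000})
        assert [(w.start, w.end) for w in wins] == [(1, 1000), (501, 1000)]

    def test_consecutive_starts_offset_by_step(self):
        wins = tile_windows({"chr1": 10_000})
        starts = [w.start for w in wins]
        assert all(b - a == 500 for a, b in zip(starts, starts[1:]))
        assert all(s % 500 == 1 for s in starts)

    @pytest.mark.parametrize("window,step", [(0, 500), (1000, 0),
                                             (-1, 500)])
    def test_bad_parameters(self, window, step):
        with pytest.raises(ValueError):
            tile_windows({"chr1": 1000}, window=window, step=step)


class TestFilterCpgs:
    def test_all_samples_must_reach_depth(self):
        depth = np.array([[25, 22, 30, 21, 20, 20],
                          [25, 22, 30, 21, 19, 20]])
        mask = filter_cpgs(depth, min_depth=20)
        assert list(mask) == [True, False]

    def test_min_depth_one_is_identity(self):
        depth = np.array([[1, 2], [3, 1]])
        assert filter_cpgs(depth, min_depth=1).all()

    def test_group_mean_scope(self):
        depth = np.array([[30, 10]])
        assert filter_cpgs(depth, min_depth=20, scope="group_mean").all()
        assert not filter_cpgs(depth, min_depth=20).any()


class TestTestWindow:
    window = GenomicWindow("chr1", 1, 1000)
    groups = (["a1", "a2", "a3"], ["b1", "b2", "b3"])

    def test_null_case(self):
        meth = np.full((2, 6), 25)
        depth = np.full((2, 6), 50)
        rec = window_test(self.window,
                          make_tables(meth, depth, sum(self.groups, [])),
                          self.groups)
        assert rec["delta_beta"] == 0
        assert rec["p"] > 0.9

    def test_extreme_separation(self):
        meth = np.concatenate([np.zeros((3, 3)), np.full((3, 3), 10)],
                              axis=1).astype(int)
        depth = np.full((3, 6), 10)
        rec = window_test(self.window,
                          make_tables(meth, depth, sum(self.groups, [])),
                          self.groups)
        assert rec["delta_beta"] == 100
        assert rec["p"] < 1e-6
        # Fisher's exact on the pooled 2x2 agrees on extremity
        assert stats.fisher_exact([[0, 90], [90, 0]])[1] < 1e-6

    def test_label_swap_negates_delta_keeps_p(self):
        rng = np.random.default_rng(1)
        meth = rng.integers(0, 20, (4, 6))
        depth = meth + rng.integers(1, 20, (4, 6))
        tables = make_tables(meth, depth, sum(self.groups, []))
        fwd = window_test(self.window, tables, self.groups)
        rev = window_test(self.window, tables,
                          (self.groups[1], self.groups[0]))
        assert fwd["delta_beta"] == pytest.approx(-rev["delta_beta"])
        assert fwd["p"] == pytest.approx(rev["p"])

    def test_too_few_cpgs_returns_none(self):
        meth = np.full((1, 6), 5)
        depth = np.full((1, 6), 10)
        tables = make_tables(meth, depth, sum(self.groups, []))
        assert window_test(self.window, tables, self.groups) is None

    def test_pooling_invariance(self):
        """Scaling every count by k preserves delta exactly and cannot
        raise the p-value."""
        rng = np.random.default_rng(2)
        meth = rng.integers(2, 15, (3, 6))
        depth = meth + rng.integers(2, 15, (3, 6))
        base = window_test(self.window,
                           make_tables(meth, depth, sum(self.groups, [])),
                           self.groups)
        for k in (2, 5):
            scaled = window_test(
                self.window,
                make_tables(meth * k, depth * k, sum(self.groups, [])),
                self.groups)
            assert scaled["delta_beta"] == pytest.approx(
                base["delta_beta"])
            assert scaled["p"] <= base["p"] + 1e-12


class TestLikelihoodRatioOracle:
    def test_rank_agreement_with_fisher(self):
        """On pooled 2x2 tables the LRT must order significance like
        Fisher's exact test (rank correlation of -log p > 0.99)."""
        rng = np.random.default_rng(5)
        n = 300
        na = rng.integers(20, 200, n)
        nb = rng.integers(20, 200, n)
        ka = rng.binomial(na, rng.uniform(0.1, 0.9, n))
        kb = rng.binomial(nb, rng.uniform(0.1, 0.9, n))
        _, p_lrt = likelihood_ratio_test(ka, na, kb, nb)
        p_fisher = np.array([
            stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])[1]
            for k1, n1, k2, n2 in zip(ka, na, kb, nb)])
        rho = stats.spearmanr(-np.log(np.maximum(p_lrt, 1e-300)),
                              -np.log(np.maximum(p_fisher, 1e-300))
                              ).statistic
        assert rho > 0.99


class TestCallDmrs:
    def test_planted_windows_recovered(self):
        """Strong planted shifts are called; null windows are not."""
        cfg = SimulationConfig(
            genome=(("chr1", 260_000),), n_cpg_per_kb=5.0,
            planted_a=10, planted_b=0, meth_shift=40.0, seed=11)
        tables, truth = simulate_methylome(cfg)
        res = call_dmrs(tables, cfg.sample_sheet(), ("saline", "OVA"))
        planted = set(truth.dmr_id)
        called = set(res.dmrs.id)
        assert len(planted & called) >= 9
        null_windows = res.windows.loc[~res.windows.id.isin(planted)]
        # planted CpGs spill into the overlapping half-windows; exclude
        near = null_windows.start.isin(
            set(truth.start - 500) | set(truth.start + 500))
        false_rate = null_windows.loc[~near, "id"].isin(called).mean()
        assert false_rate <= 0.01

    def test_contrast_groups_must_exist(self, default_sim):
        with pytest.raises(KeyError):
            call_dmrs(default_sim["tables"], default_sim["sheet"],
                      ("saline", "nonexistent"))

    def test_impossible_min_diff_calls_nothing(self, default_sim):
        res = call_dmrs(default_sim["tables"], default_sim["sheet"],
                        ("saline", "OVA"), min_diff=101.0)
        assert len(res.dmrs) == 0
        assert (res.windows.delta_beta.abs() <= 100).all()

    def test_every_dmr_satisfies_thresholds(self, pipeline_run):
        for label, called in pipeline_run["result"].dmrs.items():
            assert (called.delta_beta.abs() >= 10).all()
            assert (called.q < 0.01).all()
            assert (called.n_cpgs >= 2).all()


class TestDmrSummary:
    @pytest.mark.parametrize("args,expected", [
        ((23154, 12247, 445288), (5.2, 2.75)),
        ((4818, 4379, 449539), (1.07, 0.97)),
        ((0, 0, 100), (0.0, 0.0)),
    ])
    def test_percentages(self, args, expected):
        assert dmr_summary(*args) == expected

    def test_zero_total_is_error(self):
        with pytest.raises(ZeroDivisionError):
            dmr_summary(1, 1, 0)

    def test_counts_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            dmr_summary(60, 50, 100)
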