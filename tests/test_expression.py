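import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from methrestore.expression import (de_test, normalize_counts,
                                    signed_fold_change)
from methrestore.io import SampleSheet

SHEET_3V3 = SampleSheet({f"s{i}": "saline" for i in range(3)}
                        | {f"o{i}": "OVA" for i in range(3)})
SAMPLES = list(SHEET_3V3.samples)


def nb_counts(rng, means, dispersion, n):
    if dispersion <= 0:
        return rng.poisson(np.broadcast_to(means, (n, len(means))).T)
    lam = rng.gamma(1.0 / dispersion, means[:, None] * dispersion,
                    size=(len(means), n))
    return rng.poisson(lam)


class TestNormalize:
    def test_single_column_cpm(self):
        m = pd.DataFrame({"s": [1, 1, 2]})
        assert list(normalize_counts(m)["s"]) == [250_000, 250_000,
                                                  500_000]

    def test_column_already_at_million_is_unchanged(self):
        m = pd.DataFrame({"s": [400_000, 600_000]}, dtype=float)
        pd.testing.assert_frame_equal(normalize_counts(m), m)

    def test_scale_invariance_per_column(self):
        m = pd.DataFrame({"a": [3, 7, 11], "b": [2, 2, 6]})
        doubled = m.copy()
        doubled["a"] = m["a"] * 2
        pd.testing.assert_frame_equal(normalize_counts(m),
                                      normalize_counts(doubled))

    def test_zero_column_names_sample(self):
        m = pd.DataFrame({"good": [1, 2], "bad": [0, 0]})
        with pytest.raises(ValueError, match="bad"):
            normalize_counts(m)


class TestSignedFoldChange:
    @pytest.mark.parametrize("a,b,expected", [
        (10, 20, 2.0), (20, 10, -2.0), (7, 7, 1.0)])
    def test_examples(self, a, b, expected):
        assert signed_fold_change(a, b) == expected

    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4))
    def test_antisymmetry(self, a, b):
        fwd = signed_fold_change(a, b)
        rev = signed_fold_change(b, a)
        assert abs(fwd) >= 1 and abs(rev) >= 1
        if abs(fwd) > 1:  # the +1 boundary maps to +1 in both directions
            assert fwd == pytest.approx(-rev, rel=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            signed_fold_change(0, 5)


class TestDeTest:
    def test_identical_groups_are_null(self):
        col = np.array([100, 50, 300, 7])
        counts = pd.DataFrame({s: col for s in SAMPLES})
        res = de_test(counts, SHEET_3V3, ("saline", "OVA"))
        assert np.allclose(res.log2fc, 0)
        assert (res.p > 0.99).all()
        assert not res.significant.any()

    def test_poisson_null_calibration(self):
        """No-effect Poisson counts: empirical type-I error near 0.05."""
        rng = np.random.default_rng(12)
        lam = rng.lognormal(np.log(100), 0.5, 1000)
        counts = pd.DataFrame(
            {s: rng.poisson(lam) for s in SAMPLES})
        res = de_test(counts, SHEET_3V3, ("saline", "OVA"))
        assert 0.03 <= (res.p < 0.05).mean() <= 0.07

    def test_power_at_fourfold_change(self):
        """>= 80% of transcripts with a true 4-fold change are flagged
        (NB counts, mean 100, dispersion 0.1, 3 vs 3)."""
        rng = np.random.default_rng(7)
        base = np.concatenate([np.full(100, 100.0),
                               rng.lognormal(np.log(100), 0.5, 400)])
        shifted = base.copy()
        shifted[:100] = base[:100] / 4
        counts = pd.DataFrame(
            {s: nb_counts(rng, base, 0.1, 1)[:, 0] for s in SAMPLES[:3]}
            | {s: nb_counts(rng, shifted, 0.1, 1)[:, 0]
               for s in SAMPLES[3:]})
        res = de_test(counts, SHEET_3V3, ("saline", "OVA"))
        assert res.significant[:100].mean() >= 0.8

    def test_threshold_consistency(self, pipeline_run):
        """significant <=> |fc| >= 2 and p < 0.05 on real results."""
        for res in pipeline_run["result"].expr.values():
            expected = (res.fc_signed.abs() >= 2) & (res.p < 0.05)
            assert (res.significant == expected).all()
            assert (res.fc_signed.abs() >= 1).all()
            assert (np.sign(res.fc_signed.where(res.fc_signed.abs() > 1))
                    .fillna(1) == np.sign(res.log2fc).replace(0, 1)).all()

    def test_sign_convention(self):
        """A transcript 4x lower in group b reports fc near -4."""
        rng = np.random.default_rng(3)
        flat = rng.integers(500, 1500, 99)
        counts = pd.DataFrame(
            {s: np.concatenate([[4000], flat]) for s in SAMPLES[:3]}
            | {s: np.concatenate([[1000], flat]) for s in SAMPLES[3:]})
        res = de_test(counts, SHEET_3V3, ("saline", "OVA"))
        assert res.fc_signed.iloc[0] == pytest.approx(-4.0, rel=0.05)
        assert np.sign(res.fc_signed.iloc[0]) == np.sign(
            res.log2fc.iloc[0])

    def test_agrees_with_deseq2_oracle(self):
        """Independent NB implementation (pyDESeq2) confirms the calls:
        same direction for every significant transcript and >= 90%
        of them significant there too."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(42)
        base = np.concatenate([np.full(40, 150.0),
                               rng.lognormal(np.log(150), 0.5, 160)])
        shifted = base.copy()
        shifted[:20] = base[:20] / 4
        shifted[20:40] = base[20:40] * 4
        counts = pd.DataFrame(
            {s: nb_counts(rng, base, 0.1, 1)[:, 0] for s in SAMPLES[:3]}
            | {s: nb_counts(rng, shifted, 0.1, 1)[:, 0]
               for s in SAMPLES[3:]},
            index=[f"t{i}" for i in range(200)])
        mine = de_test(counts, SHEET_3V3, ("saline", "OVA"))

        meta = pd.DataFrame({"condition": ["a"] * 3 + ["b"] * 3},
                            index=SAMPLES)
        dds = DeseqDataSet(counts=counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "b", "a"], quiet=True)
        ds.summary()
        both = mine.join(ds.results_df[["log2FoldChange", "pvalue"]])
        sig = both[both.significant]
        assert len(sig) >= 40
        assert (np.sign(sig.log2fc)
                == np.sign(sig.log2FoldChange)).all()
        assert (sig.pvalue < 0.05).mean() >= 0.9

    def test_single_replicate_group_rejected(self):
        sheet = SampleSheet({"a": "saline", "b": "OVA", "c": "OVA"})
        counts = pd.DataFrame({"a": [1], "b": [2], "c": [3]})
        with pytest.raises(ValueError, match="2 samples"):
            de_test(counts, sheet, ("saline", "OVA"))

    def test_all_zero_transcript_dropped(self):
        counts = pd.DataFrame({s: [10, 0] for s in SAMPLES},
                              index=["keep", "drop"])
        res = de_test(counts, SHEET_3V3, ("saline", "OVA"))
        assert list(res.index) == ["keep"]
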