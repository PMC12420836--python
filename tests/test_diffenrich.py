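"""TMM normalization and the exact NB test: oracles and calibration."""

import numpy as np
import pandas as pd
import pytest

from tectool.diffenrich import (
    NBTestConfig,
    aggregate_subfamilies,
    benjamini_hochberg,
    estimate_common_dispersion,
    ma_table,
    nb_test,
    tmm_factors,
)


def _nb(rng, mean, dispersion, size):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


class TestAggregate:
    def _meta(self, loci, subfams):
        return pd.DataFrame(
            {
                "subfamily": subfams,
                "family": ["F"] * len(loci),
                "te_class": ["LINE"] * len(loci),
            },
            index=pd.Index(loci, name="locus"),
        )

    def test_single_subfamily_equals_column_sums(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(5, 3)),
                              index=[f"l{i}" for i in range(5)], columns=list("abc"))
        out = aggregate_subfamilies(counts, self._meta(counts.index, ["L1MdT"] * 5))
        assert out.shape == (1, 3)
        assert (out.iloc[0] == counts.sum(axis=0)).all()

    def test_column_sums_conserved_and_matches_recount(self, rng):
        n = 60
        loci = [f"l{i}" for i in range(n)]
        subfams = [f"S{rng.integers(6)}" for _ in range(n)]
        counts = pd.DataFrame(rng.integers(0, 400, size=(n, 4)), index=loci,
                              columns=list("abcd"))
        out = aggregate_subfamilies(counts, self._meta(loci, subfams))
        assert (out.sum(axis=0) == counts.sum(axis=0)).all()
        for sf in set(subfams):
            members = [l for l, s in zip(loci, subfams) if s == sf]
            assert (out.loc[f"{sf}:F:LINE"] == counts.loc[members].sum(axis=0)).all()

    def test_unmapped_locus_is_an_error(self, rng):
        counts = pd.DataFrame([[1, 2]], index=["lx"], columns=["a", "b"])
        with pytest.raises(ValueError, match="lx"):
            aggregate_subfamilies(counts, self._meta([], []))


class TestTMM:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.integers(1, 500, size=30)
        counts = pd.DataFrame({c: col for c in "abcd"})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self, rng):
        col = rng.integers(1, 500, size=50)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        assert np.allclose(tmm_factors(counts), 1.0, atol=1e-12)

    def test_matches_edger_reference_values(self):
        """Frozen reference factors computed with edgeR::calcNormFactors
        (Bioconductor 4.0.16, method='TMM') on this 6x4 matrix."""
        x = np.array(
            [
                [100, 210, 95, 400],
                [200, 380, 210, 100],
                [300, 640, 310, 50],
                [50, 90, 48, 300],
                [400, 820, 410, 60],
                [120, 260, 118, 500],
            ]
        )
        counts = pd.DataFrame(x, columns=list("abcd"))
        expected = [0.8766332239, 0.8768824163, 0.8668657177, 1.5006827289]
        assert np.allclose(tmm_factors(counts), expected, atol=1e-8)

    def test_geometric_mean_is_exactly_one(self, rng):
        counts = pd.DataFrame(rng.integers(0, 800, size=(40, 5)), columns=list("abcde"))
        f = tmm_factors(counts + 1)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_column_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(counts)


class TestBH:
    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        ours = benjamini_hochberg(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)
        assert (ours >= p - 1e-15).all()


class TestNBTest:
    def _frame(self, x, groups=("a1", "a2", "a3", "b1", "b2", "b3")):
        return pd.DataFrame(x, columns=list(groups),
                            index=[f"S{i}" for i in range(x.shape[0])])

    def test_identical_groups_yield_no_calls(self, rng):
        half = _nb(rng, 200, 0.1, size=(50, 3))
        counts = self._frame(np.hstack([half, half]))
        res = nb_test(counts, None, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert np.allclose(res["log2FC"], 0.0, atol=1e-9)
        assert (res["call"] == "NotSig").all()

    def test_single_replicate_rejected(self, rng):
        counts = self._frame(_nb(rng, 100, 0.1, size=(10, 6)))
        with pytest.raises(ValueError, match="2 replicates"):
            nb_test(counts, None, ["a1"], ["b1", "b2", "b3"])

    def test_group_swap_negates_log2fc_preserves_p(self, rng):
        counts = self._frame(_nb(rng, 150, 0.1, size=(80, 6)))
        counts.iloc[:10, :3] *= 4  # some signal
        a, b = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        r1 = nb_test(counts, None, a, b)
        r2 = nb_test(counts, None, b, a)
        assert np.allclose(r1["log2FC"], -r2["log2FC"], atol=1e-9)
        assert np.allclose(r1["pvalue"], r2["pvalue"], atol=1e-12)

    def test_scale_invariance_of_fold_changes_and_calls(self, rng):
        counts = self._frame(_nb(rng, 150, 0.1, size=(60, 6)))
        counts.iloc[:5, :3] *= 8
        a, b = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        r1 = nb_test(counts, None, a, b)
        r2 = nb_test(counts * 10, None, a, b)
        assert np.allclose(r1["log2FC"], r2["log2FC"], atol=1e-9)
        assert (r1["call"] == r2["call"]).all()

    def test_null_type_i_error_calibrated(self):
        """2000 null NB rows, 3 vs 3: raw p<0.05 within 3 binomial SEs."""
        rng = np.random.default_rng(1234)
        counts = self._frame(_nb(rng, 200, 0.1, size=(2000, 6)))
        res = nb_test(counts, None, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        frac = float((res["pvalue"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < 3 * se
        assert (res["call"] == "NotSig").all() or (res["padj"] >= res["pvalue"]).all()

    def test_planted_fourfold_subfamily_power(self):
        """A subfamily planted at 4-fold (member loci at mean 200,
        dispersion 0.1, 40 copies as in the default annotation, 3 vs 3)
        is called Up at BH-adjusted p<0.01 in >=95% of 200 replicates."""
        rng = np.random.default_rng(99)
        hits = 0
        n_reps = 200
        n_subfam, n_loci = 10, 40
        for _ in range(n_reps):
            mu = np.full((n_subfam * n_loci, 6), 200.0)
            mu[:n_loci, :3] *= 4.0  # first subfamily planted Up in group A
            r = 10.0
            locus_counts = rng.negative_binomial(r, r / (r + mu))
            x = locus_counts.reshape(n_subfam, n_loci, 6).sum(axis=1)
            counts = self._frame(x)
            res = nb_test(counts, None, ["a1", "a2", "a3"], ["b1", "b2", "b3"],
                          NBTestConfig(alpha=0.01))
            if res.iloc[0]["call"] == "Up":
                hits += 1
        assert hits / n_reps >= 0.95

    def test_dispersion_estimate_recovers_truth(self):
        rng = np.random.default_rng(5)
        pseudo = _nb(rng, 300, 0.15, size=(3000, 6)).astype(float)
        groups = np.array([0, 0, 0, 1, 1, 1])
        est = estimate_common_dispersion(pseudo, groups)
        assert est == pytest.approx(0.15, rel=0.15)

    def test_invalid_dispersion_rejected(self, rng):
        counts = self._frame(_nb(rng, 100, 0.1, size=(10, 6)))
        with pytest.raises(ValueError, match="dispersion"):
            nb_test(counts, None, ["a1", "a2", "a3"], ["b1", "b2", "b3"],
                    NBTestConfig(dispersion=-1.0))


class TestMATable:
    def test_rows_conserved_and_finite_logcpm(self, rng):
        counts = pd.DataFrame(
            np.vstack([np.zeros((1, 6), dtype=int), _nb(rng, 150, 0.1, size=(20, 6))]),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
            index=[f"S{i}" for i in range(21)],
        )
        res = nb_test(counts, None, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        ma = ma_table(res)
        assert len(ma) == len(counts)
        assert np.isfinite(ma["logCPM"]).all()

    def test_requires_result_columns(self):
        with pytest.raises(ValueError, match="missing"):
            ma_table(pd.DataFrame({"log2FC": [1.0]}))
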