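"""Scrambler contract, pulldown classification, PWM scanning, Fisher motifs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from tectool.bait import (
    BaitSequence,
    PWM,
    cpg_positions,
    methylate_in_silico,
    motif_enrichment,
    pulldown_enrichment,
    scan_pwm,
    scramble_preserving_cpg,
)
from tectool.simulate import PlantedBinder, simulate_pulldown


def _random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


class TestScrambler:
    def test_acgt_minimal_example(self):
        out = scramble_preserving_cpg("ACGT", seed=0)
        assert out[1:3] == "CG"
        assert sorted(out) == list("ACGT")

    def test_no_cpg_input_stays_cpg_free(self, rng):
        seq = "ATTATTAGGATTA"
        out = scramble_preserving_cpg(seq, seed=1)
        assert cpg_positions(out) == []
        assert sorted(out) == sorted(seq)

    def test_contract_on_100_random_500bp_sequences(self, rng):
        """Length, composition and exact CpG positions preserved."""
        for i in range(100):
            seq = _random_seq(rng, 500, gc=0.55)
            out = scramble_preserving_cpg(seq, seed=1000 + i)
            assert len(out) == len(seq)
            assert sorted(out) == sorted(seq)
            assert cpg_positions(out) == cpg_positions(seq)

    def test_deterministic_under_seed(self, rng):
        seq = _random_seq(rng, 400, gc=0.6)
        assert scramble_preserving_cpg(seq, seed=7) == scramble_preserving_cpg(seq, seed=7)

    def test_actually_shuffles(self, rng):
        seq = _random_seq(rng, 400, gc=0.5)
        assert scramble_preserving_cpg(seq, seed=7) != seq

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            scramble_preserving_cpg("ACGNT", seed=0)


class TestBaitBookkeeping:
    def test_cpg_positions_enumerated(self):
        bait = BaitSequence("b", "ACGCGT")
        assert bait.cpg_positions == [1, 3]

    def test_methylation_records_one_per_cpg(self):
        bait = methylate_in_silico(BaitSequence("b", "ACGCGTACGA"))
        assert bait.methylated
        assert len(bait.methylation_records) == 3

    def test_zero_cpg_bait(self):
        bait = methylate_in_silico(BaitSequence("b", "ATTA"))
        assert bait.methylated and bait.methylation_records == ()

    def test_idempotent_with_warning(self):
        bait = methylate_in_silico(BaitSequence("b", "ACGT"))
        with pytest.warns(UserWarning, match="already methylated"):
            again = methylate_in_silico(bait)
        assert again == bait


class TestPulldown:
    def _universe(self, n=50):
        return [f"P{i:03d}" for i in range(n)] + ["NRF1", "CREB1"]

    def test_no_planted_binders_no_calls(self):
        tables = simulate_pulldown(self._universe(), [], replicates=3, seed=1)
        calls = pulldown_enrichment(tables)
        assert not any(c.sequence_specific or c.methyl_sensitive for c in calls)

    def test_planted_specific_methyl_sensitive_binder_recovered(self):
        binder = PlantedBinder("NRF1", sequence_specific=True, methyl_sensitive=True)
        tables = simulate_pulldown(self._universe(), [binder], replicates=3, seed=2)
        by_name = {c.protein: c for c in pulldown_enrichment(tables)}
        assert by_name["NRF1"].sequence_specific
        assert by_name["NRF1"].methyl_sensitive

    def test_unspecific_binder_excluded_from_specific_set(self):
        binder = PlantedBinder("CREB1", sequence_specific=False, methyl_sensitive=True)
        tables = simulate_pulldown(self._universe(), [binder], replicates=3, seed=3)
        by_name = {c.protein: c for c in pulldown_enrichment(tables)}
        assert by_name["CREB1"].methyl_sensitive
        assert not by_name["CREB1"].sequence_specific

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            simulate_pulldown(self._universe(), [], replicates=1, seed=0)

    def test_protein_with_missing_values_skipped(self):
        tables = simulate_pulldown(self._universe(), [], replicates=3, seed=4)
        tables["bait_methylated"].loc["P000", ["rep1", "rep2"]] = np.nan
        calls = {c.protein: c for c in pulldown_enrichment(tables)}
        assert "bait_methylated" in calls["P000"].skipped_reason

    def test_welch_log2fc_is_mean_log_difference(self):
        tables = {
            "bait_unmethylated": pd.DataFrame({"rep1": [64.0], "rep2": [64.0], "rep3": [128.0]},
                                              index=["X"]),
            "bait_methylated": pd.DataFrame({"rep1": [8.0], "rep2": [8.0], "rep3": [16.0]},
                                            index=["X"]),
            "scrambled_unmethylated": pd.DataFrame({"rep1": [8.0], "rep2": [8.0], "rep3": [8.0]},
                                                   index=["X"]),
            "scrambled_methylated": pd.DataFrame({"rep1": [8.0], "rep2": [8.0], "rep3": [8.0]},
                                                 index=["X"]),
        }
        (call,) = pulldown_enrichment(tables)
        assert call.log2fc_bait == pytest.approx(3.0)


class TestPWMScan:
    def _exact_pwm(self, word):
        mat = np.full((len(word), 4), 1e-12)
        for i, b in enumerate(word):
            mat[i, "ACGT".index(b)] = 1.0
        mat /= mat.sum(axis=1, keepdims=True)
        return PWM(name=word, matrix=mat)

    def test_exact_match_indicator(self):
        pwm = self._exact_pwm("GCGC")
        hits = scan_pwm("AAGCGCAA", pwm)
        assert {(h.position, h.strand) for h in hits} == {(2, "+"), (2, "-")}

    def test_uniform_pwm_scores_zero(self):
        pwm = PWM(name="uniform", matrix=np.full((4, 4), 0.25))
        hits = scan_pwm("ACGTACGT", pwm, threshold=1e-9)
        assert hits == []
        hits0 = scan_pwm("ACGTACGT", pwm, threshold=0.0)
        assert all(h.score == pytest.approx(0.0) for h in hits0)

    def test_reverse_complement_hit(self):
        pwm = self._exact_pwm("AAAC")  # revcomp GTTT
        hits = scan_pwm("GGGTTTGG", pwm)
        assert any(h.strand == "-" and h.position == 2 for h in hits)

    def test_non_acgt_scored_as_background(self):
        pwm = self._exact_pwm("ACGT")
        assert scan_pwm("NNNN", pwm, threshold=1e-6) == []

    def test_matches_bruteforce_rescoring(self, rng):
        pwm = PWM(name="m", matrix=rng.dirichlet(np.ones(4), size=8))
        lo = pwm.log_odds()
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(200):
            seq = _random_seq(rng, 50)
            thr = 0.3 * lo.max(axis=1).sum()
            got = {(h.position, h.strand): h.score for h in scan_pwm(seq, pwm, thr)}
            expected = {}
            for start in range(len(seq) - 7):
                window = seq[start : start + 8]
                fwd = sum(lo[j, "ACGT".index(b)] for j, b in enumerate(window))
                rc = "".join(comp[b] for b in reversed(window))
                rev = sum(lo[j, "ACGT".index(b)] for j, b in enumerate(rc))
                if fwd >= thr:
                    expected[(start, "+")] = fwd
                if rev >= thr:
                    expected[(start, "-")] = rev
            assert set(got) == set(expected)
            for k in got:
                assert got[k] == pytest.approx(expected[k], abs=1e-9)


class TestMotifEnrichment:
    def _planted_sets(self, rng, t_rate, b_rate, n_t=100, n_b=400):
        word = "GCGCATGCGC"
        targets, background = {}, {}
        for i in range(n_t):
            s = _random_seq(rng, 200, gc=0.4)
            if rng.random() < t_rate:
                s = s[:90] + word + s[100:]
            targets[f"t{i}"] = s
        for i in range(n_b):
            s = _random_seq(rng, 200, gc=0.4)
            if rng.random() < b_rate:
                s = s[:90] + word + s[100:]
            background[f"b{i}"] = s
        return targets, background

    def test_planted_enrichment_detected(self, rng):
        from tectool.simulate import nrf1_pwm

        targets, background = self._planted_sets(rng, 0.5, 0.05)
        table = motif_enrichment(targets, background, [nrf1_pwm()])
        assert table.loc["NRF1_synthetic", "p_value"] < 1e-3

    def test_absent_motif_reports_na_and_p_one(self, rng):
        pwm = TestPWMScan()._exact_pwm("AAAAAAAAAA")
        targets = {f"t{i}": _random_seq(rng, 60, gc=0.9) for i in range(10)}
        table = motif_enrichment(targets, targets, [pwm])
        assert np.isnan(table["odds_ratio"]).all()
        assert (table["p_value"] == 1.0).all()

    def test_target_equals_background_not_enriched(self, rng):
        from tectool.simulate import nrf1_pwm

        targets, _ = self._planted_sets(rng, 0.5, 0.0, n_t=60, n_b=1)
        table = motif_enrichment(targets, targets, [nrf1_pwm()])
        assert table["p_value"].iloc[0] >= 0.5
        assert table["odds_ratio"].iloc[0] == pytest.approx(1.0)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            motif_enrichment({}, {"b": "ACGT"}, [])

    def test_fisher_matches_hypergeometric_tail_all_margins(self):
        """One-sided Fisher p equals the exhaustive hypergeometric tail sum
        on every 2x2 table with margins <= 30."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(300):
            n_t = int(rng.integers(1, 31))
            n_b = int(rng.integers(1, 31))
            k_t = int(rng.integers(0, n_t + 1))
            k_b = int(rng.integers(0, n_b + 1))
            table = [[k_t, n_t - k_t], [k_b, n_b - k_b]]
            _, p = ss.fisher_exact(table, alternative="greater")
            # tail sum of the hypergeometric pmf
            total, drawn, successes = n_t + n_b, n_t, k_t + k_b
            tail = sum(
                ss.hypergeom.pmf(x, total, successes, drawn)
                for x in range(k_t, min(drawn, successes) + 1)
            )
            assert p == pytest.approx(tail, abs=1e-9)
            checked += 1
        assert checked == 300
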