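from math import comb

import numpy as np
import pytest

from amyloscan import (PeptideRecord, SyntheticConfig,
                       TrainingConfig, binomial_tail, candidate_cutoffs,
                       class_content, confidence_levels, count_tripeptides,
                       generate_hexapeptides, rank_and_select, stats_report,
                       tripeptide_index, tune_cutoff)
from amyloscan.selection import BinomialTripeptideSelector, FeatureSpec, \
    rank_tripeptides


def exact_tail(n, N, q):
    """Direct term-by-term summation of the upper binomial tail."""
    return sum(comb(N, k) * q ** k * (1 - q) ** (N - k) for k in range(n, N + 1))


def _records(pos, neg):
    recs = [PeptideRecord(f"p{i}", s, 1) for i, s in enumerate(pos)]
    recs += [PeptideRecord(f"n{i}", s, 0) for i, s in enumerate(neg)]
    return recs


class TestCountTripeptides:
    def test_single_window_each(self):
        ct = count_tripeptides(_records(["AAA"], ["CCC"]))
        assert ct.counts_pos[tripeptide_index("AAA")] == 1
        assert ct.counts_neg[tripeptide_index("CCC")] == 1
        assert ct.q_pos == ct.q_neg == 0.5

    def test_token_counting(self):
        ct = count_tripeptides(_records(["AAAA"], ["CCC"]))
        assert ct.counts_pos[tripeptide_index("AAA")] == 2
        assert ct.q_pos == pytest.approx(2 / 3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            count_tripeptides(_records(["AAA"], []))

    def test_total_tokens_conserved(self, planted_dataset):
        ct = count_tripeptides(planted_dataset)
        expect = sum(len(r.sequence) - 2 for r in planted_dataset)
        assert ct.counts_total.sum() == expect

    def test_class_content_by_enumeration(self):
        pos, neg = ["AAAC", "CAAA"], ["GGG"]
        ct = count_tripeptides(_records(pos, neg))
        table = class_content(ct).set_index("tripeptide")
        # brute force: enumerate every window of every positive sequence
        windows = [s[i:i + 3] for s in pos for i in range(len(s) - 2)]
        for t in set(windows):
            assert table.loc[t, "content_pos"] == \
                pytest.approx(windows.count(t) / len(windows))


class TestBinomialTail:
    def test_tail_from_zero_is_one(self):
        assert binomial_tail(0, 10, 0.3) == pytest.approx(1.0)

    def test_single_bernoulli(self):
        assert binomial_tail(1, 1, 0.5) == pytest.approx(0.5)

    def test_matches_direct_summation(self):
        assert binomial_tail(7, 10, 0.3) == pytest.approx(
            exact_tail(7, 10, 0.3), abs=1e-14)

    def test_endpoint_qN(self):
        assert binomial_tail(12, 12, 0.4) == pytest.approx(0.4 ** 12, rel=1e-12)

    def test_monotone_nonincreasing_in_n(self):
        vals = [binomial_tail(n, 30, 0.62) for n in range(31)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("n,N,q", [(-1, 5, 0.5), (6, 5, 0.5), (2, 5, 0.0),
                                       (2, 5, 1.0)])
    def test_invalid_inputs(self, n, N, q):
        with pytest.raises(ValueError):
            binomial_tail(n, N, q)

    def test_monte_carlo_consistency(self):
        n, N, q = 3, 12, 0.4
        rng = np.random.default_rng(123)
        draws = rng.binomial(N, q, size=1_000_000)
        freq = (draws >= n).mean()
        p = binomial_tail(n, N, q)
        se = np.sqrt(p * (1 - p) / 1_000_000)
        assert abs(freq - p) < 3 * se


class TestConfidenceLevels:
    def test_unseen_tripeptide_cl_zero(self):
        ct = count_tripeptides(_records(["AAA"], ["CCC"]))
        stats = confidence_levels(ct)
        by_t = {s.tripeptide: s for s in stats}
        assert by_t["DDD"].cl == 0.0

    def test_one_sided_large_count_cl_near_one(self):
        ct = count_tripeptides(_records(["AAAA" * 5], ["CCCC" * 5]))
        stats = {s.tripeptide: s for s in confidence_levels(ct)}
        assert stats["AAA"].cl > 0.99

    def test_matches_exact_summation(self, planted_dataset):
        ct = count_tripeptides(planted_dataset[:10] + planted_dataset[-10:])
        stats = confidence_levels(ct)
        checked = 0
        for s in stats:
            if s.count_total == 0:
                continue
            p_pos = exact_tail(s.count_pos, s.count_total, ct.q_pos)
            p_neg = exact_tail(s.count_neg, s.count_total, ct.q_neg)
            assert s.cl == pytest.approx(1 - min(p_pos, p_neg), abs=1e-12)
            checked += 1
        assert checked >= 20


class TestRankAndSelect:
    def test_all_zero_threshold_empty(self):
        ct = count_tripeptides(_records(["AAA"], ["AAA"]))
        stats = confidence_levels(ct)
        spec = rank_and_select(stats, "threshold", 0.85)
        assert spec.selected_tripeptides == []

    def test_top_k_all(self, planted_stats):
        spec = rank_and_select(planted_stats, "top_k", 8000)
        assert len(spec.selected_tripeptides) == 8000

    def test_invalid_values(self, planted_stats):
        with pytest.raises(ValueError):
            rank_and_select(planted_stats, "top_k", 8001)
        with pytest.raises(ValueError):
            rank_and_select(planted_stats, "threshold", 1.5)

    def test_planted_tripeptides_rank_high(self, planted_stats, planted_config):
        ranks = {s.tripeptide: i + 1
                 for i, s in enumerate(rank_tripeptides(planted_stats))}
        planted = (planted_config.planted_tripeptides_pos
                   + planted_config.planted_tripeptides_neg)
        assert all(ranks[t] <= 20 for t in planted)

    def test_deterministic_byte_for_byte(self, planted_dataset, tmp_path):
        files = []
        for i in range(2):
            stats = confidence_levels(count_tripeptides(planted_dataset))
            spec = rank_and_select(stats, "threshold", 0.85)
            p = tmp_path / f"spec{i}.txt"
            spec.to_file(p)
            files.append(p.read_bytes())
        assert files[0] == files[1]

    def test_report_sorted_descending(self, planted_stats):
        rep = stats_report(planted_stats)
        assert (rep["CL"].diff().dropna() <= 1e-12).all()
        assert rep.shape[0] == 8000


class TestFeatureSpecFile:
    def test_roundtrip(self, planted_spec, tmp_path):
        p = tmp_path / "spec.txt"
        planted_spec.to_file(p)
        back = FeatureSpec.from_file(p)
        assert back.selected_tripeptides == planted_spec.selected_tripeptides
        assert back.total_dim == planted_spec.total_dim
        assert back.pseaac_params.lambda_rank == 2
        a = back.pseaac_params.scale_matrix()
        b = planted_spec.pseaac_params.scale_matrix()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_rejects_foreign_file(self, tmp_path):
        p = tmp_path / "junk.txt"
        p.write_text("hello\n")
        with pytest.raises(ValueError, match="not a feature-spec"):
            FeatureSpec.from_file(p)


class TestTuneCutoff:
    def test_single_candidate_returned(self, planted_dataset, planted_stats):
        cfg = TrainingConfig(n_trees=50, folds=3, seed=1)
        best, table = tune_cutoff([10], planted_dataset, planted_stats,
                                  config=cfg)
        assert best == 10 and len(table) == 1
        assert {"acc", "auc"} <= set(table.columns)

    def test_informative_set_beats_noise(self):
        # composition-neutral construction: the planted tripeptides are
        # reversed copies of each other (same residues, same lag products),
        # so the PseAAC block alone (k=0) is blind to the class and only the
        # tripeptide features (k=4, covering the plants) carry the signal
        cfg = SyntheticConfig(n_pos=120, n_neg=120, plant_rate=0.9,
                              composition_bias=0.0, seed=2,
                              planted_tripeptides_pos=("IVN", "LFA"),
                              planted_tripeptides_neg=("NVI", "AFL"))
        recs = generate_hexapeptides(cfg)
        stats = confidence_levels(count_tripeptides(recs))
        tcfg = TrainingConfig(n_trees=50, folds=3, seed=1)
        best, table = tune_cutoff([0, 4], recs, stats, config=tcfg)
        accs = table.set_index("k")["acc"]
        assert accs[4] > accs[0]
        assert best == 4

    def test_deterministic_winner(self, planted_dataset, planted_stats):
        cfg = TrainingConfig(n_trees=30, folds=3, seed=9)
        r1 = tune_cutoff([5, 20], planted_dataset, planted_stats, config=cfg)
        r2 = tune_cutoff([5, 20], planted_dataset, planted_stats, config=cfg)
        assert r1[0] == r2[0]
        assert r1[1].equals(r2[1])

    def test_candidate_enumeration_band(self, planted_stats):
        cands = candidate_cutoffs(planted_stats, lo=0.5, hi=0.99,
                                  max_candidates=10)
        assert 1 <= len(cands) <= 10
        ranked = rank_tripeptides(planted_stats)
        assert all(0.5 <= ranked[k - 1].cl <= 0.99 for k in cands)


class TestSelectorTransformer:
    def test_fit_transform_shapes(self, planted_dataset):
        X = [r.sequence for r in planted_dataset]
        y = [r.label for r in planted_dataset]
        sel = BinomialTripeptideSelector(mode="top_k", value=25).fit(X, y)
        assert len(sel.selected_tripeptides_) == 25
        Xt = sel.transform(X[:7])
        assert Xt.shape == (7, 25)
        # transformed columns are that sequence's TPC at the kept tripeptides
        from amyloscan import tpc_vector
        np.testing.assert_allclose(
            Xt[0], tpc_vector(X[0])[sel.selected_indices_], atol=1e-12)
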