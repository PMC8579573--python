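import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amyloscan import (AMINO_ACIDS, PseAACParams, correlation_factors,
                       encode_pseaac, encode_tpc, index_to_tripeptide,
                       pseaac_vector, standardize_scale, tpc_vector,
                       tripeptide_index)
from amyloscan.scales import RAW_SCALES, default_scales, load_scales_tsv, \
    write_scales_tsv

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=6, max_size=40)


def brute_force_pseaac(seq, scales, lam, w, count_mode):
    """Independent direct evaluation of the PseAAC definition (slow loops)."""
    L = len(seq)
    h = {s.name: s.standardized for s in scales}
    thetas = []
    for d in range(1, lam + 1):
        for s in scales:
            total = 0.0
            for i in range(L - d):
                total += h[s.name][seq[i]] * h[s.name][seq[i + d]]
            thetas.append(total / (L - d))
    f = []
    for aa in AMINO_ACIDS:
        c = seq.count(aa)
        f.append(c / L if count_mode == "frequency" else float(c))
    denom = sum(f) + w * sum(thetas)
    return np.array([x / denom for x in f] + [w * t / denom for t in thetas])


class TestScales:
    def test_standardized_mean_zero_sd_one(self):
        for name, raw in RAW_SCALES.items():
            s = standardize_scale(raw, name)
            vals = s.standardized_array()
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std(ddof=0) - 1) < 1e-9

    def test_already_standard_scale_unchanged(self):
        # ten +1 and ten -1: already mean 0, population sd 1
        raw = {aa: (1.0 if i % 2 == 0 else -1.0)
               for i, aa in enumerate(AMINO_ACIDS)}
        s = standardize_scale(raw, "pm1")
        assert s.standardized["A"] == pytest.approx(1.0)
        assert s.standardized["C"] == pytest.approx(-1.0)

    def test_manual_zscore_matches(self):
        raw = RAW_SCALES["hydrophobicity"]
        vals = np.array([raw[aa] for aa in AMINO_ACIDS])
        expect = (vals - vals.mean()) / vals.std(ddof=0)
        got = standardize_scale(raw, "h").standardized_array()
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize_scale({aa: 1.0 for aa in AMINO_ACIDS})

    def test_missing_amino_acid_named(self):
        raw = {aa: float(i) for i, aa in enumerate(AMINO_ACIDS) if aa != "W"}
        with pytest.raises(ValueError, match="W"):
            standardize_scale(raw)

    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "scales.tsv"
        write_scales_tsv(default_scales(), p)
        back = load_scales_tsv(p)
        assert [s.name for s in back] == [s.name for s in default_scales()]
        for a, b in zip(back, default_scales()):
            np.testing.assert_allclose(a.standardized_array(),
                                       b.standardized_array(), atol=1e-12)


class TestCorrelationFactors:
    def test_homopolymer_lag1_is_squared_property(self):
        params = PseAACParams(lambda_rank=1)
        th = correlation_factors("AAAAAA", params)
        expect = np.array([s.standardized["A"] ** 2 for s in params.scales])
        np.testing.assert_allclose(th, expect, atol=1e-12)

    def test_length_is_9_lambda(self):
        th = correlation_factors("ACDEFGHIK", PseAACParams(lambda_rank=2))
        assert th.shape == (18,)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="correlation rank"):
            correlation_factors("AC", PseAACParams(lambda_rank=2))

    def test_matches_direct_summation(self, toy_scales):
        params = PseAACParams(lambda_rank=1, scales=toy_scales)
        seq = "ACDG"
        th = correlation_factors(seq, params)
        for k, s in enumerate(toy_scales):
            h = s.standardized
            expect = sum(h[seq[i]] * h[seq[i + 1]] for i in range(3)) / 3
            assert th[k] == pytest.approx(expect, abs=1e-12)

    @given(seq_strategy)
    def test_reversal_leaves_theta_unchanged(self, seq):
        params = PseAACParams(lambda_rank=2)
        np.testing.assert_allclose(
            correlation_factors(seq, params),
            correlation_factors(seq[::-1], params), atol=1e-12)


class TestPseAAC:
    def test_default_dim_38(self):
        assert pseaac_vector("CGNLST", PseAACParams()).shape == (38,)
        fv = encode_pseaac("CGNLST")
        assert len(fv.names) == 38

    def test_homopolymer_single_nonzero_composition(self):
        v = pseaac_vector("AAAAAA", PseAACParams(lambda_rank=1))
        comp = v[:20]
        assert np.count_nonzero(comp) == 1
        assert comp[0] != 0  # A is first alphabetically

    @pytest.mark.parametrize("count_mode", ["count", "frequency"])
    def test_toy_oracle_full_vector(self, toy_scales, count_mode):
        params = PseAACParams(lambda_rank=1, scales=toy_scales,
                              count_mode=count_mode)
        seq = "ACDG"
        got = pseaac_vector(seq, params)
        expect = brute_force_pseaac(seq, toy_scales, 1, 0.7, count_mode)
        assert got.shape == (22,)
        np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_oracle_on_100_random_peptides(self):
        rng = np.random.default_rng(5)
        params = PseAACParams()
        for _ in range(100):
            L = int(rng.integers(6, 41))
            seq = "".join(rng.choice(list(AMINO_ACIDS), L))
            try:
                got = pseaac_vector(seq, params)
            except ValueError:
                continue  # degenerate normaliser: contract is to refuse
            expect = brute_force_pseaac(seq, params.scales, 2, 0.7, "count")
            np.testing.assert_allclose(got, expect, atol=1e-10)

    @given(seq_strategy)
    def test_sums_to_one(self, seq):
        try:
            v = pseaac_vector(seq, PseAACParams())
        except ValueError:
            return
        assert v.sum() == pytest.approx(1.0, abs=1e-9)
        assert (v[:20] >= 0).all()

    @given(seq_strategy)
    def test_permutation_preserves_composition_block(self, seq):
        params = PseAACParams()
        rng = np.random.default_rng(0)
        perm = "".join(rng.permutation(list(seq)))
        counts = np.array([seq.count(aa) for aa in AMINO_ACIDS], dtype=float)
        counts_perm = np.array([perm.count(aa) for aa in AMINO_ACIDS], dtype=float)
        np.testing.assert_array_equal(counts, counts_perm)

    def test_degenerate_denominator_rejected(self):
        # measured pathological hexapeptide: strongly anticorrelated lags
        with pytest.raises(ValueError, match="degenerate"):
            pseaac_vector("WDSWCS", PseAACParams())


class TestTripeptideIndex:
    def test_endpoints(self):
        assert tripeptide_index("AAA") == 0
        assert tripeptide_index("YYY") == 7999

    def test_bijection_over_all_codes(self):
        for i in range(8000):
            assert tripeptide_index(index_to_tripeptide(i)) == i

    @pytest.mark.parametrize("bad", ["AA", "AAAA", "AXA"])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            tripeptide_index(bad)


class TestTPC:
    def test_single_tripeptide(self):
        v = tpc_vector("AAA")
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_four_distinct_windows(self):
        v = tpc_vector("ACDEFG")
        for t in ("ACD", "CDE", "DEF", "EFG"):
            assert v[tripeptide_index(t)] == pytest.approx(0.25)

    def test_repeated_tripeptide(self):
        v = tpc_vector("AAAA")
        assert v[tripeptide_index("AAA")] == pytest.approx(1.0)

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            tpc_vector("AC")

    def test_names_dim_8000(self):
        assert len(encode_tpc("ACDEFG").names) == 8000

    @given(seq_strategy)
    def test_sums_to_one_and_sparsity(self, seq):
        v = tpc_vector(seq)
        assert v.sum() == pytest.approx(1.0, abs=1e-9)
        assert (v >= 0).all()
        assert np.count_nonzero(v) <= len(seq) - 2
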