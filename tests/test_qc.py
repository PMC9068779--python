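"""QC operations: HWE exact test, sequential filters, pruning, stratum bias."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epipair import (
    MISSING,
    QcConfig,
    filter_variants,
    hwe_exact_test,
    prune_by_distance,
    stratum_af_bias_test,
)

from .conftest import tiny_matrix, variant


def hwe_enumeration_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational enumeration of the conditional het-count distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    probs = {}
    for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom_a = (n_a - h) // 2
        hom_b = n - h - hom_a
        probs[h] = Fraction(
            factorial(n) * 2**h * factorial(n_a) * factorial(2 * n - n_a),
            factorial(hom_a) * factorial(h) * factorial(hom_b) * factorial(2 * n),
        )
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 37) == 1.0

    def test_allele_label_symmetry(self):
        for a, b, c in [(10, 10, 10), (3, 17, 5), (0, 4, 30)]:
            assert hwe_exact_test(a, b, c) == pytest.approx(
                hwe_exact_test(c, b, a), abs=1e-15
            )

    def test_matches_enumeration_oracle_spot(self):
        for a, b, c in [(10, 10, 10), (5, 0, 5), (1, 2, 3), (20, 5, 0), (7, 13, 2)]:
            assert hwe_exact_test(a, b, c) == pytest.approx(
                hwe_enumeration_oracle(a, b, c), abs=1e-12
            )

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_extreme_het_excess_is_small(self):
        # all-heterozygote tables are the classic HWE failure mode
        assert hwe_exact_test(0, 100, 0) < 1e-20

    def test_null_calibration_band(self):
        """Simulated HWE genotypes: rejection rate at 0.05 inside 99% band."""
        rng = np.random.default_rng(42)
        reps = 2000
        g = rng.binomial(2, 0.3, size=(reps, 500))
        hits = 0
        for row in g:
            a = int((row == 0).sum())
            b = int((row == 1).sum())
            c = int((row == 2).sum())
            hits += hwe_exact_test(a, b, c) <= 0.05
        rate = hits / reps
        half = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - half <= rate <= 0.05 + half


class TestFilterVariants:
    def test_reason_codes(self):
        # rs0 clean; rs1 fails HWE (all hets); rs2 fails call rate (20% missing)
        rng = np.random.default_rng(1)
        n = 200
        clean = rng.binomial(2, 0.4, n)
        het = np.ones(n, dtype=np.int8)
        gappy = rng.binomial(2, 0.4, n)
        gappy[: n // 5] = MISSING
        gm = tiny_matrix(np.column_stack([clean, het, gappy]))
        kept, report = filter_variants(gm, QcConfig())
        assert kept.rsids == ["rs0"]
        reasons = dict(zip(report.table["rsid"], report.table["reason"]))
        assert reasons == {"rs0": "", "rs1": "hwe", "rs2": "call_rate"}

    def test_info_r2_filter(self):
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, 0.4, size=(100, 2)).astype(np.int8)
        from epipair import GenotypeMatrix

        variants = [
            variant("rsA", pos=1_000, info_r2=0.9),
            variant("rsB", pos=2_000_000, info_r2=0.5),
        ]
        gm = GenotypeMatrix([f"S{i}" for i in range(100)], variants, calls)
        kept, report = filter_variants(gm, QcConfig())
        assert kept.rsids == ["rsA"]
        assert report.table.set_index("rsid").loc["rsB", "reason"] == "info_r2"

    def test_clean_input_identity_and_idempotence(self, null_data):
        gm, _ = null_data
        kept, report = filter_variants(gm, QcConfig())
        assert kept.rsids == gm.rsids
        assert report.table["pass"].all()
        kept2, report2 = filter_variants(kept, QcConfig())
        assert kept2.rsids == kept.rsids
        assert np.array_equal(kept2.calls, kept.calls)

    def test_counts_non_increasing(self, null_data):
        gm, _ = null_data
        _, report = filter_variants(gm, QcConfig())
        counts = list(report.counts.values())
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPruneByDistance:
    def test_within_window_keeps_most_significant(self):
        v1 = (variant("a", "1", 1_000_000), 1e-8)
        v2 = (variant("b", "1", 1_400_000), 1e-5)
        assert prune_by_distance([v1, v2], 500_000) == [v1]

    def test_outside_window_keeps_both(self):
        v1 = (variant("a", "1", 1_000_000), 1e-8)
        v2 = (variant("b", "1", 1_600_001), 1e-5)
        assert prune_by_distance([v1, v2], 500_000) == [v1, v2]

    def test_cross_chromosome_not_pruned(self):
        v1 = (variant("a", "1", 1_000_000), 1e-8)
        v2 = (variant("b", "2", 1_000_000), 1e-5)
        assert prune_by_distance([v1, v2], 500_000) == [v1, v2]

    def test_duplicate_position_keeps_smaller_p(self):
        v1 = (variant("a", "1", 1_000_000), 1e-5)
        v2 = (variant("b", "1", 1_000_000), 1e-8)
        with pytest.warns(UserWarning, match="duplicate"):
            out = prune_by_distance([v1, v2], 500_000)
        assert [v.rsid for v, _ in out] == ["b"]
        assert out[0][1] == 1e-8

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.data())
    def test_randomized_invariants(self, data):
        """No same-chromosome survivors within the window; global best kept."""
        n = data.draw(st.integers(2, 25))
        chroms = data.draw(
            st.lists(st.sampled_from(["1", "2", "3"]), min_size=n, max_size=n)
        )
        positions = data.draw(
            st.lists(
                st.integers(1, 5_000_000), min_size=n, max_size=n, unique=True
            )
        )
        pvals = data.draw(
            st.lists(
                st.floats(1e-12, 1.0, exclude_min=False),
                min_size=n,
                max_size=n,
                unique=True,
            )
        )
        items = [
            (variant(f"v{i}", chroms[i], positions[i]), pvals[i]) for i in range(n)
        ]
        out = prune_by_distance(items, 500_000)
        for i, (vi, _) in enumerate(out):
            for vj, _ in out[i + 1 :]:
                if vi.chrom == vj.chrom:
                    assert abs(vi.pos - vj.pos) > 500_000
        best = min(items, key=lambda t: t[1])
        assert best in out


class TestStratumBias:
    def test_single_stratum_rejected(self, null_data):
        gm, _ = null_data
        with pytest.raises(ValueError, match=">=2 strata"):
            stratum_af_bias_test(gm, ["CN"] * gm.n_samples)

    def test_identical_strata_retained(self):
        calls = np.tile([[0], [1], [2], [1]], (10, 1)).astype(np.int8)
        gm = tiny_matrix(calls)
        strata = (["CN", "MCI"] * 20)[: gm.n_samples]
        table, excluded = stratum_af_bias_test(gm, strata)
        assert excluded == []
        assert table["p_adjusted"].iloc[0] > 0.5

    def test_extreme_skew_flagged(self, rng):
        """One fully-skewed variant among null variants is the one flagged."""
        n = 40
        strata = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        null_calls = rng.binomial(2, 0.4, size=(n, 10))
        skew = np.concatenate([np.full(n // 2, 2), np.zeros(n // 2)])
        gm = tiny_matrix(np.column_stack([null_calls, skew]))
        table, excluded = stratum_af_bias_test(gm, strata)
        assert excluded == ["rs10"]
        # hypergeometric tail oracle for the fully-skewed 2x2 allele table
        from scipy import stats as ss

        oracle = ss.fisher_exact([[40, 0], [0, 40]])[1]
        assert table.set_index("rsid").loc["rs10", "min_pairwise_p"] == pytest.approx(
            oracle, rel=1e-10
        )
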