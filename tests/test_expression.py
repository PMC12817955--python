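"""Unit and property tests for normalization, DE and co-regulation analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from texrip import expression as expr
from texrip.io import Feature, GenomeAnnotation


class TestTpm:
    def test_equal_counts_equal_lengths_split_evenly(self):
        assert np.allclose(expr.tpm([10, 10], [100, 100]), [5e5, 5e5])

    def test_length_normalization(self):
        assert np.allclose(
            expr.tpm([10, 10], [100, 200]), [666666.6667, 333333.3333], atol=0.01
        )

    def test_all_zero_counts_give_all_zero(self):
        assert np.array_equal(expr.tpm([0, 0, 0], [10, 20, 30]), [0, 0, 0])

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            expr.tpm([1], [0])

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=10**6), min_size=2, max_size=20),
        st.data(),
    )
    def test_sum_is_one_million(self, counts, data):
        if sum(counts) == 0:
            counts[0] = 1
        lengths = data.draw(
            st.lists(
                st.integers(min_value=1, max_value=10**5),
                min_size=len(counts), max_size=len(counts),
            )
        )
        assert np.isclose(expr.tpm(counts, lengths).sum(), 1e6, rtol=1e-9)


class TestDeStandIn:
    def test_size_factor_ratio_for_doubled_counts(self, rng):
        counts = pd.DataFrame(
            rng.poisson(100, size=(50, 2)), columns=["a1", "a2"],
            index=[f"g{i}" for i in range(50)],
        ) + 1
        doubled = counts * 2
        sf = expr.size_factors(pd.concat([counts, doubled.rename(
            columns={"a1": "b1", "a2": "b2"})], axis=1))
        assert np.isclose(sf["b1"] / sf["a1"], 2.0)

    def test_null_groups_give_no_significant_features(self, rng):
        idx = [f"g{i}" for i in range(200)]
        a = pd.DataFrame(rng.poisson(100, size=(200, 3)), index=idx)
        b = pd.DataFrame(rng.poisson(100, size=(200, 3)), index=idx)
        res = expr.de_stand_in(a, b)
        assert np.abs(res["log2fc"]).mean() < 0.2
        # a handful of p < 0.05 by chance is fine, but the DE flag also
        # requires |lfc| >= 1, which null Poisson noise at depth 100 won't hit
        assert res["significant"].sum() == 0

    def test_planted_fourfold_change_recovered(self, rng):
        idx = [f"g{i}" for i in range(300)]
        lam = np.full(300, 200.0)
        a = pd.DataFrame(rng.poisson(lam, size=(3, 300)).T, index=idx)
        lam_b = lam.copy()
        lam_b[0] = 800.0
        b = pd.DataFrame(rng.poisson(lam_b, size=(3, 300)).T, index=idx)
        res = expr.de_stand_in(a, b).set_index("feature_id")
        assert abs(res.loc["g0", "log2fc"] - 2.0) <= 0.3
        assert res.loc["g0", "significant"]

    def test_mismatched_features_rejected(self):
        a = pd.DataFrame(np.ones((3, 2)), index=["x", "y", "z"])
        b = pd.DataFrame(np.ones((3, 2)), index=["x", "y", "w"])
        with pytest.raises(ValueError, match="differ"):
            expr.de_stand_in(a, b)

    def test_single_replicate_rejected(self):
        a = pd.DataFrame(np.ones((3, 1)), index=["x", "y", "z"])
        with pytest.raises(ValueError, match="replicates"):
            expr.de_stand_in(a, a.copy())

    def test_type_one_error_calibrated(self, rng):
        idx = [f"g{i}" for i in range(2000)]
        a = pd.DataFrame(rng.poisson(100, size=(2000, 3)), index=idx)
        b = pd.DataFrame(rng.poisson(100, size=(2000, 3)), index=idx)
        res = expr.de_stand_in(a, b)
        rate = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07


class TestBuildPairs:
    def test_antisense_overlap_rules(self):
        ann = GenomeAnnotation(
            [
                Feature("g1", "gene", 100, 500, "+"),
                Feature("g2", "gene", 500, 900, "+"),
                Feature("g3", "gene", 2000, 2400, "-"),
                Feature("as1", "asRNA", 200, 300, "-"),   # inside g1
                Feature("as2", "asRNA", 450, 550, "-"),   # spans g1/g2
                Feature("as3", "asRNA", 2100, 2200, "-"),  # same strand as g3
                Feature("as4", "asRNA", 5000, 5100, "-"),  # no overlap
            ]
        )
        pairs = expr.build_pairs(ann)
        keys = {(p.mrna_id, p.asrna_id) for p in pairs}
        assert keys == {("g1", "as1"), ("g1", "as2"), ("g2", "as2")}
        by_key = {(p.mrna_id, p.asrna_id): p.overlap_nt for p in pairs}
        assert by_key[("g1", "as2")] == 50 and by_key[("g2", "as2")] == 50


class TestPairPcc:
    def _pair(self):
        return expr.PairRecord("m", "a", 10)

    def test_identical_vectors_positive(self):
        v = pd.Series([1.0, -2.0, 3.0, 0.5])
        p = expr.pair_pcc(self._pair(), v, v.copy())
        assert p.pcc == pytest.approx(1.0) and p.corr_class == "positive"

    def test_negated_vectors_negative(self):
        x = pd.Series([1.0, 2.0, 3.0])
        p = expr.pair_pcc(self._pair(), x, -x)
        assert p.pcc == pytest.approx(-1.0) and p.corr_class == "negative"

    def test_hand_computed_value(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        y = pd.Series([1.0, 2.0, 3.0, 5.0])
        p = expr.pair_pcc(self._pair(), x, y)
        assert p.pcc == pytest.approx(6.5 / np.sqrt(5 * 8.75), abs=1e-6)
        assert p.corr_class == "positive"

    def test_threshold_is_inclusive(self):
        assert expr.classify_pcc(0.5) == "positive"
        assert expr.classify_pcc(-0.5) == "negative"
        assert expr.classify_pcc(0.49) == "uncorrelated"

    def test_too_few_contrasts_gives_missing(self):
        x = pd.Series([1.0, 2.0], index=["c1", "c2"])
        p = expr.pair_pcc(self._pair(), x, x.copy())
        assert p.pcc is None and p.corr_class == "uncorrelated"

    def test_zero_variance_gives_missing_not_zero(self):
        x = pd.Series([1.0, 1.0, 1.0, 1.0])
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        p = expr.pair_pcc(self._pair(), x, y)
        assert p.pcc is None and p.corr_class == "uncorrelated"

    def test_matches_brute_force_covariance_formula(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            p = expr.pair_pcc(
                self._pair(), pd.Series(x), pd.Series(y)
            )
            cov = np.mean((x - x.mean()) * (y - y.mean()))
            brute = cov / (x.std() * y.std())
            assert abs(p.pcc - brute) < 1e-12


class TestDirectionAgreement:
    def _pairs(self):
        return [
            expr.PairRecord("m1", "a1", 10, pcc=0.9, corr_class="positive"),
            expr.PairRecord("m2", "a2", 10, pcc=-0.8, corr_class="negative"),
        ]

    def test_sign_rule_by_hand(self):
        mrna = pd.Series({"m1": 1.2, "m2": 0.5})
        asrna = pd.Series({"a1": -0.8, "a2": 0.5})
        s = expr.direction_agreement(self._pairs(), mrna, asrna)
        assert s.pct_same == 50.0 and s.pct_opposite == 50.0

    def test_all_same_direction(self):
        mrna = pd.Series({"m1": 1.0, "m2": 2.0})
        asrna = pd.Series({"a1": 0.5, "a2": 3.0})
        s = expr.direction_agreement(self._pairs(), mrna, asrna)
        assert s.pct_same == 100.0

    def test_zero_lfc_excluded_from_denominator(self):
        mrna = pd.Series({"m1": 0.0, "m2": 1.0})
        asrna = pd.Series({"a1": 1.0, "a2": 1.0})
        s = expr.direction_agreement(self._pairs(), mrna, asrna)
        assert s.n_pairs == 1 and s.pct_same == 100.0

    def test_uncorrelated_pairs_filtered_out(self):
        pairs = [expr.PairRecord("m1", "a1", 10, pcc=0.2)]
        with pytest.raises(ValueError, match="no pairs"):
            expr.direction_agreement(
                pairs, pd.Series({"m1": 1.0}), pd.Series({"a1": 1.0})
            )

    def test_percentages_always_sum_to_100(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 20))
            pairs = [
                expr.PairRecord(f"m{i}", f"a{i}", 1, pcc=0.9) for i in range(n)
            ]
            mrna = pd.Series(rng.normal(size=n) + 0.01,
                             index=[f"m{i}" for i in range(n)])
            asrna = pd.Series(rng.normal(size=n) + 0.01,
                              index=[f"a{i}" for i in range(n)])
            s = expr.direction_agreement(pairs, mrna, asrna)
            assert s.pct_same + s.pct_opposite == pytest.approx(100.0)


class TestProteinIntegration:
    def _tables(self):
        asrna = pd.DataFrame(
            {"log2fc": [2.0, 0.2], "pvalue": [0.01, 0.5]}, index=["a1", "a2"]
        )
        mrna = pd.DataFrame(
            {"log2fc": [0.1, 0.1], "pvalue": [0.8, 0.8]}, index=["m1", "m2"]
        )
        protein = pd.DataFrame(
            {"log2fc": [-1.5, 0.0], "pvalue": [0.01, 0.9]}, index=["m1", "m2"]
        )
        return asrna, protein, mrna

    def _pairs(self):
        return [
            expr.PairRecord("m1", "a1", 10),
            expr.PairRecord("m2", "a2", 10),
            expr.PairRecord("m3", "a3", 10),  # no protein data
        ]

    def test_joint_categories_and_exclusions(self):
        asrna, protein, mrna = self._tables()
        df = expr.protein_integration(self._pairs(), asrna, protein, mrna)
        assert len(df) == 2
        assert df.attrs["n_excluded_missing"] == 1
        row = df.set_index("asrna_id").loc["a1"]
        assert row["category"] == "asRNA-up/protein-down"
        row2 = df.set_index("asrna_id").loc["a2"]
        assert row2["category"] == "asRNA-unchanged/protein-unchanged"

    def test_percentages_partition_to_100(self):
        asrna, protein, mrna = self._tables()
        df = expr.protein_integration(self._pairs(), asrna, protein, mrna)
        for molecule in ("asrna", "mrna", "protein"):
            assert expr.change_percentages(df, molecule).sum() == pytest.approx(100.0)


class TestTrajectories:
    def test_toy_group_means_match_hand_arithmetic(self):
        lfc = pd.DataFrame(
            {"log2fc": [1.0, 2.0, -1.0, -3.0]}, index=["t1", "t2", "t3", "t4"]
        )
        out = expr.smap_group_trajectories(
            {"smap1": {"t1", "t2"}}, {"tp15": lfc}, {"t1", "t2", "t3", "t4"}
        )
        means = out.set_index("group")["mean_log2fc"]
        assert means["smap1-only"] == pytest.approx(1.5)
        assert means["unbound"] == pytest.approx(-2.0)

    def test_all_unbound_yields_only_unbound_row(self):
        lfc = pd.DataFrame({"log2fc": [1.0, 2.0]}, index=["t1", "t2"])
        out = expr.smap_group_trajectories({}, {"tp": lfc}, {"t1", "t2"})
        assert list(out["group"]) == ["unbound"]
        assert out["pvalue"].isna().all()

    def test_planted_shift_detected(self, rng):
        bound = {f"b{i}" for i in range(200)}
        unbound = {f"u{i}" for i in range(200)}
        lfc = pd.DataFrame(
            {
                "log2fc": np.concatenate(
                    [rng.normal(-1.0, 0.5, 200), rng.normal(0.0, 0.5, 200)]
                )
            },
            index=sorted(bound) + sorted(unbound),
        )
        out = expr.smap_group_trajectories(
            {"smap2": bound}, {"tp": lfc}, bound | unbound
        )
        p = out.set_index("group").loc["smap2-only", "pvalue"]
        assert p < 0.005
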