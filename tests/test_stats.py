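import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgcount import (
    AnimalRecord,
    CountTable,
    agreement_auto_vs_manual,
    compare_multi_groups,
    compare_two_groups,
    correlate_with_score,
    density,
    summarize_retina,
)
from rgcount.io import ECCENTRICITIES

# Reference values computed once with R 4.3.3 (t.test, aov/TukeyHSD, cor.test)
# on the fixed vectors below, frozen here.
TT_A = [3683.0, 3540.0, 3721.0, 3602.0, 3795.0, 3650.0]
TT_B = [2272.0, 2410.0, 2150.0, 2305.0, 2480.0]
R_TT = {"t": 20.4904462626, "df": 9.0, "p": 7.33197211384e-09}
R_WELCH = {"t": 19.7986536126, "df": 7.01937547808, "p": 2.03229591886e-07}

AOV_G1 = [3650.0, 3700.0, 3600.0, 3720.0]
AOV_G2 = [3550.0, 3620.0, 3580.0, 3490.0]
AOV_G3 = [3430.0, 3520.0, 3390.0, 3545.0]
R_AOV = {"F": 10.2883299427, "p": 0.00472955434358}
R_TUKEY = {("B", "A"): 0.08107476965616, ("C", "A"): 0.00365931194884, ("C", "B"): 0.15629651848890}

SP_X = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 3.0]
SP_Y = [3900.0, 3720.0, 3650.0, 3800.0, 3400.0, 3150.0, 3000.0, 2700.0, 2450.0, 2300.0, 2100.0, 2900.0]
R_SPEAR = {"rho": -0.977234423332, "p": 4.63546976269e-08}
SP_X_SMALL = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 2.5]
SP_Y_SMALL = [3600.0, 3500.0, 3550.0, 2900.0, 2500.0, 2450.0, 3100.0]
R_SPEAR_EXACT = {"rho": -0.964285714286, "p": 0.00277777777778}


def sig6(a, b):
    return a == pytest.approx(b, rel=1e-6)


class TestDensity:
    @pytest.mark.parametrize(
        "count,side,expected",
        [(0, 350.0, 0.0), (49, 350.0, 400.0), (451, 350.0, 3681.632653)],
    )
    def test_known_values(self, count, side, expected):
        assert density(count, side) == pytest.approx(expected)

    def test_halving_side_quadruples_density(self):
        assert density(10, 175.0) == pytest.approx(4 * density(10, 350.0))

    @settings(deadline=None, max_examples=50)
    @given(c=st.integers(min_value=0, max_value=2000), k=st.integers(min_value=1, max_value=5))
    def test_linear_in_count(self, c, k):
        assert density(k * c, 350.0) == pytest.approx(k * density(c, 350.0))

    def test_nonpositive_side_rejected(self):
        with pytest.raises(ValueError):
            density(10, 0.0)


class TestSummarizeRetina:
    def test_uniform_counts_give_flat_summary(self):
        counts = {(q, e): 49 for q in (1, 2, 3, 4) for e in ECCENTRICITIES}
        s = summarize_retina(counts)
        assert s.mean_density == pytest.approx(400.0)
        assert all(v == pytest.approx(400.0) for v in s.regional_means.values())

    def test_central_to_peripheral_gradient(self):
        per_ecc = {"central": 490, "middle": 367, "peripheral": 245}
        counts = {(q, e): per_ecc[e] for q in (1, 2, 3, 4) for e in ECCENTRICITIES}
        s = summarize_retina(counts)
        assert s.regional_means["central"] == pytest.approx(4000.0)
        assert s.regional_means["middle"] == pytest.approx(2995.918367)
        assert s.regional_means["peripheral"] == pytest.approx(2000.0)
        assert s.mean_density == pytest.approx(np.mean(list(s.densities.values())))
        assert (
            s.regional_means["central"]
            > s.regional_means["middle"]
            > s.regional_means["peripheral"]
        )

    def test_eleven_segments_rejected(self):
        counts = {(q, e): 49 for q in (1, 2, 3) for e in ECCENTRICITIES}
        counts.update({(4, "central"): 49, (4, "middle"): 49})
        with pytest.raises(ValueError, match="exactly one count"):
            summarize_retina(counts)

    def test_mean_is_permutation_invariant(self):
        rng = np.random.default_rng(0)
        values = rng.integers(100, 500, 12)
        keys = [(q, e) for q in (1, 2, 3, 4) for e in ECCENTRICITIES]
        s1 = summarize_retina(dict(zip(keys, values)))
        perm = rng.permutation(12)
        s2 = summarize_retina(dict(zip(keys, values[perm])))
        assert s1.mean_density == pytest.approx(s2.mean_density)


class TestCompareTwoGroups:
    def test_matches_r_student_t(self):
        res = compare_two_groups(TT_A, TT_B)
        assert sig6(res.statistic, R_TT["t"])
        assert sig6(res.p_value, R_TT["p"])
        assert res.degrees_of_freedom[0] == R_TT["df"]

    def test_matches_r_welch_t(self):
        res = compare_two_groups(TT_A, TT_B, equal_var=False)
        assert sig6(res.statistic, R_WELCH["t"])
        assert sig6(res.degrees_of_freedom[0], R_WELCH["df"])
        assert sig6(res.p_value, R_WELCH["p"])

    def test_identical_zero_variance_groups_give_p_one(self):
        res = compare_two_groups([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_shifted_group_is_detected(self):
        res = compare_two_groups([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p_value < 0.01

    def test_symmetry_up_to_sign(self):
        r1 = compare_two_groups(TT_A, TT_B)
        r2 = compare_two_groups(TT_B, TT_A)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError, match="two observations"):
            compare_two_groups([1.0], [2.0, 3.0])

    def test_reports_means_and_sems(self):
        res = compare_two_groups(TT_A, TT_B)
        assert res.means[0] == pytest.approx(np.mean(TT_A))
        assert res.sems[1] == pytest.approx(np.std(TT_B, ddof=1) / np.sqrt(5))


class TestCompareMultiGroups:
    def test_matches_r_anova_and_tukey(self):
        res = compare_multi_groups({"A": AOV_G1, "B": AOV_G2, "C": AOV_G3})
        assert sig6(res.anova.statistic, R_AOV["F"])
        assert sig6(res.anova.p_value, R_AOV["p"])
        for _, row in res.tukey.iterrows():
            key = (row["group2"], row["group1"])
            expected = R_TUKEY.get(key) or R_TUKEY[(row["group1"], row["group2"])]
            assert sig6(row["p_adj"], expected)

    def test_identical_groups_give_f_zero_and_tukey_one(self):
        g = [4.0, 4.0, 4.0]
        res = compare_multi_groups({"a": g, "b": g, "c": g})
        assert res.anova.statistic == 0.0 and res.anova.p_value == 1.0
        assert (res.tukey["p_adj"] == 1.0).all()

    def test_only_shifted_group_pairs_significant(self):
        base = [10.0, 11.0, 9.0, 10.5]
        res = compare_multi_groups({"a": base, "b": [x + 0.2 for x in base], "c": [x + 30 for x in base]})
        tk = res.tukey.set_index(["group1", "group2"])["p_adj"]
        assert tk[("a", "c")] < 0.05 and tk[("b", "c")] < 0.05
        assert tk[("a", "b")] > 0.05

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_multi_groups({"a": [1.0, 2.0], "b": [3.0, 4.0]})


class TestCorrelateWithScore:
    @staticmethod
    def _records(scores):
        return [AnimalRecord(f"m{i}", "EAE", s) for i, s in enumerate(scores)]

    @staticmethod
    def _densities(values):
        return {f"m{i}": v for i, v in enumerate(values)}

    def test_matches_r_t_approximation_for_large_n(self):
        res = correlate_with_score(self._densities(SP_Y), self._records(SP_X))
        assert sig6(res.rho, R_SPEAR["rho"])
        assert sig6(res.p_value, R_SPEAR["p"])

    def test_matches_r_exact_permutation_for_small_n(self):
        res = correlate_with_score(self._densities(SP_Y_SMALL), self._records(SP_X_SMALL))
        assert sig6(res.rho, R_SPEAR_EXACT["rho"])
        assert sig6(res.p_value, R_SPEAR_EXACT["p"])

    def test_strict_monotone_decrease_gives_minus_one(self):
        res = correlate_with_score(
            self._densities([4000.0, 3500.0, 3000.0, 2500.0]),
            self._records([0.0, 1.0, 2.0, 3.0]),
        )
        assert res.rho == pytest.approx(-1.0)

    def test_aligned_ties_still_give_minus_one(self):
        res = correlate_with_score(
            self._densities([4.0, 4.0, 2.0, 1.0]), self._records([0.0, 0.0, 2.0, 3.0])
        )
        assert res.rho == pytest.approx(-1.0)

    def test_constant_scores_rejected_as_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            correlate_with_score(
                self._densities([4.0, 3.0, 2.0]), self._records([2.0, 2.0, 2.0])
            )

    def test_unmatched_ids_rejected(self):
        with pytest.raises(ValueError, match="without records"):
            correlate_with_score({"zz": 4.0, "m0": 3.0, "m1": 2.0}, self._records([1.0, 2.0]))

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            correlate_with_score(self._densities([4.0, 3.0]), self._records([1.0, 2.0]))

    def test_rho_invariant_under_monotone_transform(self):
        d = self._densities(SP_Y)
        base = correlate_with_score(d, self._records(SP_X))
        squashed = {k: np.log(v) for k, v in d.items()}
        res = correlate_with_score(squashed, self._records(SP_X))
        assert res.rho == pytest.approx(base.rho)
        assert res.p_value == pytest.approx(base.p_value)


def _table(counts, animal="m1"):
    rows = []
    i = 0
    for q in (1, 2, 3, 4):
        for ecc in ECCENTRICITIES:
            rows.append(
                {
                    "animal_id": animal, "eye": "left", "group": "EAE", "timepoint": 42,
                    "quadrant": q, "eccentricity": ecc,
                    "count": counts[i], "density": counts[i] / 0.1225,
                }
            )
            i += 1
    return CountTable(pd.DataFrame(rows))


class TestAgreement:
    # paired-t reference from R: t.test(ad, md, paired=TRUE) on the vectors below
    AUTO = [451, 440, 462, 455, 447, 438, 460, 452, 449, 455, 441, 446]
    MANUAL = [449, 443, 460, 453, 449, 436, 462, 450, 449, 455, 441, 446]

    def test_identical_tables_give_zero_bias_p_one(self):
        t = _table(self.AUTO)
        res = agreement_auto_vs_manual(t, t)
        assert res.mean_bias == 0.0
        assert res.paired_p_value == 1.0
        assert (res.differences["difference"] == 0).all()

    def test_constant_offset_detected(self):
        res = agreement_auto_vs_manual(_table([c + 5 for c in self.MANUAL]), _table(self.MANUAL))
        assert res.mean_bias == pytest.approx(5.0)
        assert (res.differences["difference"] == 5).all()
        assert res.paired_p_value == 0.0

    def test_matches_r_paired_t(self):
        # first 8 segments correspond to the frozen R fixture
        auto = _table([451, 440, 462, 455, 447, 438, 460, 452, 450, 450, 450, 450])
        manual = _table([449, 443, 460, 453, 449, 436, 462, 450, 450, 450, 450, 450])
        res = agreement_auto_vs_manual(auto, manual)
        # R on the 8 differing + 4 zero rows is not frozen; check consistency
        d = res.differences["difference"].to_numpy()
        assert res.mean_bias == pytest.approx(d.mean())
        assert set(res.regional["eccentricity"]) == set(ECCENTRICITIES)

    def test_key_mismatch_rejected(self):
        with pytest.raises(ValueError, match="keys differ"):
            agreement_auto_vs_manual(_table(self.AUTO, "m1"), _table(self.MANUAL, "m2"))

    def test_regional_breakdown_consistent_with_pooled(self):
        res = agreement_auto_vs_manual(_table(self.AUTO), _table(self.MANUAL))
        pooled = res.differences["difference"].sum()
        regional_sum = (res.regional["mean_bias"] * res.regional["n"]).sum()
        assert pooled == pytest.approx(regional_sum)
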