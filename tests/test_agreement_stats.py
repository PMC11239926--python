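import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneumorph import (
    GroundTruth,
    RaterProfile,
    bland_altman,
    cohens_d,
    icc,
    interpret_icc,
    pairwise_agreement_report,
    simulate_rater_measurements,
)
from aneumorph.agreement_stats import report_to_frame
from aneumorph.errors import DegenerateStatisticError, ValidationError

from conftest import rng_for

# 6 targets x 4 raters fixture; reference single-rater ICCs computed with an
# independent two-way-ANOVA implementation (pingouin ICC(A,1) / ICC(C,1))
# before these tests were written.
ICC_FIXTURE = np.array(
    [
        [5.40, 2.74, 6.77, 7.06],
        [0.88, 2.22, 5.52, 4.55],
        [4.75, 3.12, 7.02, 6.74],
        [4.92, 7.08, 6.20, 3.46],
        [5.52, 2.91, 7.02, 5.08],
        [4.42, 3.46, 7.71, 4.87],
    ]
)
ICC_FIXTURE_ABSOLUTE = 0.062696
ICC_FIXTURE_CONSISTENCY = 0.106795


class TestBlandAltman:
    def test_identity_and_shift(self):
        first = np.array([3.0, 4.0, 5.0])
        res = bland_altman(first, first)
        assert (res.mean_diff_mm, res.sd_diff_mm, res.loa_low, res.loa_high) == (0, 0, 0, 0)
        res = bland_altman(first, first + 1)
        assert res.mean_diff_mm == 1.0 and res.sd_diff_mm == 0.0

    def test_hand_computed_example(self):
        res = bland_altman([3, 4, 5], [4, 4, 7])
        assert res.mean_diff_mm == pytest.approx(1.0)
        assert res.sd_diff_mm == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(-0.96)
        assert res.loa_high == pytest.approx(2.96)

    def test_swap_antisymmetry(self):
        rng = rng_for("ba_swap")
        a, b = rng.normal(5, 2, 40), rng.normal(5, 2, 40)
        ab, ba = bland_altman(a, b), bland_altman(b, a)
        assert ab.mean_diff_mm == pytest.approx(-ba.mean_diff_mm)
        assert ab.sd_diff_mm == pytest.approx(ba.sd_diff_mm)

    def test_input_contracts(self):
        with pytest.raises(ValidationError, match="unpaired"):
            bland_altman([1, 2], [1, 2, 3])
        with pytest.raises(ValidationError, match=">= 2"):
            bland_altman([1], [2])


class TestICC:
    def test_perfect_agreement(self):
        x = np.tile([[3.0], [5.0], [9.0]], (1, 4))
        for variant in ("two_way_random_absolute_single", "two_way_mixed_consistency_single"):
            res = icc(x, variant)
            assert res.icc_value == pytest.approx(1.0)
            assert res.label == "excellent"

    def test_zero_variance_undefined(self):
        with pytest.raises(DegenerateStatisticError):
            icc(np.full((4, 3), 2.5))

    def test_fixture_matches_independent_reference(self):
        res_a = icc(ICC_FIXTURE, "two_way_random_absolute_single")
        res_c = icc(ICC_FIXTURE, "two_way_mixed_consistency_single")
        assert res_a.icc_value == pytest.approx(ICC_FIXTURE_ABSOLUTE, abs=1e-6)
        assert res_c.icc_value == pytest.approx(ICC_FIXTURE_CONSISTENCY, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pingouin_on_random_matrices(self, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        x = rng.normal(5, 2, size=(8, 4)) + rng.normal(0, 1, size=(1, 4))
        n, k = x.shape
        long = pd.DataFrame(
            {
                "t": np.repeat(np.arange(n), k),
                "r": np.tile(np.arange(k), n),
                "y": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="t", raters="r", ratings="y").set_index("Type").ICC
        # pingouin labels the two-way single-rater forms ICC(A,1) / ICC(C,1)
        assert icc(x, "two_way_random_absolute_single").icc_value == pytest.approx(
            ref["ICC(A,1)"], abs=1e-9
        )
        assert icc(x, "two_way_mixed_consistency_single").icc_value == pytest.approx(
            ref["ICC(C,1)"], abs=1e-9
        )

    def test_shift_invariances(self):
        """Adding a constant to all cells changes nothing; a per-rater shift
        leaves the consistency form alone but lowers absolute agreement."""
        base_a = icc(ICC_FIXTURE, "two_way_random_absolute_single").icc_value
        base_c = icc(ICC_FIXTURE, "two_way_mixed_consistency_single").icc_value
        shifted = ICC_FIXTURE + 3.7
        assert icc(shifted, "two_way_random_absolute_single").icc_value == pytest.approx(base_a)
        assert icc(shifted, "two_way_mixed_consistency_single").icc_value == pytest.approx(base_c)
        per_rater = ICC_FIXTURE + np.array([[0.0, 2.0, -1.0, 4.0]])
        assert icc(per_rater, "two_way_mixed_consistency_single").icc_value == pytest.approx(base_c)
        assert icc(per_rater, "two_way_random_absolute_single").icc_value < base_a

    def test_parameter_recovery_two_way_model(self):
        """Absolute-agreement ICC estimates sigma_t^2/(sigma_t^2 + sigma_r^2
        + sigma_e^2) of the generating two-way model y_ij = t_i + r_j + e_ij."""
        rng = rng_for("icc_recovery")
        st2, sr2, se2 = 4.0, 0.25, 1.0
        n, k = 1000, 5
        x = (
            rng.normal(0, np.sqrt(st2), (n, 1))
            + rng.normal(0, np.sqrt(sr2), (1, k))
            + rng.normal(0, np.sqrt(se2), (n, k))
        )
        est = icc(x, "two_way_random_absolute_single").icc_value
        assert est == pytest.approx(st2 / (st2 + sr2 + se2), abs=0.05)

    def test_input_contracts(self):
        with pytest.raises(ValidationError, match="missing"):
            icc(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ValidationError, match=">= 2"):
            icc(np.array([[1.0, 2.0]]))


class TestInterpretIcc:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.95, "excellent"),
            (0.80, "good"),
            (0.90, "good"),
            (0.75, "good"),
            (0.60, "moderate"),
            (0.50, "moderate"),
            (0.30, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_bins(self, value, label):
        assert interpret_icc(value) == label


class TestCohensD:
    def test_self_comparison_zero(self):
        a = np.array([2.0, 4.0, 5.0])
        assert cohens_d(a, a).d == 0.0
        assert cohens_d([2.0, 4.0], [2.0, 4.0]).d == 0.0

    def test_direct_formula_example(self):
        res = cohens_d([0.0, 2.0], [1.0, 3.0])
        assert abs(res.d) == pytest.approx(0.7071, abs=1e-4)
        assert res.pooled_sd == pytest.approx(np.sqrt(2))

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, c):
        a = np.array([1.0, 2.0, 4.0, 5.5])
        b = np.array([2.0, 3.0, 3.5, 7.0])
        assert cohens_d(a * c, b * c).d == pytest.approx(cohens_d(a, b).d, rel=1e-9)

    def test_constant_groups(self):
        assert cohens_d([2.0, 2.0], [2.0, 2.0]).d == 0.0
        with pytest.raises(DegenerateStatisticError):
            cohens_d([2.0, 2.0], [3.0, 3.0])


class TestPairwiseReport:
    def _table(self, profiles, n=500, sessions=1, seed=0, ruptured_every=2):
        rng = np.random.default_rng(seed)
        plane = (np.zeros(3), np.array([0.0, 0.0, 1.0]))
        truths = [
            GroundTruth(
                f"c{i:04d}",
                np.zeros(3),
                float(s),
                plane,
                "ruptured" if i % ruptured_every == 0 else "unruptured",
            )
            for i, s in enumerate(rng.uniform(8, 15, n))
        ]
        return simulate_rater_measurements(truths, profiles, sessions_per_rater=sessions, seed=seed)

    def test_noiseless_intra_rater(self):
        table = self._table([RaterProfile("r", 0.0, 1e-9)], n=30, sessions=2)
        results, _ = pairwise_agreement_report(table, mode="intra")
        block = next(r for r in results if r.stratum == "all")
        assert block.bland_altman.mean_diff_mm == pytest.approx(0.0, abs=1e-6)
        assert block.bland_altman.sd_diff_mm == pytest.approx(0.0, abs=1e-6)
        assert block.icc.icc_value == pytest.approx(1.0, abs=1e-9)

    def test_bias_recovered_between_raters(self):
        """Junior (bias 0.6, sd 2.0) vs senior (bias 0, sd 1.2): the reported
        mean difference recovers the injected bias within 3 SE at n=500."""
        table = self._table(
            [RaterProfile("junior", 0.6, 2.0), RaterProfile("senior", 0.0, 1.2)],
            n=500,
            seed=17,
            ruptured_every=10**9,  # unruptured only: multipliers stay inactive
        )
        results, _ = pairwise_agreement_report(table, mode="inter", strata=None)
        block = next(r for r in results if r.stratum == "all")
        # pairs are sorted lexicographically: first=junior, second=senior
        se = np.sqrt(2.0**2 + 1.2**2) / np.sqrt(500)
        assert abs(block.bland_altman.mean_diff_mm - (0.0 - 0.6)) < 3 * se

    def test_ruptured_stratum_has_larger_sd(self):
        profiles = [
            RaterProfile("a", 0.0, 1.0, ruptured_sd_multiplier=2.0),
            RaterProfile("b", 0.0, 1.0, ruptured_sd_multiplier=2.0),
        ]
        table = self._table(profiles, n=500, seed=3)
        results, _ = pairwise_agreement_report(table, mode="inter")
        by_stratum = {r.stratum: r for r in results}
        assert by_stratum["ruptured"].bland_altman.sd_diff_mm > by_stratum["unruptured"].bland_altman.sd_diff_mm

    def test_cohens_d_matrix_shape_and_symmetry(self):
        profiles = [RaterProfile(r, 0.0, 1.0) for r in ("a", "b", "c")]
        table = self._table(profiles, n=50)
        _, d = pairwise_agreement_report(table, mode="inter")
        assert list(d.index) == ["a", "b", "c"]
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        assert (d.to_numpy() >= 0).all()

    def test_vs_reference_mode_and_report_frame(self):
        profiles = [RaterProfile("computerized", 0.0, 0.1), RaterProfile("senior", -0.5, 1.0)]
        table = self._table(profiles, n=60)
        results, _ = pairwise_agreement_report(
            table, mode="vs_reference", reference="computerized"
        )
        assert all(r.first == "computerized" for r in results)
        frame = report_to_frame(results)
        assert {"mean_diff_mm", "icc", "cohens_d", "stratum"} <= set(frame.columns)
        with pytest.raises(ValidationError):
            pairwise_agreement_report(table, mode="vs_reference", reference="nobody")
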