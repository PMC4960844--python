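import numpy as np
import pytest
from scipy import stats
from scipy.stats import chi2_contingency

from agreemi import (
    DegenerateInputError,
    SectionMap,
    build_table,
    default_section_map,
    g_statistic,
    local_mi_matrix,
    marginal_entropies,
    mi_p_value,
    mi_significance_threshold,
    mutual_information,
    sectioned_information,
)
from agreemi.information import _local_mi_from_joint

from .conftest import binary_table, random_count_table


class TestLocalMI:
    def test_pilot_table_agreement_and_disagreement_sums(self, cam_famcam):
        local = local_mi_matrix(cam_famcam).contributions
        assert local[0, 0] + local[1, 1] == pytest.approx(0.629, abs=5e-4)
        assert local[0, 1] + local[1, 0] == pytest.approx(-0.137, abs=5e-4)

    def test_exact_independence_gives_all_zero_cells(self, independence_table):
        np.testing.assert_allclose(
            local_mi_matrix(independence_table).contributions, 0, atol=1e-15
        )

    def test_perfect_agreement_uniform_marginals(self):
        local = local_mi_matrix(binary_table([[10, 0], [0, 10]])).contributions
        np.testing.assert_allclose(local, [[0.5, 0.0], [0.0, 0.5]])

    def test_zero_cell_contributes_exactly_zero(self):
        local = local_mi_matrix(binary_table([[5, 0], [2, 7]])).contributions
        assert local[0, 1] == 0.0

    def test_degenerate_probability_input_is_flagged_not_propagated(self):
        # a positive cell over a zero marginal (p*log2(p/0) = inf) is only
        # reachable from externally supplied, inconsistent marginals; it must
        # raise, not silently return +inf
        joint = np.array([[0.5, 0.25], [0.25, 0.0]])
        assert np.isfinite(_local_mi_from_joint(joint)).all()
        with pytest.raises(DegenerateInputError):
            _local_mi_from_joint(joint, row_marginals=[0.75, 0.0],
                                 col_marginals=[0.75, 0.25])


class TestMutualInformation:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[10, 5], [5, 20]], 0.159),
            ([[20, 1], [1, 19]], 0.718),
            ([[8, 1], [1, 31]], 0.492),
        ],
    )
    def test_published_tables_reproduce(self, counts, expected):
        assert mutual_information(binary_table(counts)) == pytest.approx(
            expected, abs=5e-4
        )

    def test_scenario3_full_precision_value(self, scenario3):
        # printed as 0.015 via rounded components 0.098 - 0.083; the exact
        # sum is 0.0157, consistent with the printed G statistic 0.871
        assert mutual_information(scenario3) == pytest.approx(0.01571, abs=5e-5)

    @pytest.mark.parametrize("c", [1, 3, 250.5])
    def test_uniform_perfect_dependence_is_one_bit(self, c):
        assert mutual_information(binary_table([[c, 0], [0, c]])) == pytest.approx(1.0)

    def test_entropy_identity_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            t = random_count_table(rng)
            h_row, h_col, h_joint = marginal_entropies(t)
            assert mutual_information(t) == pytest.approx(
                h_row + h_col - h_joint, abs=1e-10
            )

    def test_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            t = random_count_table(rng)
            h_row, h_col, _ = marginal_entropies(t)
            assert mutual_information(t) <= min(h_row, h_col) + 1e-12

    def test_scale_invariance(self, scenario1):
        scaled = build_table(scenario1.counts * 7.5)
        assert mutual_information(scaled) == pytest.approx(
            mutual_information(scenario1), abs=1e-12
        )


class TestSectionedInformation:
    def test_pilot_table_split(self, cam_famcam):
        i_agr, i_dis = sectioned_information(
            cam_famcam, default_section_map(cam_famcam)
        )
        assert i_agr == pytest.approx(0.629, abs=5e-4)
        assert i_dis == pytest.approx(-0.137, abs=5e-4)

    def test_disagreement_scenario_split(self, scenario2):
        i_agr, i_dis = sectioned_information(scenario2, default_section_map(scenario2))
        assert i_agr == pytest.approx(-0.227, abs=5e-4)
        assert i_dis == pytest.approx(0.386, abs=5e-4)

    def test_half_weights_split_mi_evenly(self, cam_famcam):
        half = SectionMap(np.full((2, 2), 0.5))
        i_agr, i_dis = sectioned_information(cam_famcam, half)
        mi = mutual_information(cam_famcam)
        assert i_agr == pytest.approx(mi / 2, abs=1e-12)
        assert i_dis == pytest.approx(mi / 2, abs=1e-12)

    def test_components_sum_to_mi_for_arbitrary_weights(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            t = random_count_table(rng)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = SectionMap(rng.uniform(size=t.shape))
            i_agr, i_dis = sectioned_information(t, w)
            assert i_agr + i_dis == pytest.approx(
                local_mi_matrix(t).contributions.sum(), abs=1e-12
            )

    def test_transpose_preserves_components(self, cam_famcam):
        sec = default_section_map(cam_famcam)
        a, d = sectioned_information(cam_famcam, sec)
        at, dt = sectioned_information(cam_famcam.transpose(), sec.transpose())
        assert (at, dt) == pytest.approx((a, d), abs=1e-12)


class TestSignificance:
    @pytest.mark.parametrize(
        "counts, stat", [([[10, 5], [5, 20]], 8.809), ([[5, 10], [5, 20]], 0.871)]
    )
    def test_worked_g_statistics(self, counts, stat):
        assert g_statistic(binary_table(counts)).statistic == pytest.approx(
            stat, abs=5e-3
        )

    def test_pilot_table_chi_square_and_p(self, cam_famcam):
        res = mi_p_value(cam_famcam)
        assert res.statistic == pytest.approx(27.977, abs=5e-3)
        assert res.dof == 1
        assert res.p_value < 0.001

    def test_weak_table_p_value(self, scenario3):
        assert mi_p_value(scenario3).p_value == pytest.approx(0.35, abs=0.005)

    def test_independence_table_statistic_zero_p_one(self, independence_table):
        res = mi_p_value(independence_table)
        assert res.statistic == 0
        assert res.p_value == 1

    def test_matches_likelihood_ratio_oracle(self):
        # independent route: G = 2 sum O ln(O/E), scipy's log-likelihood test
        rng = np.random.default_rng(14)
        for _ in range(40):
            t = random_count_table(rng)
            ours = mi_p_value(t)
            g, p, dof, _ = chi2_contingency(
                t.counts, correction=False, lambda_="log-likelihood"
            )
            assert ours.statistic == pytest.approx(g, abs=1e-10)
            assert ours.dof == dof
            assert ours.p_value == pytest.approx(p, abs=1e-12)

    def test_g_scales_linearly_with_counts(self, scenario1):
        g1 = g_statistic(scenario1).statistic
        g3 = g_statistic(build_table(scenario1.counts * 3)).statistic
        assert g3 == pytest.approx(3 * g1, rel=1e-12)

    def test_zero_marginal_column_dropped_from_dof_with_warning(self):
        t = build_table([[3, 0, 4], [5, 0, 6]])
        with pytest.warns(UserWarning, match="zero-marginal"):
            assert mi_p_value(t).dof == 1


class TestSignificanceThreshold:
    def test_published_limit_at_n_1000(self):
        assert mi_significance_threshold(1000, 1, 0.05) == pytest.approx(
            0.00277, abs=5e-6
        )

    def test_threshold_inverts_the_g_conversion(self):
        for n in (40, 200, 1000):
            thr = mi_significance_threshold(n, 1, 0.05)
            assert 2 * n * np.log(2) * thr == pytest.approx(
                stats.chi2.ppf(0.95, 1), abs=1e-9
            )

    def test_strictly_decreasing_in_n(self):
        vals = [mi_significance_threshold(n) for n in (10, 50, 250, 1250)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
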