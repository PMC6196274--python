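"""Tests for directional tests, Brown pooling, distances, Sammon, fold changes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glionet import (
    CorrelationModel,
    ExpressionMatrix,
    ValidationError,
    brown_covariance,
    combine_pvalues_brown,
    directional_pvalue,
    estimate_correlation,
    fold_change_profile,
    profile_distance_matrix,
    read_expression,
    sammon_embed,
    signed_fold_change,
    state_alignment_pvalue,
    state_state_pvalue,
    write_expression,
)
from glionet.synth import SynthDesign, EffectSpec, generate_expression


@pytest.fixture(scope="module")
def concordant_data(net, ss1_state):
    design = SynthDesign(
        groups=("saline", "DFP"),
        effects=(("DFP", EffectSpec.toward(ss1_state.as_dict(net), 2.0, 1.0)),),
        seed=2024,
    )
    data, _ = generate_expression(design)
    return data


@pytest.fixture(scope="module")
def rho12(concordant_data, marker_map):
    return estimate_correlation(concordant_data, genes=marker_map.genes)


class TestDirectionalPvalue:
    treated_up = [10.0, 11.0, 12.0, 10.5, 11.5, 12.5]
    control = [1.0, 1.2, 0.8, 1.1, 0.9, 1.0]

    def test_agreement_with_predicted_rise_is_significant(self):
        assert directional_pvalue(self.treated_up, self.control, 1) < 1e-4

    def test_contradiction_of_predicted_fall_is_nonsignificant(self):
        assert directional_pvalue(self.treated_up, self.control, -1) > 0.999

    def test_predicted_no_change_uses_complement_of_two_tailed(self):
        p = directional_pvalue(self.control, [1.0, 1.05, 0.95, 1.0, 1.0, 1.0], 0)
        p2 = stats.ttest_ind(
            self.control, [1.0, 1.05, 0.95, 1.0, 1.0, 1.0], equal_var=True
        ).pvalue
        assert p == pytest.approx(1.0 - p2, abs=1e-12)

    def test_degenerate_cases_follow_the_mean_comparison(self):
        same = [2.0, 2.0, 2.0]
        higher = [3.0, 3.0, 3.0]
        assert directional_pvalue(same, same, 0) <= 1e-14  # 1 - p_two(=1), clipped
        assert directional_pvalue(higher, same, 1) <= 1e-14
        assert directional_pvalue(higher, same, -1) >= 1 - 1e-14

    def test_result_is_clipped_into_open_interval(self):
        p = directional_pvalue(self.treated_up, self.control, -1)
        assert 0.0 < p < 1.0

    def test_rejects_non_ternary_prediction(self):
        with pytest.raises(ValidationError):
            directional_pvalue(self.treated_up, self.control, 2)


class TestBrown:
    @pytest.mark.parametrize(
        "rho,expected",
        [(0.0, 0.0), (1.0, 4.00), (-0.5, -1.4575), (0.5, 0.5 * (3.25 + 0.375))],
    )
    def test_covariance_polynomial(self, rho, expected):
        assert brown_covariance(rho) == pytest.approx(expected, abs=1e-12)

    def test_covariance_domain(self):
        with pytest.raises(ValidationError):
            brown_covariance(1.5)
        with pytest.raises(ValidationError):
            brown_covariance(float("nan"))
        with pytest.warns(UserWarning, match="clamped"):
            assert brown_covariance(-0.9) == pytest.approx(brown_covariance(-0.5))

    def test_reduces_to_fisher_for_independent_tests(self):
        p = [0.01, 0.2, 0.6, 0.33]
        res = combine_pvalues_brown(p, np.eye(4))
        fisher = stats.combine_pvalues(p, method="fisher").pvalue
        assert res.c == pytest.approx(1.0, abs=1e-12)
        assert res.df == pytest.approx(8.0, abs=1e-12)
        assert res.p_combined == pytest.approx(fisher, abs=1e-12)

    def test_single_test_returns_its_own_pvalue(self):
        for p in (0.001, 0.05, 0.5, 0.97):
            res = combine_pvalues_brown([p], np.eye(1))
            assert res.p_combined == pytest.approx(p, abs=1e-12)

    def test_agrees_with_straight_line_oracle(self):
        """Independent step-by-step evaluation on 100 random (p, rho) draws."""
        rng = np.random.default_rng(11)
        chi2 = stats.chi2
        for _ in range(100):
            n = int(rng.integers(2, 13))
            p = rng.uniform(0.001, 0.999, size=n)
            a = rng.uniform(-0.4, 0.95, size=(n, n))
            rho = (a + a.T) / 2
            np.fill_diagonal(rho, 1.0)
            # oracle: literal transcription of the pooling recipe
            t0 = 0.0
            for pi in p:
                t0 += -2.0 * np.log(pi)
            var = 4.0 * n
            for i in range(n - 1):
                for j in range(i + 1, n):
                    r = rho[i, j]
                    var += 2.0 * (
                        r * (3.25 + 0.75 * r) if r >= 0 else r * (3.27 + 0.71 * r)
                    )
            c = var / (4.0 * n)
            expected = chi2.sf(t0 / c, 2.0 * n / c)
            res = combine_pvalues_brown(p, rho)
            assert res.p_combined == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            combine_pvalues_brown([0.1, 0.2], np.eye(3))


class TestStateAlignment:
    def test_invariant_to_sample_and_gene_order(
        self, concordant_data, marker_map, rho12, net, ss1_state
    ):
        base = state_alignment_pvalue(
            concordant_data, "DFP", ss1_state, marker_map, rho12, network=net
        )
        rng = np.random.default_rng(0)
        cols = list(concordant_data.values.columns)
        rng.shuffle(cols)
        rows = list(concordant_data.values.index)
        rng.shuffle(rows)
        shuffled = ExpressionMatrix(
            concordant_data.values.loc[rows, cols],
            concordant_data.groups,
            concordant_data.control_group,
        )
        again = state_alignment_pvalue(
            shuffled, "DFP", ss1_state, marker_map, rho12, network=net
        )
        assert again.p_combined == pytest.approx(base.p_combined, rel=1e-12)

    def test_missing_gene_is_named(self, concordant_data, marker_map, rho12, net, ss1_state):
        trimmed = ExpressionMatrix(
            concordant_data.values.drop(index="GFAP"),
            concordant_data.groups,
            concordant_data.control_group,
        )
        with pytest.raises(ValidationError, match="GFAP"):
            state_alignment_pvalue(
                trimmed, "DFP", ss1_state, marker_map, rho12, network=net
            )


class TestStateState:
    def test_identical_states_pool_agreement_floor(self, marker_map, rho12, net, ss1_state):
        res = state_state_pvalue(ss1_state, ss1_state, marker_map, rho12, network=net)
        assert all(p == pytest.approx(0.05) for p in res.p_values)
        assert res.p_combined < 0.05

    def test_opposed_states_disagree_on_predicted_changes(
        self, marker_map, rho12, net, ss0_state, ss1_state
    ):
        res = state_state_pvalue(ss0_state, ss1_state, marker_map, rho12, network=net)
        ss1 = ss1_state.as_dict(net)
        expected_disagreements = sum(
            1 for e in marker_map.entities for _ in marker_map.genes_for(e) if ss1[e] != 0
        )
        near_one = sum(1 for p in res.p_values if p > 0.9)
        assert near_one == expected_disagreements == 10
        assert res.p_combined > 0.5

    def test_unmapped_entities_contribute_nothing(self, marker_map, rho12, net, ss0_state):
        variant = dict(ss0_state.as_dict(net))
        variant["Neurons"] = -1  # Neurons carry no marker gene
        baseline = ss0_state.as_dict(net)
        a = state_state_pvalue(baseline, baseline, marker_map, rho12)
        b = state_state_pvalue(baseline, variant, marker_map, rho12)
        assert a.p_combined == pytest.approx(b.p_combined, rel=1e-12)


class TestDistanceMatrix:
    def test_two_states_compose_state_state(self, marker_map, rho12, net, ss0_state, ss1_state):
        d = profile_distance_matrix(
            [("SS0", ss0_state), ("SS1", ss1_state)], marker_map, rho12, network=net
        )
        direct = state_state_pvalue(ss0_state, ss1_state, marker_map, rho12, network=net)
        assert d.loc["SS0", "SS1"] == pytest.approx(direct.p_combined)

    def test_symmetry_and_zero_diagonal(
        self, concordant_data, marker_map, rho12, net, ss0_state, ss1_state
    ):
        d = profile_distance_matrix(
            [("SS0", ss0_state), ("SS1", ss1_state), "DFP"],
            marker_map,
            rho12,
            data=concordant_data,
            network=net,
        )
        m = d.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)

    def test_identical_groups_sit_close(self, marker_map, net, ss0_state):
        """The group-group distance extends the predicted-0 convention."""
        design = SynthDesign(groups=("saline", "A", "B"), effects=(), seed=5)
        data, _ = generate_expression(design)
        rho = estimate_correlation(data, genes=marker_map.genes)
        d = profile_distance_matrix(
            ["A", "B", ("SS0", ss0_state)], marker_map, rho, data=data, network=net
        )
        assert 0.0 <= d.loc["A", "B"] <= 1.0


class TestSammon:
    def test_two_profiles_embed_exactly(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        res = sammon_embed(d, seed=1)
        emb = np.linalg.norm(res.coordinates[0] - res.coordinates[1])
        assert emb == pytest.approx(0.7, rel=1e-6)
        assert res.stress < 1e-10

    def test_three_equidistant_profiles_form_a_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = sammon_embed(d, seed=0)
        assert res.stress < 1e-6
        y = res.coordinates
        sides = [np.linalg.norm(y[i] - y[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        assert np.allclose(sides, 1.0, atol=1e-3)

    def test_nonplanar_distances_leave_residual_stress(self):
        # regular tetrahedron: realizable only in 3-D
        d = np.ones((4, 4)) - np.eye(4)
        res = sammon_embed(d, seed=2)
        assert res.stress > 1e-4

    def test_stress_is_invariant_to_rigid_motion_of_the_output(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = sammon_embed(d, seed=4)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = res.coordinates @ rot.T + np.array([3.0, -2.0])

        def stress(coords):
            emb = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
            iu = np.triu_indices(len(coords), 1)
            return ((d[iu] - emb[iu]) ** 2 / d[iu]).sum() / d[iu].sum()

        assert stress(moved) == pytest.approx(res.stress, rel=1e-9)

    def test_duplicate_profiles_are_jittered_with_warning(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.warns(UserWarning, match="jitter"):
            res = sammon_embed(d, seed=0)
        assert np.isfinite(res.stress)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValidationError):
            sammon_embed(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestFoldChange:
    @pytest.mark.parametrize(
        "treated,control,expected",
        [([2.0, 2.0], [1.0, 1.0], 2.0), ([0.5, 0.5], [1.0, 1.0], -2.0), ([1.0], [1.0], 1.0)],
    )
    def test_signed_convention(self, treated, control, expected):
        assert signed_fold_change(treated, control) == pytest.approx(expected)

    def test_magnitude_never_below_one(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            t = rng.uniform(0.1, 10, size=4)
            c = rng.uniform(0.1, 10, size=4)
            assert abs(signed_fold_change(t, c)) >= 1.0

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValidationError):
            signed_fold_change([1.0, 2.0], [0.0, 0.0])

    def test_profile_signs_track_the_induced_shifts(self, concordant_data, marker_map):
        profile = fold_change_profile(concordant_data, "DFP", marker_map.genes)
        assert profile["IL1B"] > 1.0
        assert profile["IL4"] < 0.0


class TestExpressionIO:
    def test_round_trip(self, concordant_data, tmp_path):
        expr, groups = tmp_path / "expr.csv", tmp_path / "groups.csv"
        write_expression(concordant_data, expr, groups)
        back = read_expression(expr, groups)
        assert np.allclose(back.values.values, concordant_data.values.values, atol=1e-9)
        assert list(back.groups) == list(concordant_data.groups)

    def test_missing_group_label_is_an_error(self, tmp_path):
        (tmp_path / "expr.csv").write_text("gene,s1,s2,s3,s4\nG1,1,2,3,4\nG2,1,2,3,4\n")
        (tmp_path / "groups.csv").write_text("sample,group\ns1,a\ns2,a\ns3,b\ns4,\n")
        with pytest.raises(ValidationError, match="without a group"):
            read_expression(tmp_path / "expr.csv", tmp_path / "groups.csv", "a")

    def test_group_size_floor_enforced(self):
        values = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["G1"])
        groups = pd.Series({"s1": "a", "s2": "b"})
        with pytest.raises(ValidationError, match=">= 2"):
            ExpressionMatrix(values, groups, control_group="a")
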