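"""Statistical machinery: FD, residualisation, permutations, FDR, Eq-style
distance-strength model, rank tests, display transforms."""

import numpy as np
import pandas as pd
import pytest

import modbrain as mb
from modbrain.metrics import md_referenced
from modbrain.stats import MotionTrace


def trace_from_deltas(d_trans, d_rot):
    """Build a 2-volume trace with the given parameter deltas."""
    return MotionTrace(
        translations=np.vstack([np.zeros(3), np.asarray(d_trans, dtype=float)]),
        rotations=np.vstack([np.zeros(3), np.asarray(d_rot, dtype=float)]),
    )


class TestFramewiseDisplacement:
    def test_constant_parameters_zero_fd(self):
        trace = MotionTrace(np.ones((10, 3)) * 0.4, np.ones((10, 3)) * 0.01)
        res = mb.framewise_displacement(trace)
        assert not res.fd.any()
        assert res.mean_fd == 0.0
        assert not res.exclude

    def test_translation_sum(self):
        res = mb.framewise_displacement(trace_from_deltas([0.1, 0.2, 0.3], [0, 0, 0]))
        assert res.fd[0] == pytest.approx(0.6)

    def test_rotation_arc_length_on_65mm_sphere(self):
        res = mb.framewise_displacement(trace_from_deltas([0, 0, 0], [0.01, 0, 0]))
        assert res.fd[0] == pytest.approx(0.65)

    def test_exclusion_flag_above_half_mm(self):
        assert mb.framewise_displacement(trace_from_deltas([0.6, 0, 0], [0, 0, 0])).exclude
        assert not mb.framewise_displacement(trace_from_deltas([0.5, 0, 0], [0, 0, 0])).exclude

    def test_linearity_in_deltas(self):
        rng = np.random.default_rng(0)
        params = rng.normal(0, 0.1, (20, 6))
        t1 = MotionTrace(params[:, :3], params[:, 3:])
        t2 = MotionTrace(2 * params[:, :3], 2 * params[:, 3:])
        assert np.allclose(
            mb.framewise_displacement(t2).fd, 2 * mb.framewise_displacement(t1).fd
        )

    def test_single_volume_raises(self):
        with pytest.raises(ValueError):
            mb.framewise_displacement(MotionTrace(np.zeros((1, 3)), np.zeros((1, 3))))


class TestResidualize:
    def test_zero_variance_covariates_demean_only(self):
        rng = np.random.default_rng(1)
        v = rng.normal(2.0, 1.0, 30)
        cov = pd.DataFrame({"age": np.full(30, 50.0), "sex": ["M"] * 30})
        resid = mb.residualize(v, cov)
        assert np.allclose(resid, v - v.mean())

    def test_exact_linear_function_gives_zero_residuals(self):
        rng = np.random.default_rng(2)
        age = rng.uniform(20, 80, 40)
        sex = rng.integers(0, 2, 40).astype(float)
        v = 0.3 * age - 0.7 * sex + 5.0
        resid = mb.residualize(v, pd.DataFrame({"age": age, "sex": sex}))
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(3)
        age = rng.uniform(20, 80, 25)
        cov = pd.DataFrame({"age": age, "age2": 2 * age})
        with pytest.raises(ValueError, match="age"):
            mb.residualize(rng.normal(size=25), cov)

    def test_within_group_demeaning_preserves_group_effect(self):
        # ages differ by group and the signal is a pure group shift:
        # global age regression would absorb it, within-group demeaning must not
        rng = np.random.default_rng(4)
        n = 40
        group = np.repeat(["YA", "OA"], n // 2)
        age = np.where(group == "YA", rng.uniform(20, 40, n), rng.uniform(60, 80, n))
        v = np.where(group == "OA", 1.0, 0.0) + rng.normal(0, 0.05, n)
        cov = pd.DataFrame({"group": group, "age": age})
        resid = mb.residualize(v, cov, demean_age_within_group=True)
        diff = resid[group == "OA"].mean() - resid[group == "YA"].mean()
        assert diff == pytest.approx(1.0, abs=0.1)


class TestPermutationTest:
    def test_degenerate_values_p_one(self):
        a = np.ones((4, 3))
        b = np.ones((5, 3))
        res = mb.permutation_test(a, b, n_perm=200, seed=0)
        assert np.allclose(res.p, 1.0)
        assert not res.z.any()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, (15, 20))
        b = rng.normal(3.0, 1, (15, 20))  # 3-SD shift at every node
        res = mb.permutation_test(a, b, n_perm=1000, seed=1)
        assert (res.p < 0.01).mean() >= 0.95
        assert (res.direction == -1).all()

    def test_low_n_perm_warns(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="n_perm"):
            mb.permutation_test(rng.random((3, 2)), rng.random((3, 2)), n_perm=50, seed=0)

    def test_too_few_participants_raises(self):
        with pytest.raises(ValueError):
            mb.permutation_test(np.ones((1, 3)), np.ones((5, 3)), n_perm=200, seed=0)


class TestMetaAggregate:
    def test_single_iteration_identity(self):
        p = np.array([0.2, 0.8])
        z = np.array([1.0, -0.5])
        meta = mb.meta_aggregate(p[None, :], z[None, :])
        assert np.allclose(meta.p_meta, p)
        assert np.allclose(meta.z_meta, z)
        assert not meta.flip_flag.any()

    def test_alternating_signs_cancel_and_flag(self):
        z = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        p = np.full((4, 1), 0.5)
        meta = mb.meta_aggregate(p, z)
        assert meta.z_meta[0] == pytest.approx(0.0)
        assert meta.flip_flag[0]

    def test_constant_p_preserved(self):
        p = np.full((10, 3), 0.04)
        z = np.ones((10, 3))
        meta = mb.meta_aggregate(p, z)
        assert np.allclose(meta.p_meta, 0.04)


def brute_force_bh(p, alpha=0.05):
    """Step-up definition applied literally."""
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_max = rank
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_max]] = True
    return mask


class TestFdrBH:
    def test_all_ones_no_rejections(self):
        assert not mb.fdr_bh(np.ones(10)).any()

    def test_hand_worked_step_up(self):
        mask = mb.fdr_bh(np.array([0.001, 0.02, 0.9]), alpha=0.05)
        assert mask.tolist() == [True, True, False]

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            assert np.array_equal(mb.fdr_bh(p), brute_force_bh(p))

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            mb.fdr_bh(np.array([0.5, 1.2]))


class TestDistanceStrength:
    def _edges(self, rng, n, slope, intercept=0.75, noise=0.05):
        d = rng.uniform(10, 140, n)
        return pd.DataFrame(
            {
                "strength": intercept - slope * d + rng.normal(0, noise, n),
                "distance": d,
                "age": rng.uniform(20, 80, n),
                "sex": rng.integers(0, 2, n).astype(float),
            }
        )

    def test_planted_slope_difference_recovered(self):
        rng = np.random.default_rng(8)
        ea = self._edges(rng, 1200, slope=0.002)
        eb = self._edges(rng, 1200, slope=0.004)  # steeper decay in group b
        model = mb.distance_strength_fit(ea, eb, n_boot=300, seed=0)
        assert model.significance["group_x_distance"]
        assert model.mean()["group_x_distance"] == pytest.approx(-0.002, abs=3e-4)

    def test_null_groups_not_significant(self):
        rng = np.random.default_rng(9)
        ea = self._edges(rng, 1200, slope=0.002)
        eb = self._edges(rng, 1200, slope=0.002)
        model = mb.distance_strength_fit(ea, eb, n_boot=300, seed=1)
        assert not model.significance["group"]
        assert not model.significance["group_x_distance"]

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(10)
        ea = self._edges(rng, 300, slope=0.002).assign(sex=1.0)
        eb = self._edges(rng, 300, slope=0.002).assign(sex=1.0)
        with pytest.warns(UserWarning, match="sex"):
            model = mb.distance_strength_fit(ea, eb, n_boot=50, seed=2)
        assert "sex" not in model.coef_names

    def test_too_few_edges_raises(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError):
            mb.distance_strength_fit(
                self._edges(rng, 5, 0.002), self._edges(rng, 100, 0.002), n_boot=10, seed=0
            )

    def test_mean_matches_statsmodels_full_fit(self):
        # cross-check the design construction against statsmodels OLS on the
        # full (unsampled) edge population
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        ea = self._edges(rng, 400, slope=0.002)
        eb = self._edges(rng, 400, slope=0.003)
        model = mb.distance_strength_fit(ea, eb, n_boot=400, fraction=1.0, seed=3)
        pooled = pd.concat([ea.assign(group=0), eb.assign(group=1)], ignore_index=True)
        x = pd.DataFrame(
            {
                "intercept": 1.0,
                "distance": pooled["distance"],
                "group": pooled["group"],
                "group_x_distance": pooled["group"] * pooled["distance"],
                "age": pooled["age"],
                "sex": pooled["sex"],
            }
        )
        fit = sm.OLS(pooled["strength"], x).fit()
        for name in x.columns:
            assert model.mean()[name] == pytest.approx(fit.params[name], abs=1e-9)


class TestGlobalMDTests:
    def _referenced(self, values, group="G"):
        return mb.ReferencedMD(
            md_oa_index=np.asarray(values, dtype=float),
            global_md_oa=float(np.mean(values)),
            group=group,
            reference_residual_mean=np.zeros(len(values)),
            referenced_reference_residuals=np.zeros((2, len(values))),
        )

    def test_all_zero_not_significant(self):
        report = mb.global_md_tests({"G": self._referenced(np.zeros(30))})
        row = report.iloc[0]
        assert row["p"] == 1.0
        assert not row["significant"]

    def test_planted_shift_significant(self):
        rng = np.random.default_rng(13)
        vals = 0.1 + rng.normal(0, 0.02, 50)
        report = mb.global_md_tests({"G": self._referenced(vals)})
        assert report.iloc[0]["p"] < 0.05

    def test_null_calibration(self):
        rng = np.random.default_rng(14)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            vals = rng.normal(0, 0.05, 40)
            report = mb.global_md_tests({"G": self._referenced(vals)})
            rejections += report.iloc[0]["p"] < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.04)

    def test_module_level_rank_sum(self):
        rng = np.random.default_rng(15)
        modules = np.repeat([0, 1], 25)
        a = rng.normal(0, 0.01, 50)
        b = a.copy()
        b[modules == 1] += 0.5  # group difference confined to module 1
        report = mb.global_md_tests(
            {"A": self._referenced(a, "A"), "B": self._referenced(b, "B")},
            module_labels=modules,
        )
        mod_rows = report[report["family"] == "module"].set_index("module")
        assert mod_rows.loc["1", "p"] < 0.01
        assert mod_rows.loc["0", "p"] > 0.2

    def test_too_few_nodes_raises(self):
        with pytest.raises(ValueError):
            mb.global_md_tests({"G": self._referenced(np.zeros(5))})


class TestVizTransform:
    def test_md_endpoints(self):
        assert mb.viz_transform(np.array([0.0, 1.0]), "md").tolist() == [1.0, 100.0]

    def test_p_value_mapping(self):
        assert mb.viz_transform(np.array([1.0]), "p")[0] == pytest.approx(1.0)
        assert mb.viz_transform(np.array([0.05]), "p")[0] == pytest.approx(79.43, abs=0.01)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            mb.viz_transform(np.array([1.5]), "mv")
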