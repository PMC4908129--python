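"""Per-voxel OLS engine against brute-force normal-equations oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voxelwise.linear import fit_linear, probe_outputs
from voxelwise.modelspec import parse_model
from voxelwise.parcellation import parcellate
from voxelwise.volio import VoxelMatrix, mask_from_array


def _geom(tau_grid=(4, 4, 4)):
    return mask_from_array(np.ones(tau_grid))


def ols_oracle(X, y):
    """Independent normal-equations solution with textbook t statistics."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    r = y - X @ beta
    df = X.shape[0] - X.shape[1]
    s2 = (r @ r) / df
    se = np.sqrt(np.diag(s2 * np.linalg.inv(XtX)))
    return beta, se, beta / se, df


class TestFitLinearSharedDesign:
    def test_matches_normal_equations_oracle(self, rng):
        geom = _geom()
        n = 8
        x = rng.standard_normal(n)
        Y = rng.standard_normal((n, geom.tau))
        table = pd.DataFrame({"x": x})
        spec = parse_model("Y ~ x", {"Y": "voxelwise", "x": "scalar"})
        res = fit_linear(spec, table, {"Y": VoxelMatrix(Y, geom)})
        X = np.column_stack([np.ones(n), x])
        for j in range(geom.tau):
            beta, se, t, df = ols_oracle(X, Y[:, j])
            assert np.allclose(res.beta[j], beta, atol=1e-10)
            assert np.allclose(res.stat[j], t, atol=1e-10)
            assert res.df_residual[j] == df

    def test_exact_fit_zero_residual_convention(self):
        geom = _geom((2, 2, 2))
        x = np.array([1.0, 2.0, 3.0, 4.0])
        Y = np.tile((2.0 * x)[:, None], (1, geom.tau))
        table = pd.DataFrame({"x": x})
        spec = parse_model("Y ~ x", {"Y": "voxelwise", "x": "scalar"})
        res = fit_linear(spec, table, {"Y": VoxelMatrix(Y, geom)})
        assert np.allclose(res.beta[:, 1], 2.0)
        assert np.all(res.se[:, 1] == 0)
        assert np.all(np.isinf(res.stat[:, 1]) & (res.stat[:, 1] > 0))
        assert np.all(res.pvalue[:, 1] == 0)
        assert res.degenerate.all()

    def test_global_rank_deficiency_hard_error(self, rng):
        geom = _geom((2, 2, 2))
        n = 10
        x = rng.standard_normal(n)
        table = pd.DataFrame({"x": x, "x2": 2 * x})
        Y = rng.standard_normal((n, geom.tau))
        spec = parse_model("Y ~ x + x2", {"Y": "voxelwise", "x": "scalar", "x2": "scalar"})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_linear(spec, table, {"Y": VoxelMatrix(Y, geom)})

    def test_nan_subjects_dropped_per_voxel(self, rng):
        geom = _geom((2, 2, 2))
        n = 12
        x = rng.standard_normal(n)
        Y = rng.standard_normal((n, geom.tau))
        Y[3, 0] = np.nan
        Y[5, 0] = np.nan
        table = pd.DataFrame({"x": x})
        spec = parse_model("Y ~ x", {"Y": "voxelwise", "x": "scalar"})
        res = fit_linear(spec, table, {"Y": VoxelMatrix(Y, geom)})
        assert res.df_residual[0] == (n - 2) - 2
        assert res.df_residual[1] == n - 2
        keep = ~np.isnan(Y[:, 0])
        X = np.column_stack([np.ones(keep.sum()), x[keep]])
        beta, se, t, _ = ols_oracle(X, Y[keep, 0])
        assert np.allclose(res.stat[0], t, atol=1e-10)

    def test_strict_mode_errors_on_nan(self, rng):
        geom = _geom((2, 2, 2))
        Y = rng.standard_normal((6, geom.tau))
        Y[0, 0] = np.nan
        table = pd.DataFrame({"x": rng.standard_normal(6)})
        spec = parse_model("Y ~ x", {"Y": "voxelwise", "x": "scalar"})
        with pytest.raises(ValueError, match="strict"):
            fit_linear(spec, table, {"Y": VoxelMatrix(Y, geom)}, strict=True)


class TestFitLinearVoxelwiseCovariates:
    def test_voxelwise_path_matches_oracle_and_fast_path_contract(self, rng):
        geom = _geom()
        n = 20
        table = pd.DataFrame({"AGE": rng.normal(70, 5, n)})
        V = VoxelMatrix(rng.standard_normal((n, geom.tau)), geom)
        Y = VoxelMatrix(rng.standard_normal((n, geom.tau)), geom)
        spec = parse_model(
            "Y ~ V + AGE", {"Y": "voxelwise", "V": "voxelwise", "AGE": "scalar"}
        )
        res = fit_linear(spec, table, {"Y": Y, "V": V})
        for j in [0, 5, geom.tau - 1]:
            X = np.column_stack([np.ones(n), V.data[:, j], table["AGE"]])
            beta, se, t, _ = ols_oracle(X, Y.data[:, j])
            assert np.allclose(res.stat[j], t, atol=1e-10)

    def test_partition_invariance_bitwise(self, rng):
        geom = _geom()
        n = 15
        table = pd.DataFrame({"AGE": rng.normal(70, 5, n)})
        V = VoxelMatrix(rng.standard_normal((n, geom.tau)), geom)
        Y = VoxelMatrix(rng.standard_normal((n, geom.tau)), geom)
        spec = parse_model("Y ~ V", {"Y": "voxelwise", "V": "voxelwise"})
        maps = [
            fit_linear(spec, table, {"Y": Y, "V": V}, pm=parcellate(geom.tau, P)).stat
            for P in (1, 7, 64)
        ]
        assert np.array_equal(maps[0], maps[1])
        assert np.array_equal(maps[0], maps[2])

    def test_rank_deficient_voxel_flagged_not_fatal(self, rng):
        geom = _geom((2, 2, 2))
        n = 10
        V = rng.standard_normal((n, geom.tau))
        V[:, 3] = 1.0  # collinear with the intercept at voxel 3
        Y = rng.standard_normal((n, geom.tau))
        table = pd.DataFrame(index=range(n))
        spec = parse_model("Y ~ V", {"Y": "voxelwise", "V": "voxelwise"})
        res = fit_linear(
            spec, table, {"Y": VoxelMatrix(Y, geom), "V": VoxelMatrix(V, geom)}
        )
        assert res.degenerate[3]
        assert np.isnan(res.beta[3]).all()
        assert not res.degenerate[[0, 1, 2, 4]].any()

    def test_interaction_model_emits_six_coefficient_maps(self, rng):
        geom = _geom((2, 2, 2))
        n = 30
        table = pd.DataFrame(
            {
                "CDRSOB": rng.gamma(2.0, 1.0, n),
                "AGE": rng.normal(72, 6, n),
                "GENDER": rng.choice(["F", "M"], n),
            }
        )
        A = VoxelMatrix(rng.standard_normal((n, geom.tau)) + 1.0, geom)
        F = VoxelMatrix(rng.standard_normal((n, geom.tau)) + 1.0, geom)
        spec = parse_model(
            "CDRSOB ~ A + F + A*F + AGE + GENDER",
            {"CDRSOB": "scalar", "A": "voxelwise", "F": "voxelwise",
             "AGE": "scalar", "GENDER": "factor"},
        )
        res = fit_linear(spec, table, {"A": A, "F": F})
        assert res.term_names == [
            "Intercept", "A", "F", "A:F", "AGE", "GENDER[M]"
        ]
        assert res.beta.shape == (geom.tau, 6)
        assert res.stat.shape == (geom.tau, 6)
        assert np.isfinite(res.stat).all()


class TestInvariants:
    def test_scale_equivariance(self, rng):
        geom = _geom((2, 2, 2))
        n = 25
        x = rng.standard_normal(n)
        Y = rng.standard_normal((n, geom.tau))
        c = 3.7
        t1 = fit_linear(
            parse_model("Y ~ x", {"Y": "voxelwise", "x": "scalar"}),
            pd.DataFrame({"x": x}),
            {"Y": VoxelMatrix(Y, geom)},
        )
        t2 = fit_linear(
            parse_model("Y ~ x", {"Y": "voxelwise", "x": "scalar"}),
            pd.DataFrame({"x": c * x}),
            {"Y": VoxelMatrix(Y, geom)},
        )
        assert np.allclose(t2.beta[:, 1], t1.beta[:, 1] / c, atol=1e-10)
        assert np.allclose(t2.stat[:, 1], t1.stat[:, 1], atol=1e-10)

    def test_pvalues_match_t_distribution(self, rng):
        geom = _geom((2, 2, 2))
        n = 18
        x = rng.standard_normal(n)
        Y = rng.standard_normal((n, geom.tau))
        res = fit_linear(
            parse_model("Y ~ x", {"Y": "voxelwise", "x": "scalar"}),
            pd.DataFrame({"x": x}),
            {"Y": VoxelMatrix(Y, geom)},
        )
        expected = 2 * stats.t.sf(np.abs(res.stat), n - 2)
        assert np.allclose(res.pvalue, expected)


class TestProbeOutputs:
    def test_scalar_response_model_schema(self, rng):
        geom = _geom((2, 2, 2))
        n = 12
        table = pd.DataFrame(
            {"MMSE": rng.normal(27, 2, n), "AGE": rng.normal(70, 5, n),
             "GENDER": rng.choice(["F", "M"], n)}
        )
        A = VoxelMatrix(rng.standard_normal((n, geom.tau)), geom)
        spec = parse_model(
            "MMSE ~ A + AGE + GENDER",
            {"MMSE": "scalar", "A": "voxelwise", "AGE": "scalar", "GENDER": "factor"},
        )
        schema = probe_outputs(spec, table, {"A": A})
        assert schema["terms"] == ["Intercept", "A", "AGE", "GENDER[M]"]
        assert schema["stats"] == ["beta", "se", "t", "p"]

    def test_three_level_factor_gets_two_dummies(self, rng):
        geom = _geom((2, 2, 2))
        n = 12
        table = pd.DataFrame({"site": list("abc") * 4})
        Y = VoxelMatrix(rng.standard_normal((n, geom.tau)), geom)
        spec = parse_model("Y ~ site", {"Y": "voxelwise", "site": "factor"})
        schema = probe_outputs(spec, table, {"Y": Y})
        assert schema["terms"] == ["Intercept", "site[b]", "site[c]"]

    def test_probe_surfaces_failure_before_run(self, rng):
        geom = _geom((2, 2, 2))
        table = pd.DataFrame({"x": [1.0, 2.0]})
        Y = VoxelMatrix(rng.standard_normal((2, geom.tau)), geom)
        spec = parse_model("Y ~ x", {"Y": "voxelwise", "x": "scalar"})
        with pytest.raises(ValueError, match="too few subjects"):
            probe_outputs(spec, table, {"Y": Y})
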