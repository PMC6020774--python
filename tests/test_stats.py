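"""Correlation battery: formulas vs independent oracles, FDR, Steiger test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from vdrdti.cohort import EffectConfig, simulate_cohort
from vdrdti.stats import (
    BatterySpec,
    CorrTest,
    SteigerTest,
    bh_fdr,
    default_battery,
    partial_corr_one_tailed,
    pearson_one_tailed,
    run_battery,
    scatter_plot,
    steiger_z,
    williams_t,
)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        res = pearson_one_tailed(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_raw < 1e-12

    def test_hand_example(self):
        res = pearson_one_tailed([1.0, 2, 3], [1.0, 3, 2])
        assert res.r == pytest.approx(0.5, abs=1e-12)

    def test_r_half_n19_one_tailed(self):
        """r = 0.5 at n = 19: t ~ 2.381, one-tailed p ~ 0.015 (t-CDF oracle)."""
        rng = np.random.default_rng(0)
        # construct x, y with exactly r = 0.5
        x = rng.normal(size=19)
        e = rng.normal(size=19)
        e -= np.polyval(np.polyfit(x, e, 1), x)  # orthogonalize
        xs = (x - x.mean()) / x.std()
        es = (e - e.mean()) / e.std()
        y = 0.5 * xs + np.sqrt(1 - 0.25) * es
        res = pearson_one_tailed(x, y)
        assert res.r == pytest.approx(0.5, abs=1e-12)
        assert res.df == 17
        t_expected = 0.5 * np.sqrt(17) / np.sqrt(0.75)
        assert res.t_or_z == pytest.approx(t_expected, abs=1e-10)
        assert res.p_raw == pytest.approx(sps.t.sf(t_expected, 17), abs=1e-12)
        assert res.t_or_z == pytest.approx(2.381, abs=2e-3)

    def test_one_tailed_is_positive_alternative(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = -x + rng.normal(size=30) * 0.5
        res = pearson_one_tailed(x, y)
        assert res.r < 0 and res.p_raw > 0.5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_one_tailed([1.0, 1, 1], [1.0, 2, 3])


class TestPartialCorrelation:
    def test_uncorrelated_covariate_reduces_to_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        z = rng.normal(size=200)
        # orthogonalize z against x and y exactly
        for v in (x, y):
            z -= (z @ v) / (v @ v) * v
        z -= z.mean()
        # after exact orthogonalization r_xz, r_yz ~ 0 up to centering effects
        simple = pearson_one_tailed(x, y)
        partial = partial_corr_one_tailed(x, y, z)
        assert partial.r == pytest.approx(simple.r, abs=1e-2)
        assert partial.df == simple.df - 1

    def test_formula_hand_example(self):
        # r_xy=0.6, r_xz=r_yz=0.5 -> (0.6-0.25)/0.75 = 0.4667
        r = (0.6 - 0.25) / 0.75
        assert r == pytest.approx(0.46667, abs=1e-5)

    def test_residual_regression_equivalence(self):
        """The covariance formula equals correlating OLS residuals (1e-12)."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y, z = rng.normal(size=(3, 40))
            res = partial_corr_one_tailed(x, y, z)
            Z = np.column_stack([np.ones(40), z])
            rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
            ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
            assert res.r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        x, y, z = rng.normal(size=(3, 25))
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ours = partial_corr_one_tailed(x, y, z, tail="two")
        theirs = pg.partial_corr(df, x="x", y="y", covar="z")
        assert ours.r == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-10)
        assert ours.p_raw == pytest.approx(float(theirs["p_val"].iloc[0]), abs=1e-10)

    def test_degenerate_covariate_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            partial_corr_one_tailed(x, np.arange(10.0) ** 2, 2 * x + 3)


class TestSteiger:
    def test_equal_correlations_give_zero(self):
        s = steiger_z(0.5, 0.5, 0.3, 19)
        assert s.z == 0.0 and s.p_two_tailed == 1.0

    def test_antisymmetry(self):
        a = steiger_z(0.7, 0.2, 0.3, 19)
        b = steiger_z(0.2, 0.7, 0.3, 19)
        assert a.z == pytest.approx(-b.z, abs=1e-12)

    def test_non_psd_triple_rejected(self):
        with pytest.raises(ValueError):
            steiger_z(0.9, -0.9, 0.9, 19)

    def test_type_I_error_near_nominal(self):
        """Trivariate-normal null (r12 = r13): rejection rate ~ alpha at n=19.

        Smaller replicate count here; the full-scale check runs in the
        acceptance suite.
        """
        rej = steiger_null_rejection_rate(reps=20000, seed=5)
        assert rej == pytest.approx(0.05, abs=0.008)

    def test_williams_variant_agrees_in_direction(self):
        z = steiger_z(0.7, 0.3, 0.4, 19).z
        t, _ = williams_t(0.7, 0.3, 0.4, 19)
        assert np.sign(z) == np.sign(t)
        assert abs(z - t) < 0.5


def steiger_null_rejection_rate(reps: int, seed: int, n: int = 19) -> float:
    """Monte-Carlo type-I error of the dependent-correlation test under a
    trivariate normal with true r12 = r13."""
    rng = np.random.default_rng(seed)
    C = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.3], [0.4, 0.3, 1.0]])
    L = np.linalg.cholesky(C)
    crit = sps.norm.ppf(0.975)
    rejected = 0
    batch = 5000
    done = 0
    while done < reps:
        m = min(batch, reps - done)
        X = rng.standard_normal((m, n, 3)) @ L.T
        Xc = X - X.mean(axis=1, keepdims=True)
        Xs = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
        r12 = np.einsum("ri,ri->r", Xs[:, :, 0], Xs[:, :, 1])
        r13 = np.einsum("ri,ri->r", Xs[:, :, 0], Xs[:, :, 2])
        r23 = np.einsum("ri,ri->r", Xs[:, :, 1], Xs[:, :, 2])
        z = np.array(
            [steiger_z(a, b, c, n).z for a, b, c in zip(r12, r13, r23)]
        )
        rejected += int((np.abs(z) > crit).sum())
        done += m
    return rejected / reps


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: p~(i) = min_{j>=i} p(j) m / j, capped."""
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.031])[0] == pytest.approx(0.031)

    def test_step_up_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(1, 40), st.integers(0, 10**6))
    def test_matches_brute_force_oracle(self, m, seed):
        p = np.random.default_rng(seed).random(m)
        assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_adjusted_monotone_after_sorting(self):
        p = np.random.default_rng(8).random(50)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestBattery:
    def test_single_test_fdr_equals_raw(self):
        t = simulate_cohort(EffectConfig(n_subjects=19, seed=1))
        spec = BatterySpec(correlations=[CorrTest("uf_fa", "mean_high_recall")])
        rep = run_battery(t, spec)
        assert rep.correlations[0].p_fdr == pytest.approx(rep.correlations[0].p_raw)

    def test_fdr_never_below_raw_and_order_deterministic(self):
        t = simulate_cohort(EffectConfig(n_subjects=30, seed=2))
        rep = run_battery(t, default_battery())
        for c in rep.correlations:
            assert c.p_fdr >= c.p_raw - 1e-15
        labels = [c.label for c in rep.correlations]
        rep2 = run_battery(t, default_battery())
        assert labels == [c.label for c in rep2.correlations]

    def test_partial_tests_control_target_size(self):
        t = simulate_cohort(EffectConfig(n_subjects=40, seed=3))
        rep = run_battery(t, default_battery())
        partials = [c for c in rep.correlations if c.covariates]
        assert len(partials) == 3
        assert all(c.df == 40 - 3 for c in partials)

    def test_steiger_entries_two_tailed_uncorrected(self):
        t = simulate_cohort(EffectConfig(n_subjects=25, seed=4))
        rep = run_battery(t, default_battery())
        assert len(rep.steiger) == 4
        frame = rep.to_frame()
        st_rows = frame[frame["kind"] == "steiger"]
        assert st_rows["p_fdr"].isna().all()

    def test_missing_column_raises_schema_error(self):
        t = simulate_cohort(EffectConfig(n_subjects=19, seed=5))
        with pytest.raises(KeyError):
            run_battery(t.drop(columns=["uf_fa"]), default_battery())

    def test_report_tsv_json_roundtrip(self, tmp_path):
        t = simulate_cohort(EffectConfig(n_subjects=19, seed=6))
        rep = run_battery(t, default_battery())
        rep.to_tsv(tmp_path / "report.tsv")
        rep.to_json(tmp_path / "report.json")
        back = pd.read_csv(tmp_path / "report.tsv", sep="\t")
        assert len(back) == len(rep.correlations) + len(rep.steiger)
        import json

        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["q"] == rep.q

    def test_scatter_plot_written(self, tmp_path):
        t = simulate_cohort(EffectConfig(n_subjects=19, seed=7))
        out = tmp_path / "scatter.png"
        scatter_plot(t["tract_strength"], t["mean_selectivity"], out,
                     covariate=t["target_size"])
        assert out.stat().st_size > 0
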