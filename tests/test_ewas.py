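import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methdecon import BetaMatrix, CpGAssociation, ValidationError, qvalues
from methdecon.ewas import test_cpgs as cpg_tests
from methdecon.io import validate_sample_sheet


def _sheet(n_tumor, n_normal, ages=None):
    n = n_tumor + n_normal
    if ages is None:
        ages = np.linspace(40, 70, n)
    return validate_sample_sheet(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "tissue_status": ["tumor"] * n_tumor + ["normal"] * n_normal,
        "subtype": ["LumA"] * n_tumor + [None] * n_normal,
        "stage": ["I"] * n_tumor + [None] * n_normal,
        "age": ages,
    }))


def _betas(values):
    values = np.atleast_2d(values)
    return BetaMatrix(
        pd.Index([f"cg{i}" for i in range(values.shape[0])]),
        pd.Index([f"s{j}" for j in range(values.shape[1])]),
        values,
    )


class TestOLS:
    def test_matches_normal_equations_oracle(self):
        """Coefficient, SE and p reproduce a hand-rolled OLS + t-test."""
        rng = np.random.default_rng(8)
        n = 20
        sheet = _sheet(10, 10, ages=rng.uniform(40, 80, n))
        omega = rng.dirichlet([1, 1, 1], size=n)
        y = rng.random(n)
        res = cpg_tests(_betas(y), sheet, omega, adjust_age=True)
        row = res.frame.iloc[0]

        # independent oracle: explicit normal equations + t distribution
        tumor = np.r_[np.ones(10), np.zeros(10)]
        age = sheet["age"].to_numpy()
        drop = int(np.argmax(omega.mean(axis=0)))
        keep_cols = [k for k in range(3) if k != drop]
        X = np.column_stack([np.ones(n), tumor, age, omega[:, keep_cols]])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_hat
        dof = n - X.shape[1]
        sigma2 = resid @ resid / dof
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta_hat[1] / se
        p = 2 * stats.t.sf(abs(t), dof)
        assert row["beta_tumor"] == pytest.approx(beta_hat[1], rel=1e-10)
        assert row["se"] == pytest.approx(se, rel=1e-10)
        assert row["p"] == pytest.approx(p, rel=1e-10)
        assert row["n_used"] == n

    def test_constant_probe_flagged_missing(self):
        sheet = _sheet(5, 5)
        values = np.vstack([np.full(10, 0.4), np.linspace(0.1, 0.9, 10)])
        res = cpg_tests(_betas(values), sheet, None, adjust_age=False)
        assert np.isnan(res.frame.loc[0, "p"])
        assert np.isfinite(res.frame.loc[1, "p"])

    def test_noiseless_spike_recovered_exactly(self):
        sheet = _sheet(6, 6)
        y = np.r_[np.full(6, 0.7), np.full(6, 0.4)]  # +0.3 in tumors
        res = cpg_tests(_betas(y), sheet, None, adjust_age=False)
        row = res.frame.iloc[0]
        assert row["beta_tumor"] == pytest.approx(0.3, abs=1e-12)
        assert row["p"] < 1e-12 or row["p"] == 0.0
        assert row["direction"] == "hyper"

    def test_direction_matches_sign(self):
        sheet = _sheet(6, 6)
        rng = np.random.default_rng(3)
        up = np.r_[np.full(6, 0.8), np.full(6, 0.2)] + rng.normal(0, 0.01, 12)
        dn = np.r_[np.full(6, 0.2), np.full(6, 0.8)] + rng.normal(0, 0.01, 12)
        res = cpg_tests(_betas(np.vstack([up, dn])), sheet, None, adjust_age=False)
        assert list(res.frame["direction"]) == ["hyper", "hypo"]

    def test_probewise_missing_drops_samples(self):
        sheet = _sheet(8, 8)
        rng = np.random.default_rng(4)
        values = rng.random((3, 16))
        values[1, :3] = np.nan
        res = cpg_tests(_betas(values), sheet, None, adjust_age=False)
        assert list(res.frame["n_used"]) == [16, 13, 16]

    def test_missing_age_drops_samples_in_adjusted_model(self):
        ages = np.r_[np.full(5, np.nan), np.linspace(40, 70, 11)]
        sheet = _sheet(8, 8, ages=ages)
        rng = np.random.default_rng(5)
        res = cpg_tests(_betas(rng.random((2, 16))), sheet, None, adjust_age=True)
        assert (res.frame["n_used"] == 11).all()

    def test_single_tissue_group_rejected(self):
        sheet = validate_sample_sheet(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(8)],
            "tissue_status": ["tumor"] * 8,
            "subtype": ["LumA"] * 8,
            "stage": ["I"] * 8,
            "age": np.linspace(40, 60, 8),
        }))
        with pytest.raises(ValidationError, match="both tumor and normal"):
            cpg_tests(_betas(np.random.default_rng(1).random((1, 8))), sheet,
                      None, adjust_age=False)

    def test_too_few_samples_rejected(self):
        sheet = _sheet(2, 2)
        with pytest.raises(ValidationError, match="degrees of freedom"):
            cpg_tests(_betas(np.random.default_rng(2).random(4)), sheet, None,
                      adjust_age=True)

    def test_summary_reports_counts(self):
        sheet = _sheet(10, 10)
        rng = np.random.default_rng(6)
        res = cpg_tests(_betas(rng.random((20, 20))), sheet, None, adjust_age=False)
        assert "probes tested:        20 of 20" in res.summary()


class TestQvalues:
    def test_bh_equivalence_when_pi0_forced_to_one(self):
        """With pi0 = 1 the step-up estimator is exactly Benjamini-Hochberg."""
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042,
                      0.06, 0.074, 0.205, 0.212, 0.216])
        q = qvalues(p, lambda_grid=np.array([0.0]))
        m = len(p)
        # independent BH oracle: step-up cumulative minimum
        order = np.argsort(p)
        bh = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            prev = min(prev, p[i] * m / rank_from_top)
            bh[i] = prev
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_all_ones_give_pi0(self):
        q = qvalues(np.ones(50))
        np.testing.assert_allclose(q, 1.0)

    def test_uniform_null_yields_no_discoveries(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            q = qvalues(rng.random(10_000))
            hits += (q < 0.05).sum()
        assert hits / (20 * 10_000) < 0.001

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_order_invariance_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(200)
        q = qvalues(p)
        perm = rng.permutation(200)
        q_perm = qvalues(p[perm])
        np.testing.assert_allclose(q[perm], q_perm, atol=1e-12)
        assert (q >= 0).all() and (q <= 1).all()

    def test_monotone_in_p(self):
        rng = np.random.default_rng(9)
        p = rng.random(500)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty_and_invalid_inputs(self):
        assert qvalues(np.array([])).size == 0
        with pytest.raises(ValidationError):
            qvalues(np.array([0.5, 1.5]))
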