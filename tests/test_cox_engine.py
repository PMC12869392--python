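"""Oracle checks of the counting-process Breslow partial-likelihood engine."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from oudtraj.survival import CountingProcessCox, CoxData
from oudtraj.survival._cox import default_lambdas, fista_lasso, newton_fit

from conftest import toy_rows


def brute_loglik(start, stop, event, x, beta):
    """Breslow partial log-likelihood by direct risk-set enumeration."""
    times = sorted({t for t, d in zip(stop, event) if d})
    ll = 0.0
    for tau in times:
        deaths = [i for i in range(len(stop)) if stop[i] == tau and event[i]]
        risk = [i for i in range(len(stop)) if start[i] < tau <= stop[i]]
        ll += sum(beta * x[i] for i in deaths)
        ll -= len(deaths) * np.log(sum(np.exp(beta * x[i]) for i in risk))
    return ll


class TestPartialLikelihood:
    def test_toy_matches_grid_search(self):
        """Single binary covariate on a three-row toy with two events: the
        unpenalized coefficient must sit at the brute-force maximizer of the
        enumerated partial likelihood (1-D grid search oracle)."""
        start = [0.0, 0.0, 0.0]
        stop = [5.0, 6.0, 7.0]
        event = [1, 1, 0]
        x = [1.0, 0.0, 1.0]
        grid = np.linspace(-4, 4, 20001)
        lls = [brute_loglik(start, stop, event, x, b) for b in grid]
        b_oracle = grid[int(np.argmax(lls))]
        data = CoxData.from_arrays(start, stop, event, np.array(x)[:, None])
        beta, _, _ = newton_fit(data)
        assert beta[0] == pytest.approx(b_oracle, abs=2e-3)

    def test_loglik_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(0)
        start = np.repeat([0.0, 1.0, 2.0], 4)
        stop = start + rng.integers(1, 4, 12)
        event = rng.integers(0, 2, 12)
        event[0] = 1
        x = rng.normal(size=12)
        data = CoxData.from_arrays(start, stop, event, x[:, None])
        for beta in (-0.7, 0.0, 1.3):
            assert data.loglik(np.array([beta])) == pytest.approx(
                brute_loglik(start, stop, event, x, beta)
            )

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        n, p = 40, 3
        start = np.zeros(n)
        stop = rng.uniform(1, 10, n)
        event = rng.integers(0, 2, n)
        event[:5] = 1
        X = rng.normal(size=(n, p))
        data = CoxData.from_arrays(start, stop, event, X)
        beta = rng.normal(scale=0.3, size=p)
        _, grad = data.loglik_grad(beta)
        eps = 1e-6
        for j in range(p):
            e = np.zeros(p)
            e[j] = eps
            fd = (data.loglik(beta + e) - data.loglik(beta - e)) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_no_events_refused(self):
        with pytest.raises(ValueError, match="no events"):
            CoxData.from_arrays([0.0], [1.0], [0], np.ones((1, 1)))


class TestAgainstLifelines:
    def test_unpenalized_fit_matches_lifelines_without_ties(self):
        """With no tied event times Breslow and Efron coincide, so our Newton
        fit must agree with lifelines' CoxTimeVaryingFitter."""
        from lifelines import CoxTimeVaryingFitter

        df = toy_rows()
        res = CountingProcessCox(df, feature_cols=["x", "z"]).fit()
        ctv = CoxTimeVaryingFitter()
        ctv.fit(
            df, id_col="person_id", start_col="t_start", stop_col="t_stop",
            event_col="event",
        )
        for c in ("x", "z"):
            assert res.params[c] == pytest.approx(ctv.params_[c], rel=1e-4, abs=1e-5)
            assert res.bse[c] == pytest.approx(ctv.standard_errors_[c], rel=1e-3)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestAgainstRSurvival:
    def test_breslow_ties_match_coxph(self, tmp_path):
        """Tied event times: our Breslow fit must match
        survival::coxph(..., ties='breslow') on the same start-stop frame."""
        rng = np.random.default_rng(4)
        n = 60
        df = pd.DataFrame(
            {
                "person_id": np.arange(n),
                "t_start": np.zeros(n),
                "t_stop": rng.integers(1, 8, n).astype(float),  # heavy ties
                "event": rng.integers(0, 2, n),
                "x": rng.normal(size=n).round(3),
                "z": rng.integers(0, 2, n).astype(float),
            }
        )
        df.loc[0, "event"] = 1
        csv = tmp_path / "rows.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                library(survival)
                d <- read.csv("{csv}")
                f <- coxph(Surv(t_start, t_stop, event) ~ x + z, data=d,
                           ties="breslow")
                cat(sprintf("%.10f %.10f\\n", coef(f)[1], coef(f)[2]))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        )
        bx, bz = map(float, out.stdout.split())
        res = CountingProcessCox(df, feature_cols=["x", "z"]).fit()
        assert res.params["x"] == pytest.approx(bx, abs=1e-6)
        assert res.params["z"] == pytest.approx(bz, abs=1e-6)


class TestLasso:
    @staticmethod
    def _data(seed=0, n=200, p=6):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        eta = X[:, 0]  # one true effect
        stop = rng.exponential(np.exp(-eta)) + 0.01
        event = (stop < np.quantile(stop, 0.7)).astype(int)
        return CoxData.from_arrays(np.zeros(n), stop, event, X)

    def test_lambda_max_zeroes_everything(self):
        data = self._data()
        pf = np.ones(data.X.shape[1])
        lams = default_lambdas(data, pf)
        beta = fista_lasso(data, lams[0] * 1.0001, pf, tol=1e-9)
        assert np.allclose(beta, 0.0, atol=1e-8)

    def test_kkt_conditions_at_solution(self):
        """Independent optimality oracle: at the minimizer of
        -ll/n + lam*||b||_1, |grad_j| <= lam for zero coefficients and
        grad_j = -lam * sign(b_j) for active ones."""
        data = self._data()
        pf = np.ones(data.X.shape[1])
        lam = default_lambdas(data, pf)[10]
        beta = fista_lasso(data, lam, pf, tol=1e-12, max_iter=5000)
        _, grad = data.loglik_grad(beta)
        g = -grad / data.n_events  # gradient of the smooth loss
        for j, b in enumerate(beta):
            if b == 0:
                assert abs(g[j]) <= lam * 1.001
            else:
                assert g[j] + lam * np.sign(b) == pytest.approx(0.0, abs=lam * 1e-2)

    def test_path_is_warm_started_and_sparser_at_high_lambda(self):
        data = self._data()
        pf = np.ones(data.X.shape[1])
        lams = default_lambdas(data, pf, n_lambda=10)
        from oudtraj.survival._cox import lasso_path

        path = lasso_path(data, lams, pf)
        nnz = (path != 0).sum(axis=1)
        assert nnz[0] <= nnz[-1]
        assert nnz[-1] >= 1
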