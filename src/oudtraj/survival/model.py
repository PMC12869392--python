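"""Proportional-hazards models on person-period data, statsmodels-style.

:class:`CountingProcessCox` is the model object: built from a long-format
person-period frame (``person_id, t_start, t_stop, event, features...``).
``fit()`` maximizes the unpenalized Breslow partial likelihood and returns
:class:`CoxResults` (coefficients, Wald intervals, ``summary()``);
``fit_cv()`` runs a cross-validated lasso path and returns
:class:`LassoCoxResults` holding only the exactly-nonzero coefficients at
the CV-deviance-minimizing penalty.

On top of the model objects sit the pipeline operations: per-shard penalized
fits, shard aggregation (selection frequency + mean hazard ratio),
frequency/|log HR| prioritization, and the low-dimensional summary-feature
fit with Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _cox
from ._cox import ConvergenceError, CoxData

logger = logging.getLogger(__name__)

_META_COLS = {"person_id", "t_start", "t_stop", "event", "transition"}

#: |beta| beyond which an estimate is flagged as likely separation
SEPARATION_ABS_COEF = 10.0


class CountingProcessCox:
    """Cox proportional-hazards model on start-stop (counting-process) rows.

    Parameters
    ----------
    data : person-period frame with ``person_id, t_start, t_stop, event``
        plus numeric feature columns.
    feature_cols : columns to use as predictors; defaults to every numeric
        non-metadata column.  Constant columns are dropped with a logged
        note.  The design is standardized internally (zero mean, unit
        variance); all reported coefficients are on the original scale.
    transition : optional label carried through to results.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        feature_cols: Sequence[str] | None = None,
        transition: str | None = None,
    ):
        if feature_cols is None:
            feature_cols = [
                c
                for c in data.columns
                if c not in _META_COLS and pd.api.types.is_numeric_dtype(data[c])
            ]
        X = data[list(feature_cols)].to_numpy(dtype=float)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            dropped = [c for c, k in zip(feature_cols, keep) if not k]
            logger.info("dropping constant columns: %s", dropped)
        self.feature_names = [c for c, k in zip(feature_cols, keep) if k]
        X = X[:, keep]
        self._mean = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._Xs = (X - self._mean) / self._sd
        self.transition = transition
        self.person_id = data["person_id"].to_numpy()
        self._start = data["t_start"].to_numpy(dtype=float)
        self._stop = data["t_stop"].to_numpy(dtype=float)
        self._event = data["event"].to_numpy(dtype=int)
        self.data = CoxData.from_arrays(self._start, self._stop, self._event, self._Xs)

    @property
    def n_events(self) -> int:
        return self.data.n_events

    # ------------------------------------------------------------------
    def fit(self, tol: float = 1e-9, max_iter: int = 50) -> "CoxResults":
        """Unpenalized fit (damped Newton); Wald standard errors."""
        beta_s, se_s, ll = _cox.newton_fit(self.data, tol=tol, max_iter=max_iter)
        beta = beta_s / self._sd
        se = se_s / self._sd
        return CoxResults(
            model=self,
            params=pd.Series(beta, index=self.feature_names),
            bse=pd.Series(se, index=self.feature_names),
            loglik=ll,
        )

    # ------------------------------------------------------------------
    def fit_cv(
        self,
        K: int = 10,
        seed: int = 0,
        n_lambda: int = 25,
        lambda_min_ratio: float = 0.05,
        penalty_factor: Mapping[str, float] | None = None,
        tol: float = 1e-6,
        max_iter: int = 1000,
    ) -> "LassoCoxResults":
        """L1 path with K-fold CV over persons; keeps the deviance minimizer.

        Fold assignment partitions *persons* (not rows) by a seeded draw, so
        a person's correlated intervals never straddle the train/test split.
        The penalty is chosen at the minimum of the summed held-out partial
        deviance (-2 * test log partial likelihood), not the 1-SE rule.
        """
        if K < 2:
            raise ValueError("K must be >= 2")
        pf = np.ones(len(self.feature_names))
        if penalty_factor:
            for name, v in penalty_factor.items():
                if name in self.feature_names:
                    pf[self.feature_names.index(name)] = float(v)
        lambdas = _cox.default_lambdas(self.data, pf, n_lambda, lambda_min_ratio)

        persons = np.unique(self.person_id)
        rng = np.random.default_rng(seed)
        fold_of = dict(
            zip(persons, rng.permuted(np.arange(persons.size) % K))
        )
        row_fold = np.asarray([fold_of[p] for p in self.person_id])

        deviance = np.zeros(len(lambdas))
        for k in range(K):
            test = row_fold == k
            train = ~test
            if self._event[test].sum() == 0 or self._event[train].sum() < 2:
                logger.warning("fold %d lacks events; skipped in CV", k)
                continue
            d_train = CoxData.from_arrays(
                self._start[train], self._stop[train], self._event[train], self._Xs[train]
            )
            d_test = CoxData.from_arrays(
                self._start[test], self._stop[test], self._event[test], self._Xs[test]
            )
            path = _cox.lasso_path(d_train, lambdas, pf, tol=tol, max_iter=max_iter)
            for j in range(len(lambdas)):
                deviance[j] += -2.0 * d_test.loglik(path[j])

        best = int(np.argmin(deviance))
        full_path = _cox.lasso_path(self.data, lambdas, pf, tol=tol, max_iter=max_iter)
        beta_s = full_path[best]
        beta = beta_s / self._sd
        nz = np.flatnonzero(beta_s)
        selected = {self.feature_names[j]: float(beta[j]) for j in nz}
        return LassoCoxResults(
            model=self,
            selected=selected,
            lam=float(lambdas[best]),
            lambdas=lambdas,
            cv_deviance=deviance,
            K=K,
            seed=seed,
        )


@dataclass
class CoxResults:
    """Unpenalized fit: coefficients, Wald inference, summary table."""

    model: CountingProcessCox
    params: pd.Series
    bse: pd.Series
    loglik: float

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "CI_low": np.exp(self.params - z * self.bse),
                "CI_high": np.exp(self.params + z * self.bse),
            }
        )

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        out = pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                "se": self.bse,
                "CI_low": ci["CI_low"],
                "CI_high": ci["CI_high"],
                "p": self.pvalues,
            }
        )
        out.index.name = "feature"
        return out


@dataclass
class LassoCoxResults:
    """CV-lasso fit: the exactly-nonzero coefficients at the chosen penalty."""

    model: CountingProcessCox
    selected: dict[str, float]
    lam: float
    lambdas: np.ndarray
    cv_deviance: np.ndarray
    K: int
    seed: int

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": pd.Series(self.selected, dtype=float),
                "HR": np.exp(pd.Series(self.selected, dtype=float)),
            }
        )
        out.index.name = "feature"
        return out.sort_values("coef", key=np.abs, ascending=False)


# ---------------------------------------------------------------------------
# sharded selection pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShardFitResult:
    """Nonzero coefficients from one shard's penalized fit."""

    transition: str
    shard_id: int
    selected: Mapping[str, float]
    lam: float
    K: int
    seed: int

    def __post_init__(self):
        if any(b == 0 for b in self.selected.values()):
            raise ValueError("ShardFitResult must store nonzero coefficients only")


def fit_penalized_cox_shard(
    rows: pd.DataFrame,
    K: int = 10,
    seed: int = 0,
    transition: str = "onset",
    shard_id: int = 0,
    feature_cols: Sequence[str] | None = None,
    **cv_kwargs,
) -> ShardFitResult:
    """Run the CV-lasso on one shard of person-period rows."""
    model = CountingProcessCox(rows, feature_cols=feature_cols, transition=transition)
    if model.n_events < 2:
        raise ValueError("shard has fewer than 2 events; fit refused")
    res = model.fit_cv(K=K, seed=seed, **cv_kwargs)
    for name, b in res.selected.items():
        if abs(b) > SEPARATION_ABS_COEF:
            logger.warning(
                "feature %s has |coef|=%.3g; possible separation", name, abs(b)
            )
    return ShardFitResult(
        transition=transition,
        shard_id=shard_id,
        selected=res.selected,
        lam=res.lam,
        K=K,
        seed=seed,
    )


def shard_persons(persons: Sequence, n_shards: int, seed: int = 0) -> list[np.ndarray]:
    """Randomly partition person ids into ``n_shards`` near-equal shards."""
    persons = np.asarray(persons)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(persons)
    return [np.sort(s) for s in np.array_split(perm, n_shards)]


def aggregate_shards(results: Sequence[ShardFitResult]) -> pd.DataFrame:
    """Selection counts and mean hazard ratio across shards.

    ``mean_HR`` is the arithmetic mean of ``exp(beta)`` over the shards that
    selected the feature (not ``exp(mean beta)``).
    """
    results = list(results)
    if not results:
        return pd.DataFrame(columns=["feature", "selection_count", "n_shards", "mean_HR"])
    transitions = {r.transition for r in results}
    if len(transitions) > 1:
        raise ValueError(f"results mix transitions: {sorted(transitions)}")
    n_shards = len(results)
    hrs: dict[str, list[float]] = {}
    for r in results:
        for name, beta in r.selected.items():
            hrs.setdefault(name, []).append(float(np.exp(beta)))
    rows = [
        {
            "feature": name,
            "selection_count": len(v),
            "n_shards": n_shards,
            "mean_HR": float(np.mean(v)),
        }
        for name, v in hrs.items()
    ]
    out = pd.DataFrame(rows).sort_values("feature", kind="mergesort")
    return out.reset_index(drop=True)


def prioritize_features(
    agg: pd.DataFrame, min_frequency: float, top_n: int
) -> pd.DataFrame:
    """Keep frequently-selected features, ranked by frequency then |ln HR|."""
    if not 0 < min_frequency <= 1:
        raise ValueError("min_frequency must be in (0, 1]")
    if agg.empty:
        return agg.head(0)
    freq = agg["selection_count"] / agg["n_shards"]
    kept = agg.loc[freq >= min_frequency].copy()
    kept["_freq"] = kept["selection_count"] / kept["n_shards"]
    kept["_mag"] = np.abs(np.log(kept["mean_HR"]))
    kept = kept.sort_values(
        ["_freq", "_mag", "feature"], ascending=[False, False, True], kind="mergesort"
    )
    return kept.drop(columns=["_freq", "_mag"]).head(top_n).reset_index(drop=True)


# ---------------------------------------------------------------------------
# summary-feature analysis with FDR
# ---------------------------------------------------------------------------


def fit_summary_cox_with_fdr(
    rows: pd.DataFrame,
    feature_cols: Sequence[str] | None = None,
    transition: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Unpenalized multivariable fit on a compact summary-feature set.

    Returns one row per feature: ``HR``, Wald 95% CI, ``p`` and the
    Benjamini–Hochberg ``q`` across the feature set, with a ``significant``
    flag at ``q < alpha``.  Non-convergence yields NA estimates (with a
    logged error) rather than silence.
    """
    model = CountingProcessCox(rows, feature_cols=feature_cols, transition=transition)
    names = model.feature_names
    try:
        res = model.fit()
    except ConvergenceError as exc:
        logger.error("summary Cox fit did not converge: %s", exc)
        return pd.DataFrame(
            {
                "feature": names,
                "HR": np.nan,
                "CI_low": np.nan,
                "CI_high": np.nan,
                "p": np.nan,
                "q": np.nan,
                "significant": False,
            }
        )
    for name, b in res.params.items():
        if abs(b) > SEPARATION_ABS_COEF:
            logger.warning(
                "feature %s has |coef|=%.3g; possible separation", name, abs(b)
            )
    table = res.summary(alpha=alpha).reset_index()
    _, q, _, _ = multipletests(table["p"], method="fdr_bh")
    table["q"] = q
    table["significant"] = table["q"] < alpha
    return table[
        ["feature", "HR", "CI_low", "CI_high", "p", "q", "significant"]
    ]
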