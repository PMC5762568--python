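"""Survival modeling: Cox regression, survival-forest importance, relevance.

A habitat is "relevant" when it passes a two-stage screen: (1) positive
out-of-bag permutation variable importance (VIMP) in a random survival forest
grown on the 16 habitat proportions, and (2) a Wald p-value below 0.05 for the
habitat's own coefficient in a Cox proportional-hazards model adjusted for the
clinical covariates (age, KPS, tumor volume, IDH1 status).  One Cox model is
fitted per important habitat: the habitat proportion plus the four covariates.

The Cox partial likelihood is maximized by Newton–Raphson with Breslow tie
handling; standard errors come from the inverse observed information.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.utils import check_random_state

from .types import CLINICAL_COVARIATES, N_HABITATS

HABITAT_COLUMNS = [f"p_{h}" for h in range(N_HABITATS)]


class ConvergenceError(RuntimeError):
    """Cox Newton–Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message}; log-likelihood trace: {trace}")
        self.trace = trace


def build_survival_frame(
    compositions: pd.DataFrame, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Join habitat proportions with survival outcome and covariates."""
    cols = ["os_months", "event", *CLINICAL_COVARIATES]
    df = compositions[HABITAT_COLUMNS].join(clinical[cols], how="inner")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in survival dataset column(s): {bad}")
    if int(df["event"].sum()) < 2:
        raise ValueError("survival dataset must contain at least 2 events")
    return df


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (Breslow ties, Newton–Raphson)."""

    params: pd.Series  # beta per predictor
    se: pd.Series
    z: pd.Series
    p: pd.Series
    loglik: float
    loglik_null: float
    n_iter: int
    n: int
    n_events: int


def _cox_quantities(beta, X, times_desc, events_desc, riskset_end):
    """Log partial likelihood, score and information (Breslow ties).

    Rows are sorted by descending time, so the risk set of an event at
    position i is the prefix 0..riskset_end[i]; prefix sums over exp(eta)
    give the Breslow denominators.
    """
    eta = X @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    S0 = np.cumsum(w)[riskset_end]
    S1 = np.cumsum(wx, axis=0)[riskset_end]
    S2 = np.cumsum(wxx, axis=0)[riskset_end]
    ev = events_desc.astype(bool)
    loglik = float(np.sum(eta[ev] - (np.log(S0[ev]) + shift)))
    mean = S1[ev] / S0[ev, None]
    score = X[ev].sum(axis=0) - mean.sum(axis=0)
    info = (
        np.sum(S2[ev] / S0[ev, None, None], axis=0)
        - mean.T @ mean
    )
    return loglik, score, info


def fit_cox(
    data: pd.DataFrame,
    predictors: list[str],
    duration_col: str = "os_months",
    event_col: str = "event",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Maximize the Cox partial likelihood (Breslow tie handling).

    Converges when the score's max-norm drops below ``tol``; raises
    :class:`ConvergenceError` with the iteration trace otherwise.
    """
    X = data[predictors].to_numpy(dtype=np.float64)
    times = data[duration_col].to_numpy(dtype=np.float64)
    events = data[event_col].to_numpy(dtype=np.int64)
    n, k = X.shape
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("cannot fit Cox model with zero events")
    if n_events < 2:
        raise ValueError("Cox model requires at least 2 events")
    sds = X.std(axis=0)
    constant = [p for p, s in zip(predictors, sds) if s == 0]
    if constant:
        raise ValueError(f"non-identifiable: constant predictor(s) {constant}")
    means = X.mean(axis=0)
    Xc = X - means  # centering leaves beta unchanged, stabilizes exp()

    order = np.argsort(-times, kind="stable")
    Xc, times_d, events_d = Xc[order], times[order], events[order]
    # last index sharing each row's time: risk set = {j : t_j >= t_i}
    riskset_end = np.searchsorted(-times_d, -times_d, side="right") - 1

    beta = np.zeros(k)
    loglik, score, info = _cox_quantities(beta, Xc, times_d, events_d, riskset_end)
    loglik_null = loglik
    trace = [loglik]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix at iteration {n_iter} "
                f"(collinear predictors?)", trace
            ) from exc
        # step-halving keeps the ascent property
        for _ in range(30):
            new_ll, new_score, new_info = _cox_quantities(
                beta + step, Xc, times_d, events_d, riskset_end
            )
            if new_ll >= loglik - 1e-12:
                break
            step = step / 2.0
        beta, loglik, score, info = beta + step, new_ll, new_score, new_info
        trace.append(loglik)
    else:
        raise ConvergenceError(
            f"Cox Newton–Raphson did not converge in {max_iter} iterations", trace
        )

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    from scipy import stats

    pvals = 2.0 * stats.norm.sf(np.abs(z))
    idx = pd.Index(predictors)
    return CoxFit(
        params=pd.Series(beta, idx),
        se=pd.Series(se, idx),
        z=pd.Series(z, idx),
        p=pd.Series(pvals, idx),
        loglik=loglik,
        loglik_null=loglik_null,
        n_iter=n_iter,
        n=n,
        n_events=n_events,
    )


@dataclass
class ImportanceTable:
    """Per-habitat OOB permutation variable importance from a survival forest."""

    table: pd.DataFrame  # index: feature name; column: vimp
    oob_error: float  # baseline OOB ensemble error (1 - Harrell's C)
    params: dict = field(default_factory=dict)


def _oob_mask(tree, n_samples: int) -> np.ndarray:
    """Out-of-bag mask for one tree, reconstructed from its bootstrap seed."""
    rs = check_random_state(tree.random_state)
    sampled = rs.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return mask


def _concordance_error(times, events, risk) -> float:
    from sksurv.metrics import concordance_index_censored

    c = concordance_index_censored(events.astype(bool), times, risk)[0]
    return 1.0 - c


def rsf_importance(
    data: pd.DataFrame,
    feature_cols: list[str] | None = None,
    duration_col: str = "os_months",
    event_col: str = "event",
    n_trees: int = 500,
    mtry: int | None = None,
    min_leaf: int = 3,
    seed: int = 0,
) -> ImportanceTable:
    """Grow a random survival forest and compute OOB permutation VIMP.

    VIMP of a feature is the increase in the out-of-bag ensemble prediction
    error (1 - Harrell's concordance of the OOB-averaged risk score) when that
    feature is permuted among each tree's out-of-bag samples.  Deterministic
    given ``seed``.
    """
    from sksurv.ensemble import RandomSurvivalForest
    from sksurv.util import Surv

    if feature_cols is None:
        feature_cols = HABITAT_COLUMNS
    X = data[feature_cols].to_numpy(dtype=np.float64)
    times = data[duration_col].to_numpy(dtype=np.float64)
    events = data[event_col].to_numpy(dtype=np.int64)
    n, p = X.shape
    if n < 20:
        raise ValueError("random survival forest needs >= 20 patients for OOB VIMP")
    if int(events.sum()) < min_leaf:
        raise ValueError(
            f"fewer events ({int(events.sum())}) than the terminal-node minimum ({min_leaf})"
        )
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))

    y = Surv.from_arrays(event=events.astype(bool), time=times)
    forest = RandomSurvivalForest(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_leaf,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)

    oob_masks = [_oob_mask(tree, n) for tree in forest.estimators_]
    base_sum = np.zeros(n)
    base_cnt = np.zeros(n)
    tree_oob_pred = []
    for tree, oob in zip(forest.estimators_, oob_masks):
        pred = tree.predict(X[oob])
        tree_oob_pred.append(pred)
        base_sum[oob] += pred
        base_cnt[oob] += 1
    covered = base_cnt > 0
    base_risk = np.zeros(n)
    base_risk[covered] = base_sum[covered] / base_cnt[covered]
    err0 = _concordance_error(times[covered], events[covered], base_risk[covered])

    rng = np.random.default_rng(seed)
    vimp = np.zeros(p)
    for j in range(p):
        perm_sum = np.zeros(n)
        for t_idx, (tree, oob) in enumerate(zip(forest.estimators_, oob_masks)):
            Xp = X[oob].copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm_sum[oob] += tree.predict(Xp)
        perm_risk = np.zeros(n)
        perm_risk[covered] = perm_sum[covered] / base_cnt[covered]
        errj = _concordance_error(times[covered], events[covered], perm_risk[covered])
        vimp[j] = errj - err0

    table = pd.DataFrame({"vimp": vimp}, index=pd.Index(feature_cols, name="feature"))
    return ImportanceTable(
        table=table,
        oob_error=err0,
        params={
            "n_trees": n_trees,
            "mtry": mtry,
            "min_leaf": min_leaf,
            "seed": seed,
            "n": n,
            "n_events": int(events.sum()),
        },
    )


def select_relevant(
    importance: ImportanceTable,
    cox_results: dict[int, CoxFit],
    alpha: float = 0.05,
) -> list[int]:
    """Habitats with positive VIMP AND adjusted-model Wald p < alpha.

    ``cox_results`` holds the per-habitat Cox fits for the important habitats
    (the second stage of the screen); an empty selection is a valid outcome.
    """
    selected = []
    for h in range(N_HABITATS):
        col = f"p_{h}"
        if col not in importance.table.index:
            continue
        if importance.table.loc[col, "vimp"] <= 0:
            continue
        fit = cox_results.get(h)
        if fit is None:
            continue
        if fit.p[col] < alpha:
            selected.append(h)
    return selected


@dataclass
class RelevanceResult:
    """Outcome of the two-stage relevance screen."""

    relevant: list[int]
    importance: ImportanceTable
    cox_fits: dict[int, CoxFit]
    skipped: dict[int, str]  # important habitats whose Cox fit failed, with reason


def relevant_habitats(
    data: pd.DataFrame,
    alpha: float = 0.05,
    n_trees: int = 500,
    mtry: int | None = None,
    min_leaf: int = 3,
    seed: int = 0,
) -> RelevanceResult:
    """Two-stage screen: RSF VIMP > 0, then covariate-adjusted Cox p < alpha.

    Cox models are fitted only for habitats with positive VIMP, each model
    containing that habitat's proportion plus the four clinical covariates.
    """
    importance = rsf_importance(
        data, HABITAT_COLUMNS, n_trees=n_trees, mtry=mtry, min_leaf=min_leaf, seed=seed
    )
    cox_fits: dict[int, CoxFit] = {}
    skipped: dict[int, str] = {}
    for h in range(N_HABITATS):
        col = f"p_{h}"
        if importance.table.loc[col, "vimp"] <= 0:
            continue
        try:
            cox_fits[h] = fit_cox(data, [col, *CLINICAL_COVARIATES])
        except (ValueError, ConvergenceError) as exc:
            skipped[h] = str(exc)
    relevant = select_relevant(importance, cox_fits, alpha=alpha)
    return RelevanceResult(
        relevant=relevant, importance=importance, cox_fits=cox_fits, skipped=skipped
    )
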