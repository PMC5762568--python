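"""Associating habitat compositions with tumor sub-volumes and pathway scores.

Sub-volume associations use Spearman rank correlation (midranks; p from the
t-approximation), uncorrected, mirroring the per-pair reporting of the
relevance analysis.  Pathway associations use two-part Dirichlet regression:
for one habitat h, the response is the composition (p_h, 1 - p_h) compressed
off the simplex boundary, and both Dirichlet concentration parameters depend
on the pathway score x through a log link,

    alpha_ic = exp(beta_c0 + beta_c1 * x_i),      c in {habitat, rest}.

The reported association coefficient is the mean-model contrast
``beta_habitat,1 - beta_rest,1``: the sign of dE[y_habitat]/dx equals the
sign of this contrast at every x (a single component's slope mixes mean and
precision effects and is not direction-identified in practice), and the
contrast equals the logit-mean slope of the equivalent Beta regression.  Its
sign gives the direction (up/down), its absolute value the strength used for
ranking.  Significance is Wald-based on the contrast, with Bonferroni
correction over the pathways tested per habitat.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    valid: bool
    reason: str = ""


def spearman_test(x: np.ndarray, y: np.ndarray) -> SpearmanResult:
    """Spearman rank correlation with midrank ties and t-approximation p.

    A constant input yields a flagged (``valid=False``) result instead of a
    crash; |rho| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("spearman_test requires n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(np.nan, np.nan, False, "constant input vector")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if abs(rho) >= 1.0 - 1e-12:
        return SpearmanResult(float(np.sign(rho)), 0.0, True)
    return SpearmanResult(rho, float(res.pvalue), True)


def boundary_transform(y: np.ndarray, n: int, n_components: int = 2) -> np.ndarray:
    """Compress proportions off the simplex boundary: y* = (y(n-1) + 1/C)/n.

    Order-preserving, maps [0, 1] into (0, 1), and leaves 0.5 fixed for the
    two-part case. Applied unconditionally before Dirichlet regression since
    the Dirichlet density is degenerate at observed 0/1 proportions.
    """
    if n < 2:
        raise ValueError("boundary transform requires cohort size n >= 2")
    y = np.asarray(y, dtype=np.float64)
    return (y * (n - 1) + 1.0 / n_components) / n


def _nll_and_grad(theta: np.ndarray, x: np.ndarray, ly1: np.ndarray, ly2: np.ndarray):
    with np.errstate(over="ignore", invalid="ignore"):
        a = np.exp(theta[0] + theta[1] * x)
        b = np.exp(theta[2] + theta[3] * x)
        s = a + b
        ll = (
            special.gammaln(s)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * ly1
            + (b - 1.0) * ly2
        )
        nll = -ll.sum()
        if not np.isfinite(nll):  # overflowed excursion: reject the step
            return np.inf, np.zeros(4)
        ds = special.digamma(s)
        ga = (ds - special.digamma(a) + ly1) * a
        gb = (ds - special.digamma(b) + ly2) * b
        grad = -np.array([ga.sum(), (ga * x).sum(), gb.sum(), (gb * x).sum()])
    return float(nll), grad


def _observed_information(theta: np.ndarray, x: np.ndarray, ly1, ly2) -> np.ndarray:
    """Analytic observed information (negative Hessian of the log-likelihood)."""
    a = np.exp(theta[0] + theta[1] * x)
    b = np.exp(theta[2] + theta[3] * x)
    s = a + b
    ts = special.polygamma(1, s)
    ga_lin = special.digamma(s) - special.digamma(a) + ly1  # dLL/d alpha1
    gb_lin = special.digamma(s) - special.digamma(b) + ly2
    # second derivatives wrt the linear predictors u1 = log a, u2 = log b
    d11 = (ts - special.polygamma(1, a)) * a * a + ga_lin * a
    d22 = (ts - special.polygamma(1, b)) * b * b + gb_lin * b
    d12 = ts * a * b
    H = np.empty((4, 4))
    z = [np.ones_like(x), x]
    for p in range(2):
        for q in range(2):
            H[p, q] = np.sum(d11 * z[p] * z[q])
            H[2 + p, 2 + q] = np.sum(d22 * z[p] * z[q])
            H[p, 2 + q] = np.sum(d12 * z[p] * z[q])
            H[2 + q, p] = H[p, 2 + q]
    return -H


@dataclass
class DirichletFit:
    """Two-part Dirichlet regression fit for one (habitat, covariate) pair."""

    beta: np.ndarray  # (b_h0, b_h1, b_r0, b_r1)
    se: np.ndarray
    coefficient: float  # mean-model contrast b_h1 - b_r1
    wald_z: float
    wald_p: float
    loglik: float
    start_logliks: list[float]  # log-likelihood at each starting point
    converged: bool
    message: str = ""


def _moment_start(y1: np.ndarray) -> np.ndarray:
    """Method-of-moments Beta intercepts (slopes zero)."""
    m, v = float(y1.mean()), float(y1.var())
    v = max(v, 1e-6)
    common = max(m * (1.0 - m) / v - 1.0, 1e-3)
    a0 = max(m * common, 1e-3)
    b0 = max((1.0 - m) * common, 1e-3)
    return np.array([np.log(a0), 0.0, np.log(b0), 0.0])


def fit_dirichlet_regression(
    y1: np.ndarray,
    x: np.ndarray,
    grad_tol: float = 1e-6,
    max_iter: int = 500,
) -> DirichletFit:
    """MLE of the two-part Dirichlet regression via quasi-Newton ascent.

    ``y1`` are interior habitat proportions (already boundary-compressed);
    the second component is ``1 - y1``.  Three deterministic starts (zeros,
    method-of-moments intercepts, perturbed moments) are run and the best
    final likelihood wins; convergence requires gradient max-norm below
    ``grad_tol`` at the winner.
    """
    y1 = np.asarray(y1, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if y1.size != x.size:
        raise ValueError("y and x must have equal length")
    if y1.size < 10:
        raise ValueError("Dirichlet regression requires n >= 10")
    if np.any((y1 <= 0) | (y1 >= 1)):
        raise ValueError("proportions must be strictly inside (0, 1); apply boundary_transform")
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")
    ly1, ly2 = np.log(y1), np.log1p(-y1)

    mom = _moment_start(y1)
    starts = [
        np.zeros(4),
        mom,
        mom + np.array([0.3, 0.2, -0.3, -0.2]),
    ]
    start_lls, results = [], []
    for theta0 in starts:
        start_lls.append(-_nll_and_grad(theta0, x, ly1, ly2)[0])
        res = optimize.minimize(
            _nll_and_grad,
            theta0,
            args=(x, ly1, ly2),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": grad_tol * 1e-2},
        )
        results.append(res)
    best = min(results, key=lambda r: r.fun)
    theta = best.x
    nll, grad = _nll_and_grad(theta, x, ly1, ly2)
    # Newton polish with the analytic information to reach the gradient
    # tolerance L-BFGS's ftol stop can leave unmet
    for _ in range(25):
        if np.max(np.abs(grad)) < grad_tol:
            break
        info = _observed_information(theta, x, ly1, ly2)
        try:
            step = np.linalg.solve(info, -grad)
        except np.linalg.LinAlgError:
            break
        new_theta = theta + step
        new_nll, new_grad = _nll_and_grad(new_theta, x, ly1, ly2)
        halvings = 0
        while not np.isfinite(new_nll) or new_nll > nll + 1e-10:
            step /= 2.0
            new_theta = theta + step
            new_nll, new_grad = _nll_and_grad(new_theta, x, ly1, ly2)
            halvings += 1
            if halvings > 30:
                break
        if halvings > 30:
            break
        theta, nll, grad = new_theta, new_nll, new_grad
    converged = bool(np.max(np.abs(grad)) < grad_tol)
    loglik = -float(nll)

    coefficient = float(theta[1] - theta[3])
    se = np.full(4, np.nan)
    wald_z = wald_p = np.nan
    if converged:
        info = _observed_information(theta, x, ly1, ly2)
        try:
            cov = np.linalg.inv(info)
            diag = np.diag(cov)
            contrast_var = cov[1, 1] + cov[3, 3] - 2.0 * cov[1, 3]
            if np.all(diag > 0) and contrast_var > 0:
                se = np.sqrt(diag)
                wald_z = coefficient / np.sqrt(contrast_var)
                wald_p = 2.0 * stats.norm.sf(abs(wald_z))
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
    return DirichletFit(
        beta=theta,
        se=se,
        coefficient=coefficient,
        wald_z=float(wald_z),
        wald_p=float(wald_p),
        loglik=loglik,
        start_logliks=start_lls,
        converged=converged,
        message="" if converged else "optimizer did not reach gradient tolerance",
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * m)."""
    return min(1.0, p * m)


def rank_by_magnitude(table: pd.DataFrame) -> pd.DataFrame:
    """Rank associations within each direction by |coefficient|, descending.

    Adds ``rank`` (1-based within direction) and ``top5`` columns; rows with
    missing coefficients are left unranked.
    """
    table = table.copy()
    table["rank"] = np.nan
    for direction in ("up", "down"):
        mask = (table["direction"] == direction) & table["coefficient"].notna()
        order = table.loc[mask, "coefficient"].abs().sort_values(ascending=False)
        table.loc[order.index, "rank"] = np.arange(1, mask.sum() + 1)
    table["top5"] = table["rank"] <= 5
    return table


def pathway_screen(
    p_h: pd.Series,
    scores: pd.DataFrame,
    alpha: float = 0.05,
    top_k: int = 5,
) -> pd.DataFrame:
    """Dirichlet-regression screen of one habitat against all pathways.

    Fits one two-part Dirichlet regression per pathway column, Bonferroni-
    adjusts the Wald p over the number of pathways tested, splits results by
    slope sign and ranks by |coefficient| within each direction.  Fits that
    fail to converge are excluded from ranking with a logged reason.
    """
    ids = p_h.index.intersection(scores.index)
    if len(ids) < 10:
        raise ValueError("pathway screen requires >= 10 complete patients")
    y1 = boundary_transform(p_h.loc[ids].to_numpy(), n=len(ids))
    m = scores.shape[1]
    rows = []
    for pathway in scores.columns:
        x = scores.loc[ids, pathway].to_numpy(dtype=np.float64)
        try:
            fit = fit_dirichlet_regression(y1, x)
        except ValueError as exc:
            rows.append(
                {
                    "pathway": pathway,
                    "coefficient": np.nan,
                    "raw_p": np.nan,
                    "bonferroni_p": np.nan,
                    "direction": "none",
                    "converged": False,
                    "note": str(exc),
                }
            )
            continue
        if not fit.converged:
            rows.append(
                {
                    "pathway": pathway,
                    "coefficient": np.nan,
                    "raw_p": np.nan,
                    "bonferroni_p": np.nan,
                    "direction": "none",
                    "converged": False,
                    "note": fit.message,
                }
            )
            continue
        rows.append(
            {
                "pathway": pathway,
                "coefficient": fit.coefficient,
                "raw_p": fit.wald_p,
                "bonferroni_p": bonferroni(fit.wald_p, m),
                "direction": "up" if fit.coefficient > 0 else "down",
                "converged": True,
                "note": "",
            }
        )
    table = rank_by_magnitude(pd.DataFrame(rows))
    table["significant"] = table["bonferroni_p"] < alpha
    if top_k != 5:
        table["top5"] = table["rank"] <= top_k
    table = table.sort_values(
        ["direction", "rank"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return table


def subvolume_screen(
    compositions: pd.DataFrame,
    subvolumes: pd.DataFrame,
    habitats: list[int],
) -> pd.DataFrame:
    """Spearman rho and raw p for each (relevant habitat, sub-volume) pair."""
    ids = compositions.index.intersection(subvolumes.index)
    rows = []
    for h in habitats:
        p_h = compositions.loc[ids, f"p_{h}"].to_numpy()
        for name in subvolumes.columns:
            res = spearman_test(p_h, subvolumes.loc[ids, name].to_numpy())
            rows.append(
                {
                    "habitat": h,
                    "subvolume": name,
                    "rho": res.rho,
                    "p": res.p,
                    "valid": res.valid,
                    "note": res.reason,
                }
            )
    return pd.DataFrame(rows)
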