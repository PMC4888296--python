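"""Loess screening and Gaussian additive models (GAMs) for species responses.

Two tools used to evaluate how adjusted bird counts relate to the landscape
predictors:

* :func:`loess_fit` — locally weighted polynomial regression (tricube
  weights, default degree 2) with a nonlinearity report comparing the local
  fit against the ordinary linear regression via an approximate F statistic;
* :class:`AdditiveModel` — an additive model with Gaussian errors and an
  identity link: penalized cubic B-spline smooths for continuous predictors
  (basis dimension 10 per term, curvature penalty), survey year as an
  unpenalized factor, smoothing parameters chosen by minimising the
  generalized cross-validation (GCV) score.  The fit reports per-smooth
  effective degrees of freedom (edf), approximate Wald-type term p-values,
  deviance explained, GCV and an AIC based on the effective degrees of
  freedom of the penalized fit — the quantities used for multi-model
  comparison.  Smooth-term p-values are approximate (penalized Wald).

:func:`backward_select` performs stepwise backward AIC selection over the
model terms and reports the full and the best-fitted model with their
delta-AIC, mirroring the structure of a GAM comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.gam.smooth_basis import BSplines


# --------------------------------------------------------------------- loess
def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> dict:
    """Locally weighted polynomial regression with a nonlinearity report.

    At each observed ``x_i`` a weighted polynomial of the given degree is
    fitted to the ``ceil(span * n)`` nearest points with tricube weights.
    The report compares the loess residual sum of squares against an
    ordinary linear fit through an approximate F statistic with the loess
    operator trace as model degrees of freedom.

    Returns a dict with ``fitted``, ``enp`` (equivalent number of
    parameters), ``rss``, ``linear_rss``, ``F`` and ``p``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 points")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise ValueError(
            f"span {span} gives neighbourhoods of {k} points; "
            f"need at least {degree + 2} for degree {degree}"
        )

    L = np.zeros((n, n))
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        if h == 0:
            w = np.ones(idx.size)
        else:
            w = (1 - np.minimum(d[idx] / h, 1) ** 3) ** 3
        # local design centred on x_i for numerical stability
        t = x[idx] - x[i]
        X = np.vander(t, degree + 1, increasing=True)
        WX = X * w[:, None]
        beta_op = np.linalg.pinv(X.T @ WX) @ WX.T  # maps y[idx] -> local coef
        L[i, idx] = beta_op[0]  # prediction at t=0 is the constant term
    fitted = L @ y
    resid = y - fitted
    rss = float(resid @ resid)
    enp = float(np.trace(L))

    # ordinary linear fit for the comparison
    Xl = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(Xl, y, rcond=None)
    lin_resid = y - Xl @ beta
    lin_rss = float(lin_resid @ lin_resid)

    df1 = max(enp - 2.0, 1e-8)
    df2 = max(n - enp, 1.0)
    if rss <= 1e-12 * max(lin_rss, 1.0):
        F = 0.0 if lin_rss <= 1e-12 else np.inf
    else:
        F = max(lin_rss - rss, 0.0) / df1 / (rss / df2)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return {
        "fitted": fitted,
        "enp": enp,
        "rss": rss,
        "linear_rss": lin_rss,
        "F": float(F),
        "p": p,
    }


# ----------------------------------------------------------------------- GAM
@dataclass
class _Term:
    name: str
    kind: str  # "smooth", "factor" or "intercept"
    cols: slice = field(default=None)
    penalty: np.ndarray | None = None
    shrink_penalty: np.ndarray | None = None


class AdditiveModel:
    """Gaussian-identity additive model with GCV-selected smoothing.

    Parameters
    ----------
    data : DataFrame
        Must contain the response, the smooth terms, and the factor terms;
        rows with missing values in any used column are dropped before the
        fit (none may remain missing).
    response : str
        Column with the (adjusted-count) response.
    smooth_terms : sequence of str
        Continuous predictors, each entering as a penalized cubic B-spline
        smooth with basis dimension 10.
    factor_terms : sequence of str
        Categorical predictors entered as unpenalized dummy factors (the
        survey year in this analysis; a smooth does not apply).

    Examples
    --------
    >>> gam = AdditiveModel(df, "adjusted_count",
    ...                     ["pct_forest", "compactness"], ["year"])
    >>> res = gam.fit()
    >>> res.summary()
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        smooth_terms: tuple[str, ...],
        factor_terms: tuple[str, ...] = (),
        basis_df: int = 10,
        degree: int = 3,
        gcv_gamma: float = 1.4,
    ) -> None:
        smooth_terms = tuple(smooth_terms)
        factor_terms = tuple(factor_terms)
        if len(set(smooth_terms)) != len(smooth_terms):
            dupes = [t for t in smooth_terms if smooth_terms.count(t) > 1]
            raise ValueError(f"duplicate predictor terms: {sorted(set(dupes))}")
        used = [response, *smooth_terms, *factor_terms]
        df = pd.DataFrame(data)[used].dropna().reset_index(drop=True)
        n = len(df)
        n_terms = len(smooth_terms) + len(factor_terms)
        if n < 10 * max(n_terms, 1):
            raise ValueError(
                f"{n} rows is too few for {n_terms} terms (need >= 10 per term)"
            )
        # collinear smooth terms produce a rank-deficient design; name them
        for i, a in enumerate(smooth_terms):
            for b in smooth_terms[i + 1 :]:
                xa, xb = df[a].to_numpy(float), df[b].to_numpy(float)
                if np.std(xa) == 0 or np.std(xb) == 0:
                    continue
                if abs(np.corrcoef(xa, xb)[0, 1]) > 1 - 1e-10:
                    raise ValueError(f"collinear terms: {a!r} and {b!r}")

        self.data = df
        self.gcv_gamma = gcv_gamma
        self.response = response
        self.smooth_terms = smooth_terms
        self.factor_terms = factor_terms
        self.y = df[response].to_numpy(dtype=float)

        blocks = [np.ones((n, 1))]
        terms: list[_Term] = [_Term("intercept", "intercept", slice(0, 1))]
        pos = 1
        for name in factor_terms:
            dummies = pd.get_dummies(df[name], drop_first=True).to_numpy(float)
            blocks.append(dummies)
            terms.append(_Term(name, "factor", slice(pos, pos + dummies.shape[1])))
            pos += dummies.shape[1]
        self._bsplines = None
        if smooth_terms:
            xs = df[list(smooth_terms)].to_numpy(dtype=float)
            # discrete predictors (few distinct values) get a smaller basis:
            # a df-k spline on u distinct values is rank-deficient for k > u
            dfs, degs = [], []
            for name in smooth_terms:
                u = df[name].nunique()
                if u < 4:
                    raise ValueError(
                        f"smooth term {name!r} has only {u} distinct values"
                    )
                d_j = int(min(basis_df, u - 1))
                dfs.append(d_j)
                degs.append(int(min(degree, d_j - 1)))
            self._bsplines = BSplines(
                xs,
                df=dfs,
                degree=degs,
                constraints="center",
            )
            for j, name in enumerate(smooth_terms):
                sm = self._bsplines.smoothers[j]
                blocks.append(sm.basis)
                # shrinkage ("double penalty") companion: the curvature
                # penalty leaves its null space (linear trends) unpenalized,
                # so a second penalty on that null space, with its own
                # GCV-chosen weight, lets uninformative smooths shrink to
                # zero effective degrees of freedom
                evals, evecs = np.linalg.eigh(sm.cov_der2)
                null = evecs[:, evals < 1e-10 * max(evals.max(), 1.0)]
                terms.append(
                    _Term(
                        name,
                        "smooth",
                        slice(pos, pos + sm.dim_basis),
                        sm.cov_der2,
                        null @ null.T,
                    )
                )
                pos += sm.dim_basis
        self.X = np.concatenate(blocks, axis=1)
        self.terms = terms
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("rank-deficient design matrix")

    # ------------------------------------------------------------------ fit
    def _penalty(self, log_alpha: np.ndarray) -> np.ndarray:
        # two penalties per smooth: curvature and null-space shrinkage;
        # log-alphas clipped to keep exp() finite under free-ranging optimizers
        log_alpha = np.clip(log_alpha, -20.0, 25.0)
        p = self.X.shape[1]
        S = np.zeros((p, p))
        k = 0
        for t in self.terms:
            if t.kind == "smooth":
                S[t.cols, t.cols] += np.exp(log_alpha[k]) * t.penalty
                S[t.cols, t.cols] += np.exp(log_alpha[k + 1]) * t.shrink_penalty
                k += 2
        return S

    def _solve(self, log_alpha: np.ndarray):
        X, y = self.X, self.y
        n = len(y)
        XtX = X.T @ X
        A = XtX + self._penalty(log_alpha)
        try:
            c, low = linalg.cho_factor(A)
        except (linalg.LinAlgError, ValueError):
            return None
        beta = linalg.cho_solve((c, low), X.T @ y)
        Ainv_XtX = linalg.cho_solve((c, low), XtX)
        edf_diag = np.diag(Ainv_XtX)
        edf = float(edf_diag.sum())
        resid = y - X @ beta
        rss = float(resid @ resid)
        # gamma = 1.4 inflates the edf cost in GCV, the standard guard
        # against its tendency to undersmooth at finite n
        gcv = (
            n * rss / (n - self.gcv_gamma * edf) ** 2
            if n > self.gcv_gamma * edf
            else np.inf
        )
        return beta, rss, edf, edf_diag, gcv, (c, low)

    def fit(self, maxiter: int = 400) -> "AdditiveModelResults":
        """Minimise GCV over the per-smooth log smoothing parameters."""
        k = sum(1 for t in self.terms if t.kind == "smooth")
        if k == 0:
            sol = self._solve(np.zeros(0))
            return AdditiveModelResults(self, np.zeros(0), sol, converged=True)

        def objective(la):
            sol = self._solve(la)
            return 1e12 if sol is None else sol[4]

        best = None
        starts = (
            np.tile([0.0, -4.0], k),
            np.tile([4.0, 0.0], k),
            np.tile([8.0, 2.0], k),
            np.tile([14.0, 8.0], k),
        )
        for start in starts:
            res = optimize.minimize(
                objective,
                start,
                method="Powell",
                options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        sol = self._solve(best.x)
        converged = bool(best.success and sol is not None and np.isfinite(best.fun))
        if sol is None:
            raise np.linalg.LinAlgError("penalized normal equations not SPD")
        return AdditiveModelResults(self, best.x, sol, converged=converged)


class AdditiveModelResults:
    """Penalized additive-model fit: edf, p-values, GCV, AIC, deviance."""

    def __init__(self, model: AdditiveModel, log_alpha, sol, converged: bool):
        self.model = model
        self.log_alpha = np.asarray(log_alpha)
        beta, rss, edf, edf_diag, gcv, chol = sol
        self.params = beta
        self.rss = rss
        self.edf_total = edf
        self._edf_diag = edf_diag
        self.gcv = gcv
        self.converged = converged
        n = len(model.y)
        self.nobs = n
        self.scale = rss / max(n - edf, 1.0)  # sigma^2 estimate
        # Bayesian posterior covariance of the penalized coefficients
        p = model.X.shape[1]
        self._cov = linalg.cho_solve(chol, np.eye(p)) * self.scale
        self.fittedvalues = model.X @ beta
        tss = float(((model.y - model.y.mean()) ** 2).sum())
        self.deviance_explained = 100.0 * (1.0 - rss / tss) if tss > 0 else np.nan
        # AIC from the effective degrees of freedom of the penalized fit
        # (+1 for the scale parameter)
        self.aic = n * np.log(rss / n) + n * (1 + np.log(2 * np.pi)) + 2 * (edf + 1)

    def edf(self, term: str) -> float:
        """Effective degrees of freedom attributed to one term."""
        for t in self.model.terms:
            if t.name == term and t.kind != "intercept":
                return float(self._edf_diag[t.cols].sum())
        raise KeyError(term)

    def pvalue(self, term: str) -> float:
        """Approximate Wald-type p-value for a term (chi-square with edf df)."""
        for t in self.model.terms:
            if t.name == term and t.kind != "intercept":
                dof = self.edf(term)
                if t.kind == "smooth" and dof < 0.01:
                    return 1.0  # term penalized away entirely: no evidence
                b = self.params[t.cols]
                V = self._cov[t.cols, t.cols]
                stat = float(b @ np.linalg.pinv(V, rcond=1e-10) @ b)
                return float(stats.chi2.sf(stat, max(dof, 0.01)))
        raise KeyError(term)

    def summary(self) -> pd.DataFrame:
        """Per-term edf and approximate p-value, plus fit statistics."""
        rows = []
        for t in self.model.terms:
            if t.kind == "intercept":
                continue
            rows.append(
                {
                    "term": t.name,
                    "type": t.kind,
                    "edf": self.edf(t.name),
                    "p": self.pvalue(t.name),
                }
            )
        out = pd.DataFrame(rows)
        out.attrs["deviance_explained"] = self.deviance_explained
        out.attrs["gcv"] = self.gcv
        out.attrs["aic"] = self.aic
        out.attrs["converged"] = self.converged
        return out


def backward_select(
    data: pd.DataFrame,
    response: str,
    smooth_terms: tuple[str, ...],
    factor_terms: tuple[str, ...] = (),
    key_p: float = 0.01,
    parsimony: float = 2.0,
    alpha_remove: float | None = 0.05,
) -> dict:
    """Stepwise backward selection over additive-model terms.

    Classical backward elimination with AIC ranking: at each step the least
    significant term is dropped while its approximate p-value exceeds
    ``alpha_remove`` (default 0.05); when every remaining term is
    significant, a term is still dropped if that lowers AIC under the usual
    model-equivalence convention (models within ``parsimony`` AIC units,
    default 2, are indistinguishable and the more parsimonious one is
    preferred).  ``alpha_remove=None`` with ``parsimony=0`` gives strict
    AIC-descent-only selection.  Returns a dict with
    the fitted ``full`` and ``best`` results, the selection ``path`` and a
    Table-style comparison ``table`` (per-term edf and p for both models,
    deviance explained, GCV, delta-AIC relative to the best model, and
    significance flags at p < ``key_p``).
    """
    smooth_terms = tuple(smooth_terms)
    factor_terms = tuple(factor_terms)

    def fit_terms(sm, fa):
        return AdditiveModel(data, response, sm, fa).fit()

    full = fit_terms(smooth_terms, factor_terms)
    cur_sm, cur_fa = list(smooth_terms), list(factor_terms)
    cur = full
    path = [(tuple(cur_sm), tuple(cur_fa), full.aic)]
    while cur_sm or cur_fa:
        if len(cur_sm) + len(cur_fa) > 1 and alpha_remove is not None:
            # classical elimination: weakest non-significant term goes first
            pvals = {
                (t, kind): cur.pvalue(t)
                for t, kind in [(t, "smooth") for t in cur_sm]
                + [(t, "factor") for t in cur_fa]
            }
            (worst, kind), p_worst = max(pvals.items(), key=lambda kv: kv[1])
            if p_worst > alpha_remove:
                if kind == "smooth":
                    cur_sm.remove(worst)
                else:
                    cur_fa.remove(worst)
                cur = fit_terms(tuple(cur_sm), tuple(cur_fa))
                path.append((tuple(cur_sm), tuple(cur_fa), cur.aic))
                continue
        candidates = []
        for t in cur_sm:
            sm = tuple(x for x in cur_sm if x != t)
            if not sm and not cur_fa:
                continue
            try:
                candidates.append((fit_terms(sm, tuple(cur_fa)), t, "smooth"))
            except ValueError:
                continue
        for t in cur_fa:
            fa = tuple(x for x in cur_fa if x != t)
            if not cur_sm and not fa:
                continue
            try:
                candidates.append((fit_terms(tuple(cur_sm), fa), t, "factor"))
            except ValueError:
                continue
        if not candidates:
            break
        cand = min(candidates, key=lambda c: c[0].aic)
        if cand[0].aic >= cur.aic + parsimony and parsimony > 0:
            break
        if parsimony == 0 and cand[0].aic >= cur.aic:
            break
        cur = cand[0]
        if cand[2] == "smooth":
            cur_sm.remove(cand[1])
        else:
            cur_fa.remove(cand[1])
        path.append((tuple(cur_sm), tuple(cur_fa), cur.aic))

    best = cur
    rows = []
    for label, res in (("full", full), ("best", best)):
        for t in res.model.terms:
            if t.kind == "intercept":
                continue
            p = res.pvalue(t.name)
            rows.append(
                {
                    "model": label,
                    "term": t.name,
                    "type": t.kind,
                    "edf": res.edf(t.name),
                    "p": p,
                    "key_factor": bool(p < key_p),
                    "deviance_explained_pct": res.deviance_explained,
                    "gcv": res.gcv,
                    "aic": res.aic,
                    "delta_aic": res.aic - best.aic,
                    "converged": res.converged,
                }
            )
    return {"full": full, "best": best, "path": path, "table": pd.DataFrame(rows)}
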