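"""Two-level longitudinal models of scroll behaviour and accuracy.

Study design: DRPT occasions (level 1) are nested within residents
(level 2).  For the scroll outcomes (``PercTimeFullRunsAvg``,
``PercTimeRelAreaAvg``) a ladder of linear mixed models is fitted by full
maximum likelihood:

* Model 0 — unconditional means (random resident intercept only),
* Model 1 — + fixed TrTime,
* Model 2 — + fixed DRPTdiff,
* Model 3 — + random TrTime slope (unstructured 2x2 covariance).

Fixed-effect standard errors are cluster-robust (sandwich) at the resident
level, guarding against mild non-normality of level-1 residuals.  Nested
models are compared by likelihood-ratio tests on the full-ML deviance; the
effect size is the level-1 explained variance relative to the unconditional
means model, (sigma2_e_null - sigma2_e_fit) / sigma2_e_null.

For diagnostic accuracy the outcome is n_correct of n_questions per
occasion, modelled as a binomial logit GLMM with a resident-level random
intercept, estimated by full ML with adaptive Gauss-Hermite quadrature
(20 nodes by default).  The ladder adds TrTime, then DRPTdiff and the two
scroll averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .records import DRPTRecord, ValidationError, UndefinedMetricError

OUTCOME_ALIASES = {
    "PercTimeFullRunsAvg": "perc_time_full_runs_avg",
    "PercTimeRelAreaAvg": "perc_time_rel_area_avg",
    "fullruns": "perc_time_full_runs_avg",
    "relarea": "perc_time_rel_area_avg",
}


@dataclass(frozen=True)
class FixedEffect:
    name: str
    b: float
    se: float
    p: float
    or_: float | None = None  # exp(b); logistic models only
    ci: tuple[float, float] | None = None  # 95% CI for the odds ratio


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_e: float | None  # level-1 residual variance (binomial: fixed, None)
    sigma2_u0: float  # resident random-intercept variance
    sigma2_u1: float | None = None  # random TrTime-slope variance
    cov_u01: float | None = None


@dataclass(frozen=True)
class ModelFit:
    name: str
    kind: str  # "linear" | "logistic"
    fixed: tuple[FixedEffect, ...]
    var: VarianceComponents
    deviance: float
    n_params: int
    n_obs: int
    n_groups: int
    converged: bool
    r2_level1: float | None = None

    def effect(self, predictor: str) -> FixedEffect:
        for fe in self.fixed:
            if fe.name == predictor:
                return fe
        raise KeyError(f"predictor {predictor!r} not in model {self.name!r}")


def records_to_frame(records: Iterable[DRPTRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    df = pd.DataFrame(
        {
            "resident_id": [r.resident_id for r in records],
            "drpt_id": [r.drpt_id for r in records],
            "tr_time": [r.tr_time for r in records],
            "drpt_diff": [r.drpt_diff for r in records],
            "perc_time_full_runs_avg": [r.perc_time_full_runs_avg for r in records],
            "perc_time_rel_area_avg": [r.perc_time_rel_area_avg for r in records],
            "n_correct": [r.n_correct for r in records],
            "n_questions": [r.n_questions for r in records],
        }
    )
    return df


# ---------------------------------------------------------------------------
# linear mixed models (statsmodels MixedLM, full ML) + cluster-robust SEs
# ---------------------------------------------------------------------------


def _cluster_robust_cov(result) -> np.ndarray:
    """Resident-clustered sandwich covariance of the fixed effects.

    With beta_hat = A^{-1} sum_j X_j' V_j^{-1} y_j and A = sum_j X_j' V_j^{-1} X_j,
    the sandwich is A^{-1} (sum_j s_j s_j') A^{-1} with
    s_j = X_j' V_j^{-1} (y_j - X_j beta_hat) and V_j the fitted marginal
    covariance of cluster j.
    """
    model = result.model
    beta = result.fe_params.to_numpy()
    scale = result.scale
    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    k = len(beta)
    A = np.zeros((k, k))
    B = np.zeros((k, k))
    for g in np.unique(model.group_labels):
        idx = np.flatnonzero(np.asarray(model.groups) == g)
        X = model.exog[idx]
        y = model.endog[idx]
        Z = model.exog_re[idx] if model.exog_re is not None else np.ones((len(idx), 1))
        V = Z @ cov_re @ Z.T + scale * np.eye(len(idx))
        Vi = np.linalg.inv(V)
        XtVi = X.T @ Vi
        A += XtVi @ X
        s = XtVi @ (y - X @ beta)
        B += np.outer(s, s)
    Ainv = np.linalg.inv(A)
    return Ainv @ B @ Ainv


def _lmm_fit_to_modelfit(result, name: str, robust: bool = True) -> ModelFit:
    beta = result.fe_params
    if robust:
        cov = _cluster_robust_cov(result)
        ses = np.sqrt(np.diag(cov))
    else:
        ses = result.bse_fe.to_numpy()
    fixed = []
    for j, pname in enumerate(beta.index):
        b = float(beta.iloc[j])
        se = float(ses[j])
        z = b / se if se > 0 else np.inf
        fixed.append(
            FixedEffect(name=pname, b=b, se=se, p=float(2 * stats.norm.sf(abs(z))))
        )
    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    sigma2_u1 = float(cov_re[1, 1]) if cov_re.shape[0] > 1 else None
    cov_u01 = float(cov_re[0, 1]) if cov_re.shape[0] > 1 else None
    n_vc = 1 + (3 if cov_re.shape[0] > 1 else 1)  # scale + re-cov entries
    return ModelFit(
        name=name,
        kind="linear",
        fixed=tuple(fixed),
        var=VarianceComponents(
            sigma2_e=float(result.scale),
            sigma2_u0=float(cov_re[0, 0]),
            sigma2_u1=sigma2_u1,
            cov_u01=cov_u01,
        ),
        deviance=float(-2.0 * result.llf),
        n_params=len(beta) + n_vc,
        n_obs=int(result.model.exog.shape[0]),
        n_groups=len(result.model.group_labels),
        converged=bool(result.converged),
    )


def _fit_mixedlm(model):
    """Full-ML fit with an optimizer fallback.

    Powell handles the boundary region (random-intercept variance near
    zero) dependably; BFGS is the backstop.  The better log-likelihood wins.
    """
    best = None
    for method in ("powell", "bfgs"):
        try:
            result = model.fit(reml=False, method=method, maxiter=2000)
        except Exception:
            continue
        if np.isfinite(result.llf) and (best is None or result.llf > best.llf + 1e-6):
            best = result
        if best is not None and best.converged:
            break
    if best is None:
        raise ValidationError("mixed model failed to fit with every optimizer")
    return best


def fit_lmm_ladder(
    records: Iterable[DRPTRecord] | pd.DataFrame,
    outcome: str,
    robust: bool = True,
    max_model: int = 3,
) -> list[ModelFit]:
    """Fit the Model 0..``max_model`` linear ladder by full ML.

    ``outcome`` may be a column name or one of the conventional labels
    (``PercTimeFullRunsAvg`` / ``PercTimeRelAreaAvg``).  Non-convergence of
    a rung flags that fit and the ladder continues.
    """
    import statsmodels.formula.api as smf

    df = records_to_frame(records)
    outcome = OUTCOME_ALIASES.get(outcome, outcome)
    if outcome not in df.columns:
        raise ValidationError(f"unknown outcome {outcome!r}")
    if df["resident_id"].nunique() < 2 or len(df) < 2:
        raise ValidationError("need records for at least two residents")
    df = df.rename(columns={outcome: "_y"})
    specs = [
        ("Model 0", "_y ~ 1", None),
        ("Model 1", "_y ~ tr_time", None),
        ("Model 2", "_y ~ tr_time + drpt_diff", None),
        ("Model 3", "_y ~ tr_time + drpt_diff", "~tr_time"),
    ]
    fits: list[ModelFit] = []
    null_sigma2_e: float | None = None
    for name, formula, re_formula in specs[: max_model + 1]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    formula, df, groups=df["resident_id"], re_formula=re_formula
                )
                result = _fit_mixedlm(model)
            fit = _lmm_fit_to_modelfit(result, name, robust=robust)
        except Exception as exc:  # singular fits etc.: flag, keep climbing
            warnings.warn(f"{name} failed to converge: {exc}")
            fit = ModelFit(
                name=name,
                kind="linear",
                fixed=(),
                var=VarianceComponents(sigma2_e=np.nan, sigma2_u0=np.nan),
                deviance=np.nan,
                n_params=0,
                n_obs=len(df),
                n_groups=df["resident_id"].nunique(),
                converged=False,
            )
        if name == "Model 0" and fit.converged:
            null_sigma2_e = fit.var.sigma2_e
        if null_sigma2_e is not None and fit.converged and name != "Model 0":
            fit = _with_r2(fit, null_sigma2_e)
        fits.append(fit)
    return fits


def _with_r2(fit: ModelFit, null_sigma2_e: float) -> ModelFit:
    from dataclasses import replace

    if null_sigma2_e <= 0:
        return fit
    r2 = max(0.0, (null_sigma2_e - fit.var.sigma2_e) / null_sigma2_e)
    return replace(fit, r2_level1=r2)


def level1_r2(fit: ModelFit, null_fit: ModelFit) -> float:
    """Proportional reduction of level-1 residual variance vs the
    unconditional means model, floored at 0."""
    if not (fit.converged and null_fit.converged):
        raise ValidationError("both fits must have converged")
    if not null_fit.var.sigma2_e or null_fit.var.sigma2_e <= 0:
        raise UndefinedMetricError("null model has zero level-1 variance")
    return max(0.0, (null_fit.var.sigma2_e - fit.var.sigma2_e) / null_fit.var.sigma2_e)


def select_best(ladder: Sequence[ModelFit], alpha: float = 0.05) -> ModelFit:
    """Forward selection by likelihood-ratio test on full-ML deviances.

    Each converged extension replaces the current best only if its deviance
    reduction is significant at ``alpha`` for the added parameters; ties and
    non-significant extensions keep the simpler model.
    """
    converged = [f for f in ladder if f.converged]
    if len(converged) < 2:
        raise ValidationError("need at least two converged fits to select")
    best = converged[0]
    for cand in converged[1:]:
        df = cand.n_params - best.n_params
        if df <= 0:
            continue
        lr = best.deviance - cand.deviance
        if lr > 0 and stats.chi2.sf(lr, df) < alpha:
            best = cand
    return best


def lr_test(simple: ModelFit, complex_: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio statistic, df and p for two nested full-ML fits."""
    lr = simple.deviance - complex_.deviance
    df = complex_.n_params - simple.n_params
    return lr, df, float(stats.chi2.sf(max(lr, 0.0), df))


# ---------------------------------------------------------------------------
# binomial logit GLMM by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------


class _BinomialRI:
    """Binomial logit model with a Gaussian random intercept per cluster.

    Marginal log-likelihood per cluster is integrated over the random
    intercept with adaptive Gauss-Hermite quadrature: the integrand is
    re-centred at its mode (found by a few Newton steps, vectorized across
    clusters) and scaled by the curvature there, which keeps 20 nodes
    accurate even for large clusters.
    """

    def __init__(self, y, n, X, group_idx, n_groups, n_quad: int = 20):
        self.y = np.asarray(y, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.gidx = np.asarray(group_idx)
        self.J = n_groups
        self.z, self.w = np.polynomial.hermite.hermgauss(n_quad)
        self.const = float(
            np.sum(
                special.gammaln(self.n + 1)
                - special.gammaln(self.y + 1)
                - special.gammaln(self.n - self.y + 1)
            )
        )

    def _mode(self, eta, sigma2):
        """Per-cluster mode and curvature of log p(y|u) + log phi(u)."""
        u = np.zeros(self.J)
        for _ in range(25):
            p = special.expit(eta + u[self.gidx])
            g = np.bincount(self.gidx, self.y - self.n * p, minlength=self.J) - u / sigma2
            h = -np.bincount(self.gidx, self.n * p * (1 - p), minlength=self.J) - 1 / sigma2
            step = g / h
            u -= step
            if np.max(np.abs(step)) < 1e-9:
                break
        return u, -h  # h < 0 at the mode

    def loglike(self, params) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma2 = np.exp(2 * log_sigma)
        eta = self.X @ beta
        u_hat, curv = self._mode(eta, sigma2)
        tau = 1.0 / np.sqrt(curv)  # (J,)
        # nodes per cluster: u_jk = u_hat_j + sqrt(2) tau_j z_k
        u_nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * self.z[None, :]
        eta_nodes = eta[:, None] + u_nodes[self.gidx]  # (N, K)
        # log p(y|u) summed within cluster, per node
        ll_obs = self.y[:, None] * eta_nodes - self.n[:, None] * np.logaddexp(0.0, eta_nodes)
        ll_clust = np.zeros((self.J, len(self.z)))
        np.add.at(ll_clust, self.gidx, ll_obs)
        log_phi = -0.5 * u_nodes**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        h_nodes = ll_clust + log_phi
        # AGQ weights: sqrt(2) tau_j w_k exp(z_k^2) e^{h}
        log_int = special.logsumexp(
            h_nodes + self.z[None, :] ** 2 + np.log(self.w)[None, :], axis=1
        ) + 0.5 * np.log(2.0) + np.log(tau)
        return float(np.sum(log_int) + self.const)

    def fit(self, start_beta=None):
        k = self.X.shape[1]
        if start_beta is None:
            # GLM start: pooled binomial logit
            import statsmodels.api as sm

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glm = sm.GLM(
                    np.column_stack([self.y, self.n - self.y]),
                    self.X,
                    family=sm.families.Binomial(),
                ).fit()
            start_beta = glm.params
        x0 = np.concatenate([start_beta, [np.log(0.3)]])
        neg = lambda p: -self.loglike(p)
        res = optimize.minimize(neg, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
        if not res.success:  # one polish pass from where BFGS stopped
            res2 = optimize.minimize(neg, res.x, method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8})
            if res2.fun <= res.fun:
                res = res2
        return res


def fit_binomial_glmm(
    df: pd.DataFrame,
    predictors: Sequence[str],
    n_quad: int = 20,
    name: str = "binomial",
) -> ModelFit:
    """Fit ``n_correct`` of ``n_questions`` ~ predictors + (1 | resident).

    Full ML with adaptive Gauss-Hermite quadrature (``n_quad`` nodes).
    Reports odds ratios with 95% Wald confidence intervals.  Apparent
    separation (runaway coefficients or a non-finite information matrix)
    flags the fit as non-converged.
    """
    from statsmodels.tools import numdiff

    if (df["n_questions"] < 1).any():
        raise ValidationError("every record needs n_questions >= 1")
    groups, gidx = np.unique(df["resident_id"].to_numpy(), return_inverse=True)
    X = np.column_stack(
        [np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in predictors]
    )
    names = ["Intercept"] + list(predictors)
    mod = _BinomialRI(
        df["n_correct"].to_numpy(),
        df["n_questions"].to_numpy(),
        X,
        gidx,
        len(groups),
        n_quad=n_quad,
    )
    res = mod.fit()
    params = res.x
    # runaway coefficients mean the likelihood is maximized at the boundary
    # (complete separation / degenerate outcome); flag rather than report
    converged = bool(np.all(np.abs(params[:-1]) < 15))
    se = np.full(len(params), np.nan)
    if converged:
        try:
            H = numdiff.approx_hess(params, lambda p: -mod.loglike(p))
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.any(d <= 0) or not np.all(np.isfinite(d)):
                converged = False
            else:
                se = np.sqrt(d)
        except np.linalg.LinAlgError:
            converged = False
    fixed = []
    for j, pname in enumerate(names):
        b, s = float(params[j]), float(se[j])
        z = b / s if s > 0 else np.nan
        with np.errstate(over="ignore"):
            lo, hi = np.exp(b - 1.96 * s), np.exp(b + 1.96 * s)
        fixed.append(
            FixedEffect(
                name=pname,
                b=b,
                se=s,
                p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                or_=float(np.exp(b)),
                ci=(float(lo), float(hi)),
            )
        )
    sigma2_u0 = float(np.exp(2 * params[-1]))
    return ModelFit(
        name=name,
        kind="logistic",
        fixed=tuple(fixed),
        var=VarianceComponents(sigma2_e=None, sigma2_u0=sigma2_u0),
        deviance=float(2 * res.fun),
        n_params=len(params),
        n_obs=len(df),
        n_groups=len(groups),
        converged=converged,
    )


def fit_binomial_ladder(
    records: Iterable[DRPTRecord] | pd.DataFrame, n_quad: int = 20
) -> list[ModelFit]:
    """The accuracy ladder: intercept-only, + TrTime, + DRPTdiff and both
    scroll averages.  Fits flagged non-converged (e.g. separation) stay in
    the list but are excluded from selection."""
    df = records_to_frame(records)
    ladder_specs = [
        ("Model 0", []),
        ("Model 1", ["tr_time"]),
        (
            "Model 2",
            ["tr_time", "perc_time_full_runs_avg", "perc_time_rel_area_avg", "drpt_diff"],
        ),
    ]
    fits = []
    for name, preds in ladder_specs:
        try:
            fits.append(fit_binomial_glmm(df, preds, n_quad=n_quad, name=name))
        except Exception as exc:
            warnings.warn(f"{name} failed: {exc}")
            fits.append(
                ModelFit(
                    name=name,
                    kind="logistic",
                    fixed=(),
                    var=VarianceComponents(sigma2_e=None, sigma2_u0=np.nan),
                    deviance=np.nan,
                    n_params=0,
                    n_obs=len(df),
                    n_groups=df["resident_id"].nunique(),
                    converged=False,
                )
            )
    return fits


def marginal_effect(fit: ModelFit, predictor: str, delta: float) -> float:
    """Outcome-scale change for a ``delta`` increase of ``predictor``.

    Linear models: b * delta (percent points).  Logistic models: OR**delta,
    the multiplicative change in the odds of a correct answer.
    """
    fe = fit.effect(predictor)
    if fit.kind == "logistic":
        return float(np.exp(fe.b) ** delta)
    return float(fe.b * delta)
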