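"""Cross-classified mixed model for directed linkage estimates.

The response is the per-dyad linkage coefficient b1.  Fixed effects form
the full factorial of cohort drug condition, receiver role, sender role
(each effect-coded ±0.5) and linearly centered session — 16 terms
including the intercept.  Non-independence is absorbed by crossed random
intercepts for cohort, cohort×session cell, dyad, receiver and sender
(receivers/senders/dyads are *not* nested in cohort: facilitators recur
across cohorts).  Variance components are estimated by REML; Wald tests
of single-degree-of-freedom contrasts use Satterthwaite denominator
degrees of freedom, and effect sizes are reported as

    R²β = ((ν1/ν2) F) / (1 + (ν1/ν2) F),

the semi-partial R² for fixed effects in mixed models.

The REML criterion is evaluated densely:

    -2 rl(θ) = log|V| + log|X'V⁻¹X| + y'Py + const,
    V(θ) = σ²_e I + Σ_k σ²_k Z_k Z_kᵀ,

with analytic score  ∂(-2rl)/∂θ_j = tr(P V_j) − yᵀP V_j P y, which is
exact for the crossed-intercept structure used here and fast at the
sample sizes this design produces (hundreds to ~1000 estimates).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

RANDOM_FACTORS = ("cohort", "cohort_session", "dyad", "receiver", "sender")

_FACTOR_CODES = {
    "drug": {"oxytocin": 0.5, "placebo": -0.5},
    "receiver_role": {"facilitator": 0.5, "participant": -0.5},
    "sender_role": {"facilitator": 0.5, "participant": -0.5},
}


class EmptyCellError(ValueError):
    """A requested factorial cell contains no included estimates."""


@dataclass
class ModelFrame:
    """Design for the cross-classified fit."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    random_labels: dict  # factor name -> integer codes per row
    random_levels: dict  # factor name -> number of levels
    data: pd.DataFrame
    session_midpoint: float

    @property
    def n(self) -> int:
        return len(self.y)


def build_model_frame(
    table: pd.DataFrame,
    coding: str = "effect",
    session_midpoint: float | None = None,
) -> ModelFrame:
    """Model frame from a linkage table (included estimates only).

    Fixed design: full 2×2×2×linear factorial of drug condition,
    receiver role, sender role and centered session (16 columns with
    intercept).  With ``coding="effect"`` the two-level factors are
    coded ±0.5 so main effects are averages over the factorial; dummy
    (0/1) coding is available as a sensitivity option.

    Raises :class:`EmptyCellError` naming the factor when a two-level
    factor has only one level present.
    """
    if coding not in ("effect", "dummy"):
        raise ValueError("coding must be 'effect' or 'dummy'")
    df = table[table["included"] & np.isfinite(table["b1"])].copy()
    if df.empty:
        raise EmptyCellError("no included linkage estimates")

    if session_midpoint is None:
        session_midpoint = (df["session"].min() + df["session"].max()) / 2.0

    codes = {}
    for col_in, name, mapping in (
        ("drug_condition", "drug", _FACTOR_CODES["drug"]),
        ("receiver_role", "receiver_role", _FACTOR_CODES["receiver_role"]),
        ("sender_role", "sender_role", _FACTOR_CODES["sender_role"]),
    ):
        levels = set(df[col_in].unique())
        if len(levels) < 2:
            raise EmptyCellError(
                f"factor '{name}' has a single level {sorted(levels)}; "
                "the factorial cell for the other level is empty"
            )
        m = dict(mapping)
        if coding == "dummy":
            m = {k: (1.0 if v > 0 else 0.0) for k, v in m.items()}
        codes[name] = df[col_in].map(m).to_numpy(float)
    codes["session"] = df["session"].to_numpy(float) - session_midpoint

    factor_names = ["drug", "receiver_role", "sender_role", "session"]
    columns = []
    cols = []
    for r in range(len(factor_names) + 1):
        for combo in itertools.combinations(factor_names, r):
            name = ":".join(combo) if combo else "intercept"
            v = np.ones(len(df))
            for f in combo:
                v = v * codes[f]
            columns.append(name)
            cols.append(v)
    X = np.column_stack(cols)

    df["cohort_session"] = (
        df["cohort_id"].astype(str) + ":" + df["session"].astype(str)
    )
    label_sources = {
        "cohort": "cohort_id",
        "cohort_session": "cohort_session",
        "dyad": "dyad_id",
        "receiver": "receiver_id",
        "sender": "sender_id",
    }
    random_labels, random_levels = {}, {}
    for name in RANDOM_FACTORS:
        lab, uniq = pd.factorize(df[label_sources[name]], sort=True)
        random_labels[name] = lab.astype(np.intp)
        random_levels[name] = len(uniq)

    return ModelFrame(
        y=df["b1"].to_numpy(float),
        X=X,
        columns=columns,
        random_labels=random_labels,
        random_levels=random_levels,
        data=df.reset_index(drop=True),
        session_midpoint=float(session_midpoint),
    )


# ---------------------------------------------------------------------------
# REML engine


class _REMLProblem:
    """Profiled REML for crossed random intercepts.

    theta layout: [sigma2_residual, sigma2_factor_1, ..., sigma2_factor_K].

    V(θ) = σ²_e I + Z diag(d) Zᵀ with Z the stacked indicator matrix of
    all random-factor levels (q columns total) and d the per-column
    variances.  All linear algebra runs through the Woodbury identity in
    the q-dimensional level space, so cost per evaluation is O(q³ + nqp)
    rather than O(n³); with hundreds of linkage estimates and a few
    hundred levels this keeps replicated fits cheap.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, labels: dict):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.n, self.p = self.X.shape
        self.factor_names = list(labels)
        self.labels = [np.asarray(labels[k], np.intp) for k in self.factor_names]
        self.K = len(self.labels)
        # stacked indicator matrix and per-factor column blocks
        sizes = [int(lab.max()) + 1 if lab.size else 0 for lab in self.labels]
        self.q = int(sum(sizes))
        self.blocks = []
        Z = np.zeros((self.n, self.q))
        start = 0
        for lab, size in zip(self.labels, sizes):
            Z[np.arange(self.n), start + lab] = 1.0
            self.blocks.append(slice(start, start + size))
            start += size
        self.Z = Z
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ self.X

    def _factor_expand(self, theta: np.ndarray) -> np.ndarray:
        d = np.empty(self.q)
        for k, blk in enumerate(self.blocks):
            d[blk] = theta[k + 1]
        return d

    def _core(self, theta: np.ndarray):
        s2 = float(theta[0])
        d = self._factor_expand(theta)
        sd = np.sqrt(d)
        C = s2 * np.eye(self.q) + (sd[:, None] * self.ZtZ) * sd[None, :]
        cC, lowC = cho_factor(C, lower=True)
        logdetV = (self.n - self.q) * np.log(s2) + 2.0 * np.sum(
            np.log(np.diag(cC))
        )

        def vinv(M, ZtM):
            # V^{-1} M = (M - Z diag(sd) C^{-1} diag(sd) Z'M) / s2
            t = cho_solve((cC, lowC), sd[:, None] * ZtM)
            return (M - self.Z @ (sd[:, None] * t)) / s2

        ViX = vinv(self.X, self.ZtX)
        Viy = vinv(
            self.y[:, None], (self.Z.T @ self.y)[:, None]
        ).ravel()
        XtViX = self.X.T @ ViX
        cx = np.linalg.cholesky(XtViX)
        logdetXtViX = 2.0 * np.sum(np.log(np.diag(cx)))
        beta = np.linalg.solve(XtViX, self.X.T @ Viy)
        Py = Viy - ViX @ beta
        yPy = float(self.y @ Py)
        return (cC, lowC), sd, ViX, XtViX, beta, Py, logdetV, logdetXtViX, yPy

    def neg2_restricted_loglik(self, theta: np.ndarray) -> float:
        *_, ld, ldx, yPy = self._core(theta)
        return ld + ldx + yPy

    def neg2_rl_and_grad(self, theta: np.ndarray):
        choC, sd, ViX, XtViX, beta, Py, ld, ldx, yPy = self._core(theta)
        f = ld + ldx + yPy
        s2 = float(theta[0])
        Cinv = cho_solve(choC, np.eye(self.q))
        # V^{-1} Z from its Woodbury form; ViZ'Z blocks give the traces
        ViZ = (self.Z - self.Z @ (sd[:, None] * Cinv * sd[None, :]) @ self.ZtZ) / s2
        G = np.linalg.inv(XtViX)
        B = ViX.T @ self.Z  # p x q: X' V^{-1} Z
        u = self.Z.T @ Py
        GViX = G @ ViX.T

        grad = np.empty(self.K + 1)
        tr_Vinv = (self.n - self.q + s2 * np.trace(Cinv)) / s2
        tr_PX = float(np.sum(GViX * ViX.T))  # tr(G (ViX)'ViX)
        grad[0] = (tr_Vinv - tr_PX) - float(Py @ Py)
        GB = G @ B
        for k, blk in enumerate(self.blocks):
            tr_ViZk = float(np.sum(ViZ[:, blk] * self.Z[:, blk]))
            tr_corr = float(np.sum(GB[:, blk] * B[:, blk]))
            grad[k + 1] = (tr_ViZk - tr_corr) - float(u[blk] @ u[blk])
        return f, grad

    def fit(self, gtol: float = 1e-6):
        # optimize variance ratios phi = theta / v0 so the problem is
        # scale-free; v0 is the OLS residual variance
        beta_ols, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta_ols
        v0 = float(resid @ resid) / max(self.n - self.p, 1)
        v0 = max(v0, 1e-300)

        def f_scaled(phi):
            f, g = self.neg2_rl_and_grad(v0 * np.asarray(phi))
            return f, v0 * g

        bounds = [(1e-10, None)] + [(0.0, None)] * self.K
        starts = [
            np.concatenate([[0.5], np.full(self.K, 0.5 / max(self.K, 1))]),
            np.ones(self.K + 1),
        ]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                f_scaled, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 1000, "gtol": gtol, "ftol": 1e-14},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                break
        if not best.success:  # derivative-free rescue from the best point
            res = optimize.minimize(
                lambda phi: f_scaled(phi)[0], best.x, method="Powell",
                bounds=bounds, options={"maxiter": 4000, "xtol": 1e-10},
            )
            if res.fun <= best.fun:
                best = res
        # convergence = small projected gradient at the returned point
        f, g = f_scaled(best.x)
        proj = np.where(
            (np.asarray(best.x) <= 1e-10) & (g > 0), 0.0, g
        )
        best.x = v0 * np.asarray(best.x)
        best.fun = f
        best.success = bool(
            best.success or np.max(np.abs(proj)) < 1e-3 * (1.0 + abs(f))
        )
        return best

    def beta_cov(self, theta: np.ndarray):
        _, _, _, XtViX, beta, _, _, _, _ = self._core(theta)
        return beta, np.linalg.inv(XtViX)

    def contrast_variance(self, theta: np.ndarray, L: np.ndarray) -> float:
        _, cov = self.beta_cov(theta)
        return float(L @ cov @ L)


@dataclass
class LinkageModelFit:
    """REML fit: fixed effects, variance components, and test machinery."""

    frame: ModelFrame
    beta: np.ndarray
    cov_beta: np.ndarray
    variance_components: dict
    converged: bool
    boundary: dict
    neg2_loglik: float
    n_iter: int
    theta: np.ndarray = field(repr=False)
    _problem: _REMLProblem = field(repr=False)
    _theta_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def fixed_effects(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_beta))
        return pd.DataFrame(
            {"term": self.frame.columns, "estimate": self.beta, "se": se}
        )

    def contrast_vector(self, term: str) -> np.ndarray:
        L = np.zeros(len(self.frame.columns))
        L[self.frame.columns.index(term)] = 1.0
        return L


class ConvergenceError(RuntimeError):
    pass


def fit_crossclassified(
    frame: ModelFrame, gtol: float = 1e-6, on_failure: str = "raise"
) -> LinkageModelFit:
    """REML fit of the cross-classified variance-components model.

    Variances are constrained nonnegative; components estimated at the
    boundary (zero) are reported with a boundary flag, not hidden.
    Non-convergence raises :class:`ConvergenceError` carrying the
    optimizer message unless ``on_failure="warn"``.
    """
    prob = _REMLProblem(frame.y, frame.X, frame.random_labels)
    res = prob.fit(gtol=gtol)
    if not res.success and on_failure == "raise":
        raise ConvergenceError(
            f"REML did not converge: {res.message} (nit={res.nit})"
        )
    theta = np.asarray(res.x, float)
    beta, cov_unscaled = prob.beta_cov(theta)
    vc = {"residual": float(theta[0])}
    boundary = {}
    for k, name in enumerate(prob.factor_names):
        vc[name] = float(theta[k + 1])
        boundary[name] = bool(theta[k + 1] <= 1e-12 * max(theta[0], 1e-300))
    return LinkageModelFit(
        frame=frame,
        beta=beta,
        cov_beta=cov_unscaled,
        variance_components=vc,
        converged=bool(res.success),
        boundary=boundary,
        neg2_loglik=float(res.fun),
        n_iter=int(res.nit),
        theta=theta,
        _problem=prob,
    )


def _active_components(theta: np.ndarray) -> list[int]:
    """Variance parameters treated as free in the delta method.

    Components estimated on the zero boundary are held fixed there: the
    REML criterion is not differentiable across the boundary and the
    singular Hessian direction would otherwise corrupt the Satterthwaite
    denominator.  (On lme4's Cholesky scale those directions vanish
    automatically; fixing them is the variance-scale equivalent.)  The
    residual variance is always active.
    """
    tol = 1e-8 * max(float(theta[0]), 1e-300)
    return [0] + [j for j in range(1, len(theta)) if theta[j] > tol]


def _theta_covariance(fit: LinkageModelFit) -> np.ndarray:
    """Asymptotic covariance of the active variance parameters.

    2 × (pseudo)inverse of the finite-difference Hessian of the −2·REML
    criterion, computed from the analytic score; cached on the fit.
    """
    if fit._theta_cov is not None:
        return fit._theta_cov
    prob, theta = fit._problem, fit.theta
    active = _active_components(theta)
    m = len(active)
    H = np.zeros((m, m))
    scale = max(float(np.max(theta)), 1e-12)
    for a_i, j in enumerate(active):
        h = 1e-5 * max(theta[j], 1e-3 * scale)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] = max(tm[j] - h, 0.0)
        _, gp = prob.neg2_rl_and_grad(tp)
        _, gm = prob.neg2_rl_and_grad(tm)
        H[a_i] = (gp[active] - gm[active]) / (tp[j] - tm[j])
    H = (H + H.T) / 2.0
    fit._theta_cov = 2.0 * np.linalg.pinv(H)
    return fit._theta_cov


def satterthwaite_df(fit: LinkageModelFit, L: np.ndarray) -> float:
    """Satterthwaite denominator df for a 1-df contrast L.

    ν = 2 f(θ̂)² / (gᵀ A g), where f(θ) = L cov(β̂; θ) Lᵀ, g its
    gradient in the (non-boundary) variance parameters, and A the
    asymptotic covariance of θ̂.  Falls back to residual df (n − p) if
    the delta-method variance is not positive.
    """
    prob, theta = fit._problem, fit.theta
    f0 = prob.contrast_variance(theta, L)
    active = _active_components(theta)
    g = np.zeros(len(active))
    scale = max(float(np.max(theta)), 1e-12)
    for a_i, j in enumerate(active):
        h = 1e-5 * max(theta[j], 1e-3 * scale)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] = max(tm[j] - h, 0.0)
        g[a_i] = (
            prob.contrast_variance(tp, L) - prob.contrast_variance(tm, L)
        ) / (tp[j] - tm[j])
    A = _theta_covariance(fit)
    denom = float(g @ A @ g)
    if denom <= 0 or not np.isfinite(denom):
        return float(prob.n - prob.p)
    nu = 2.0 * f0 * f0 / denom
    return float(nu) if np.isfinite(nu) and nu > 0 else float(prob.n - prob.p)


@dataclass
class EffectTest:
    label: str
    estimate: float
    se: float
    F: float
    df1: float
    df2: float
    p: float
    rbeta: float

    @property
    def t(self) -> float:
        return float(np.sign(self.estimate) * np.sqrt(self.F)) if self.df1 == 1 else np.nan


def effect_size_rbeta(F: float, nu1: float, nu2: float) -> float:
    """Semi-partial R²β from a Wald F statistic and its dfs.

    R²β = ((ν1/ν2)·F) / (1 + (ν1/ν2)·F); lies in [0, 1) and increases
    monotonically in F.
    """
    if F < 0:
        raise ValueError("F must be nonnegative")
    if nu1 <= 0 or nu2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    ratio = (nu1 / nu2) * F
    return ratio / (1.0 + ratio)


def test_effect(
    fit: LinkageModelFit,
    term: str | np.ndarray,
    df_method: str = "satterthwaite",
    label: str | None = None,
) -> EffectTest:
    """Wald test of a fixed-effect term or a contrast vector.

    1-df contrasts get Satterthwaite denominator df (so F = t² with the
    same fractional df); ``df_method="residual"`` uses n − p.  A zero
    contrast vector or one outside the column space is rejected.
    """
    if isinstance(term, str):
        L = fit.contrast_vector(term)
        label = label or term
    else:
        L = np.asarray(term, float)
        label = label or "contrast"
    if L.ndim != 1 or L.shape[0] != len(fit.frame.columns):
        raise ValueError("contrast vector has wrong length")
    if not np.any(L != 0):
        raise ValueError("zero contrast vector")
    est = float(L @ fit.beta)
    var = float(L @ fit.cov_beta @ L)
    if var <= 0:
        raise ValueError("contrast lies outside the estimable space")
    se = float(np.sqrt(var))
    F = est * est / var
    if df_method == "satterthwaite":
        df2 = satterthwaite_df(fit, L)
    elif df_method == "residual":
        df2 = float(fit._problem.n - fit._problem.p)
    else:
        raise ValueError("df_method must be 'satterthwaite' or 'residual'")
    p = float(stats.f.sf(F, 1, df2))
    return EffectTest(
        label=label, estimate=est, se=se, F=float(F), df1=1.0, df2=df2,
        p=p, rbeta=effect_size_rbeta(F, 1.0, df2),
    )


def _condition_code(condition: str) -> float:
    try:
        return _FACTOR_CODES["drug"][condition]
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}") from None


def simple_effects_by_session(
    fit: LinkageModelFit, session: float, df_method: str = "satterthwaite"
) -> list[EffectTest]:
    """Condition means and their difference at one (re-centered) session.

    Because session enters linearly, re-centering the model at session s
    and reading the lower-order terms is algebraically identical to the
    contrasts used here: the mean for condition c at session s averages
    the role factors out (effect coding ±0.5), and the condition
    difference picks up the drug term plus (s − midpoint) times the
    drug×session interaction.
    """
    cols = fit.frame.columns
    d = session - fit.frame.session_midpoint
    out = []
    for cond in ("oxytocin", "placebo"):
        c = _condition_code(cond)
        L = np.zeros(len(cols))
        L[cols.index("intercept")] = 1.0
        L[cols.index("drug")] = c
        L[cols.index("session")] = d
        L[cols.index("drug:session")] = c * d
        out.append(
            test_effect(fit, L, df_method=df_method,
                        label=f"{cond} mean linkage @ session {session:g}")
        )
    Ld = np.zeros(len(cols))
    Ld[cols.index("drug")] = 1.0
    Ld[cols.index("drug:session")] = d
    out.append(
        test_effect(fit, Ld, df_method=df_method,
                    label=f"oxytocin - placebo @ session {session:g}")
    )
    return out


def linear_trend_by_condition(
    fit: LinkageModelFit, df_method: str = "satterthwaite"
) -> list[EffectTest]:
    """Within-condition linear session slopes (change in linkage per session)."""
    cols = fit.frame.columns
    out = []
    for cond in ("oxytocin", "placebo"):
        c = _condition_code(cond)
        L = np.zeros(len(cols))
        L[cols.index("session")] = 1.0
        L[cols.index("drug:session")] = c
        out.append(
            test_effect(fit, L, df_method=df_method,
                        label=f"{cond} session slope")
        )
    return out
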