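"""Mixed-effects logit engine: binomial and baseline-category multinomial
models with crossed random intercepts, estimated by Laplace-approximated
maximum likelihood.

The model for observation i with predictor x_i (year or monitoring duration)
and non-reference state s is

    eta_{is} = beta0_s + beta1_s * x_i (+ beta2_s * x_i^2)
               + sum_f u_{f, g_f(i), s},        u_{f,.,s} ~ N(0, sigma2_f)

with state probabilities softmax(eta) against a reference state (a neutral
trend). The binomial case is the S=1 special case of the same likelihood.
Random intercepts are independent across grouping factors (e.g. species and
station) and, for the multinomial, across states, with one variance per
factor.

Estimation: for a given set of variances the fixed effects and random modes
are found jointly by penalized Newton iterations (with step halving, so the
penalized objective is monotonically non-decreasing); the marginal likelihood
is then approximated by a Laplace expansion around the joint mode, and the
variances are optimized in an outer Nelder–Mead loop over their logs. As the
variances approach zero the criterion reduces exactly to the ordinary
(fixed-effects) logit likelihood.

Predictors are internally centered and scaled to roughly unit range for
numerical stability; fitted probabilities are always reported on the
original predictor scale.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

STATES3 = ("negative", "neutral", "positive")

#: |standardized coefficient| beyond which a state is considered perfectly
#: separated (probabilities pinned at 0/1).
SEPARATION_BOUND = 15.0

_LOG_SIGMA_BOUNDS = (-6.0, 3.0)


@dataclasses.dataclass
class GlmmSpec:
    """Model specification for :func:`fit_glmm`."""

    response_kind: str = "multinomial3"  # or "binomial"
    quadratic: bool = False
    random_groups: tuple[str, ...] = ("species", "station")
    reference_state: str = "neutral"

    def n_fixed_terms(self) -> int:
        return 3 if self.quadratic else 2


@dataclasses.dataclass
class GlmmFit:
    """A fitted mixed logit model."""

    spec: GlmmSpec
    states: tuple[str, ...]  # non-reference states, model order
    reference: str
    coef: np.ndarray  # (p, S) on the standardized predictor scale
    coef_se: np.ndarray  # (p, S)
    sigma2: dict[str, float]
    loglik: float
    aic: float
    converged: bool
    separation: bool
    x_center: float
    x_scale: float
    year_p: float | None = None
    n_obs: int = 0
    group_levels: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    random_modes: dict[str, np.ndarray] = dataclasses.field(default_factory=dict, repr=False)
    monitor: list[float] = dataclasses.field(default_factory=list, repr=False)

    def coef_original_scale(self) -> np.ndarray:
        """Fixed coefficients mapped back to the raw predictor scale."""
        m, s = self.x_center, self.x_scale
        out = np.zeros_like(self.coef)
        b = self.coef
        if b.shape[0] == 1:
            out[0] = b[0]
        elif b.shape[0] == 2:
            out[1] = b[1] / s
            out[0] = b[0] - b[1] * m / s
        else:
            out[2] = b[2] / s**2
            out[1] = b[1] / s - 2.0 * b[2] * m / s**2
            out[0] = b[0] - b[1] * m / s + b[2] * m**2 / s**2
        return out

    def slope_ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Wald CI for the linear predictor-term coefficient(s), raw scale.

        Exact for linear models; for quadratic fixed effects the interval is
        the delta-method interval of the raw linear term.
        """
        z = stats.norm.ppf(0.5 + level / 2.0)
        slope = self.coef_original_scale()[1]
        se = self.coef_se[1] / self.x_scale
        return slope - z * se, slope + z * se

    def to_json(self) -> str:
        payload = {
            "response_kind": self.spec.response_kind,
            "quadratic": self.spec.quadratic,
            "states": list(self.states),
            "reference": self.reference,
            "coef_standardized": self.coef.tolist(),
            "coef_original": self.coef_original_scale().tolist(),
            "coef_se": self.coef_se.tolist(),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "separation": self.separation,
            "year_p": self.year_p,
            "n_obs": self.n_obs,
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Internal dense-Newton machinery


class _Problem:
    """Preprocessed model arrays shared across likelihood evaluations."""

    def __init__(
        self,
        spec: GlmmSpec,
        data: pd.DataFrame,
        state_col: str,
        year_col: str,
        levels: dict[str, np.ndarray] | None = None,
    ):
        self.spec = spec
        x_raw = np.asarray(data[year_col], dtype=float)
        self.x_center = float(np.mean(x_raw))
        self.x_scale = float(max(np.ptp(x_raw) / 2.0, 1e-12)) if np.ptp(x_raw) > 0 else 1.0
        x = (x_raw - self.x_center) / self.x_scale

        cols = [np.ones_like(x), x]
        if spec.quadratic:
            cols.append(x * x)
        self.X = np.column_stack(cols)
        self.n, self.p = self.X.shape

        observed = pd.unique(data[state_col])
        if spec.response_kind == "multinomial3":
            self.reference = spec.reference_state
            self.state_order = tuple(
                s for s in STATES3 if s != self.reference and s in observed
            )
            if self.reference not in observed and len(self.state_order) < 2:
                raise ValueError("multinomial3 requires >=2 observed states")
        else:
            obs = sorted(map(str, observed))
            if len(obs) > 2:
                raise ValueError(f"binomial response with >2 states: {obs}")
            if len(obs) == 1 and spec.reference_state not in obs:
                # degenerate: every outcome is the "success" state; the fit
                # will separate (intercept at bound) and be flagged as such
                ref, non_ref = spec.reference_state, obs
            else:
                ref = spec.reference_state if spec.reference_state in obs else obs[0]
                non_ref = [s for s in obs if s != ref]
            self.reference = ref
            self.state_order = tuple(non_ref)
        self.S = len(self.state_order)
        if self.S == 0:
            raise ValueError("response has a single observed state")

        # one-hot of non-reference states; reference rows are all-zero
        state = np.asarray(data[state_col]).astype(str)
        self.Y = np.column_stack(
            [(state == s).astype(float) for s in self.state_order]
        )

        self.factors = list(spec.random_groups)
        self.idx: list[np.ndarray] = []
        self.levels: dict[str, np.ndarray] = {}
        for f in self.factors:
            lv = (
                levels[f]
                if levels is not None and f in levels
                else np.unique(np.asarray(data[f]).astype(str))
            )
            self.levels[f] = lv
            lookup = {v: i for i, v in enumerate(lv)}
            self.idx.append(
                np.array([lookup[v] for v in np.asarray(data[f]).astype(str)], dtype=int)
            )
        self.L = [len(self.levels[f]) for f in self.factors]
        self.F = len(self.factors)

        # parameter layout: beta blocks per state, then per factor per state
        self.dim_beta = self.p * self.S
        self.dim_u = self.S * sum(self.L)
        self.dim = self.dim_beta + self.dim_u
        self.u_offsets = []
        base = self.dim_beta
        for Lf in self.L:
            self.u_offsets.append(base)
            base += self.S * Lf

    # -- likelihood pieces ---------------------------------------------------

    def eta(self, v: np.ndarray) -> np.ndarray:
        B = v[: self.dim_beta].reshape(self.S, self.p).T  # (p, S)
        eta = self.X @ B
        for fi in range(self.F):
            Uf = v[self.u_offsets[fi] : self.u_offsets[fi] + self.S * self.L[fi]]
            Uf = Uf.reshape(self.S, self.L[fi]).T  # (L, S)
            eta = eta + Uf[self.idx[fi]]
        return eta

    def loglik_obs(self, eta: np.ndarray) -> float:
        m = np.maximum(np.max(eta, axis=1), 0.0)
        lse = m + np.log(np.exp(-m) + np.sum(np.exp(eta - m[:, None]), axis=1))
        return float(np.sum(self.Y * eta) - np.sum(lse))

    def probs(self, eta: np.ndarray) -> np.ndarray:
        m = np.maximum(np.max(eta, axis=1), 0.0)
        e = np.exp(eta - m[:, None])
        denom = np.exp(-m) + e.sum(axis=1)
        return e / denom[:, None]

    def prior_precision(self, sigma2: np.ndarray) -> np.ndarray:
        prec = np.zeros(self.dim)
        for fi in range(self.F):
            sl = slice(self.u_offsets[fi], self.u_offsets[fi] + self.S * self.L[fi])
            prec[sl] = 1.0 / sigma2[fi]
        return prec

    def penalized_obj(self, v: np.ndarray, prec: np.ndarray) -> float:
        return self.loglik_obs(self.eta(v)) - 0.5 * float(np.sum(prec * v * v))

    def _u_slice(self, fi: int, s: int) -> slice:
        return slice(
            self.u_offsets[fi] + s * self.L[fi],
            self.u_offsets[fi] + (s + 1) * self.L[fi],
        )

    def grad_hess(self, v: np.ndarray, prec: np.ndarray, *, u_only: bool = False):
        """Gradient and Hessian (negated curvature matrix A) of the penalized
        log-likelihood at v; with ``u_only`` only the random-effect blocks."""
        eta = self.eta(v)
        Pi = self.probs(eta)
        R = self.Y - Pi  # (n, S)
        # per-observation curvature wrt eta: diag(pi) - pi pi'
        W = Pi[:, :, None] * (np.eye(self.S)[None, :, :] - Pi[:, None, :])

        off = 0 if not u_only else self.dim_beta
        dim = self.dim - off
        g = np.zeros(dim)
        A = np.zeros((dim, dim))

        def sh(sl: slice) -> slice:  # shift a full-layout slice into A's frame
            return slice(sl.start - off, sl.stop - off)

        for s in range(self.S):
            if not u_only:
                g[s * self.p : (s + 1) * self.p] = self.X.T @ R[:, s]
            for fi in range(self.F):
                g[sh(self._u_slice(fi, s))] = np.bincount(
                    self.idx[fi], weights=R[:, s], minlength=self.L[fi]
                )

        for s in range(self.S):
            bs = slice(s * self.p, (s + 1) * self.p)
            for s2 in range(self.S):
                w = W[:, s, s2]
                bs2 = slice(s2 * self.p, (s2 + 1) * self.p)
                if not u_only:
                    A[bs, bs2] = self.X.T @ (w[:, None] * self.X)
                for fi in range(self.F):
                    us = sh(self._u_slice(fi, s))
                    if not u_only:
                        M = np.column_stack(
                            [
                                np.bincount(
                                    self.idx[fi],
                                    weights=w * self.X[:, j],
                                    minlength=self.L[fi],
                                )
                                for j in range(self.p)
                            ]
                        )
                        A[us, bs2] = M
                        A[bs2, us] = M.T
                    for fj in range(self.F):
                        us2 = sh(self._u_slice(fj, s2))
                        if fi == fj:
                            d = np.bincount(self.idx[fi], weights=w, minlength=self.L[fi])
                            A[us, us2] += np.diag(d)
                        else:
                            flat = np.bincount(
                                self.idx[fi] * self.L[fj] + self.idx[fj],
                                weights=w,
                                minlength=self.L[fi] * self.L[fj],
                            )
                            A[us, us2] += flat.reshape(self.L[fi], self.L[fj])

        g -= (prec * v)[off:]
        A += np.diag(prec[off:])
        return g, A

    def newton(
        self,
        v0: np.ndarray,
        prec: np.ndarray,
        *,
        u_only: bool = False,
        max_iter: int = 60,
        tol: float = 1e-9,
    ) -> tuple[np.ndarray, bool]:
        """Maximize the penalized log-likelihood over (beta, u) (or u only)
        with damped Newton steps; the objective never decreases."""
        v = v0.copy()
        obj = self.penalized_obj(v, prec)
        ub = slice(self.dim_beta, self.dim)
        for _ in range(max_iter):
            g, A = self.grad_hess(v, prec, u_only=u_only)
            gmax = float(np.max(np.abs(g)))
            if gmax < 1e-6:
                return v, True
            try:
                step = np.linalg.solve(A + 1e-10 * np.eye(A.shape[0]), g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(A, g, rcond=None)[0]
            alpha, accepted = 1.0, False
            for _ in range(30):
                v_new = v.copy()
                if u_only:
                    v_new[ub] = v[ub] + alpha * step
                else:
                    v_new = v + alpha * step
                obj_new = self.penalized_obj(v_new, prec)
                if obj_new >= obj - 1e-13:
                    v, obj, accepted = v_new, obj_new, True
                    break
                alpha *= 0.5
            if not accepted:  # stalled: objective cannot be increased
                return v, gmax < 1e-3
        g, _ = self.grad_hess(v, prec, u_only=u_only)
        return v, float(np.max(np.abs(g))) < 1e-3

    def laplace_criterion(
        self, v_hat: np.ndarray, prec: np.ndarray, sigma2: np.ndarray
    ) -> float:
        """Laplace-approximated marginal log-likelihood at the joint mode."""
        pen = self.penalized_obj(v_hat, prec)
        if self.dim_u == 0:
            return pen
        _, A_uu = self.grad_hess(v_hat, prec, u_only=True)
        sign, logdet_A = np.linalg.slogdet(A_uu)
        if sign <= 0:
            return -np.inf
        logdet_D = sum(
            self.S * self.L[fi] * np.log(sigma2[fi]) for fi in range(self.F)
        )
        return pen - 0.5 * logdet_D - 0.5 * logdet_A


def laplace_loglik(
    spec: GlmmSpec,
    data: pd.DataFrame,
    beta: np.ndarray,
    sigma2: dict[str, float],
    *,
    state_col: str = "state",
    year_col: str = "year",
    standardize: bool = False,
) -> float:
    """Laplace marginal log-likelihood at *fixed* coefficients and variances.

    ``beta`` has shape (p, S) on the raw predictor scale unless
    ``standardize``. Used as the quadrature-checkable likelihood surface.
    """
    prob = _Problem(spec, data, state_col, year_col)
    if not standardize:
        prob.x_center, prob.x_scale = 0.0, 1.0
        x = np.asarray(data[year_col], dtype=float)
        cols = [np.ones_like(x), x]
        if spec.quadratic:
            cols.append(x * x)
        prob.X = np.column_stack(cols)
    beta = np.asarray(beta, dtype=float).reshape(prob.p, prob.S)
    sig = np.array([sigma2[f] for f in prob.factors], dtype=float)
    prec = prob.prior_precision(sig)
    v = np.zeros(prob.dim)
    v[: prob.dim_beta] = beta.T.ravel()
    v_hat, _ = prob.newton(v, prec, u_only=True)
    return prob.laplace_criterion(v_hat, prec, sig)


# ---------------------------------------------------------------------------
# Fitting


def fit_glmm(
    spec: GlmmSpec,
    data: pd.DataFrame,
    *,
    state_col: str = "state",
    year_col: str = "year",
    warm_start: GlmmFit | None = None,
    compute_year_p: bool = True,
    fixed_sigma2: dict[str, float] | None = None,
) -> GlmmFit:
    """Fit the mixed logit model by Laplace maximum likelihood.

    ``data`` holds one row per population-year (or per population for the
    duration analyses) with the state, the predictor and the grouping
    columns named in ``spec.random_groups``. ``warm_start`` seeds the
    optimizer from a previous fit on comparable data (used heavily by the
    cluster bootstrap). With ``fixed_sigma2`` the variance components are
    held at the given values and only the fixed effects and random modes are
    re-estimated (one Newton solve) — the fast path for bootstrap replicates.
    """
    levels = warm_start.group_levels if warm_start is not None else None
    prob = _Problem(spec, data, state_col, year_col, levels=levels)

    v0 = np.zeros(prob.dim)
    log_sigma0 = np.full(prob.F, np.log(0.5))
    if warm_start is not None and warm_start.coef.shape == (prob.p, prob.S):
        v0[: prob.dim_beta] = warm_start.coef.T.ravel()
        log_sigma0 = np.array(
            [
                0.5 * np.log(max(warm_start.sigma2.get(f, 0.25), 1e-5))
                for f in prob.factors
            ]
        )

    state = {"v": v0, "best": None}

    def negloglik(log_sigma: np.ndarray) -> float:
        log_sigma = np.clip(log_sigma, *_LOG_SIGMA_BOUNDS)
        sig = np.exp(2.0 * log_sigma)
        prec = prob.prior_precision(sig)
        v_hat, ok = prob.newton(state["v"], prec)
        if ok:
            state["v"] = v_hat
        crit = prob.laplace_criterion(v_hat, prec, sig)
        if state["best"] is None or crit > state["best"][0]:
            state["best"] = (crit, v_hat.copy(), sig.copy(), ok)
        return -crit

    monitor: list[float] = []
    if fixed_sigma2 is not None and prob.F > 0:
        sigma2_vec = np.array(
            [max(fixed_sigma2.get(f, 0.0), 1e-10) for f in prob.factors]
        )
        prec0 = prob.prior_precision(sigma2_vec)
        v_hat, converged = prob.newton(v0, prec0)
        loglik = prob.laplace_criterion(v_hat, prec0, sigma2_vec)
        monitor.append(loglik)
    elif prob.F > 0:
        simplex = None
        if warm_start is not None:
            # tight simplex around the warm variances: few outer iterations
            simplex = np.vstack([log_sigma0] * (prob.F + 1))
            for j in range(prob.F):
                simplex[j + 1, j] += 0.1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                lambda ls: monitor.append(-negloglik(ls)) or -monitor[-1],
                log_sigma0,
                method="Nelder-Mead",
                options={
                    "xatol": 2e-3,
                    "fatol": 1e-6,
                    "maxiter": 200,
                    "initial_simplex": simplex,
                },
            )
        loglik, v_hat, sigma2_vec, inner_ok = state["best"]
        converged = bool(res.success or len(monitor) > 5) and inner_ok
    else:
        prec = np.zeros(prob.dim)
        v_hat, converged = prob.newton(v0, prec)
        sigma2_vec = np.zeros(0)
        loglik = prob.penalized_obj(v_hat, prec)

    # variances indistinguishable from zero report as zero
    sigma2_vec = np.where(sigma2_vec < np.exp(2 * _LOG_SIGMA_BOUNDS[0]) * 1.01, 0.0, sigma2_vec)

    prec = prob.prior_precision(np.maximum(sigma2_vec, 1e-12))
    g, A = prob.grad_hess(v_hat, prec)
    try:
        cov_beta = np.linalg.inv(A)[: prob.dim_beta, : prob.dim_beta]
        se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(prob.dim_beta, np.nan)

    coef = v_hat[: prob.dim_beta].reshape(prob.S, prob.p).T
    coef_se = se.reshape(prob.S, prob.p).T
    separation = bool(np.any(np.abs(coef) > SEPARATION_BOUND))
    if separation:
        warnings.warn("possible separation: coefficients at bound", stacklevel=2)

    n_par = prob.dim_beta + prob.F
    fit = GlmmFit(
        spec=spec,
        states=prob.state_order,
        reference=prob.reference,
        coef=coef,
        coef_se=coef_se,
        sigma2={f: float(s) for f, s in zip(prob.factors, sigma2_vec)},
        loglik=float(loglik),
        aic=float(-2.0 * loglik + 2.0 * n_par),
        converged=bool(converged),
        separation=separation,
        x_center=prob.x_center,
        x_scale=prob.x_scale,
        n_obs=prob.n,
        group_levels=prob.levels,
        monitor=monitor,
    )
    for fi, f in enumerate(prob.factors):
        sl = slice(prob.u_offsets[fi], prob.u_offsets[fi] + prob.S * prob.L[fi])
        fit.random_modes[f] = v_hat[sl].reshape(prob.S, prob.L[fi]).T

    if compute_year_p:
        fit.year_p = _year_lr_test(spec, data, state_col, year_col, fit)
    return fit


def _year_lr_test(
    spec: GlmmSpec, data: pd.DataFrame, state_col: str, year_col: str, full: GlmmFit
) -> float:
    """Likelihood-ratio test of the year block (linear + optional quadratic)."""
    null_spec = dataclasses.replace(spec, quadratic=False)
    null_fit = _fit_intercept_only(null_spec, data, state_col, year_col)
    df = full.coef.shape[1] * (full.coef.shape[0] - 1)
    lr = max(2.0 * (full.loglik - null_fit), 0.0)
    return float(stats.chi2.sf(lr, df))


def _fit_intercept_only(
    spec: GlmmSpec, data: pd.DataFrame, state_col: str, year_col: str
) -> float:
    """Maximized Laplace log-likelihood of the no-year model."""
    prob = _Problem(spec, data, state_col, year_col)
    prob.X = prob.X[:, :1]
    prob.p = 1
    prob.dim_beta = prob.S
    prob.dim = prob.dim_beta + prob.dim_u
    base = prob.dim_beta
    prob.u_offsets = []
    for Lf in prob.L:
        prob.u_offsets.append(base)
        base += prob.S * Lf

    state = {"v": np.zeros(prob.dim), "best": -np.inf}

    def nll(log_sigma):
        sig = np.exp(2.0 * np.clip(log_sigma, *_LOG_SIGMA_BOUNDS))
        prec = prob.prior_precision(sig)
        v_hat, ok = prob.newton(state["v"], prec)
        if ok:
            state["v"] = v_hat
        crit = prob.laplace_criterion(v_hat, prec, sig)
        state["best"] = max(state["best"], crit)
        return -crit

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        optimize.minimize(
            nll,
            np.full(prob.F, np.log(0.5)),
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 150},
        )
    return float(state["best"])


def select_polynomial(
    spec: GlmmSpec,
    data: pd.DataFrame,
    *,
    state_col: str = "state",
    year_col: str = "year",
) -> tuple[GlmmSpec, GlmmFit]:
    """Choose by AIC whether the year effect includes a quadratic term.

    Ties (and the degenerate case where only one of the two fits converges)
    resolve to the simpler, linear model.
    """
    lin_spec = dataclasses.replace(spec, quadratic=False)
    quad_spec = dataclasses.replace(spec, quadratic=True)
    lin = fit_glmm(lin_spec, data, state_col=state_col, year_col=year_col)
    quad = fit_glmm(quad_spec, data, state_col=state_col, year_col=year_col)
    if not lin.converged and not quad.converged:
        raise RuntimeError("neither the linear nor the quadratic model converged")
    if not quad.converged:
        return lin_spec, lin
    if not lin.converged:
        return quad_spec, quad
    if quad.aic < lin.aic:
        return quad_spec, quad
    return lin_spec, lin


def predict_state_probabilities(fit: GlmmFit, years: np.ndarray) -> pd.DataFrame:
    """Population-level state probabilities (random effects at zero) per year.

    Returns a frame with one row per year and columns ``pi_negative``,
    ``pi_neutral``, ``pi_positive``; states absent from the fitted model get
    probability 0 (binomial sub-model) and the reference state takes the
    softmax remainder. Probabilities sum to one.
    """
    years = np.asarray(years, dtype=float)
    x = (years - fit.x_center) / fit.x_scale
    cols = [np.ones_like(x), x]
    if fit.coef.shape[0] == 3:
        cols.append(x * x)
    X = np.column_stack(cols[: fit.coef.shape[0]])
    eta = X @ fit.coef  # (n_years, S)
    m = np.maximum(np.max(eta, axis=1), 0.0)
    e = np.exp(eta - m[:, None])
    denom = np.exp(-m) + e.sum(axis=1)
    pi_states = e / denom[:, None]
    pi_ref = np.exp(-m) / denom

    out = {f"pi_{s}": np.zeros_like(x) for s in STATES3}
    for j, s in enumerate(fit.states):
        out[f"pi_{s}"] = pi_states[:, j]
    out[f"pi_{fit.reference}"] = pi_ref
    frame = pd.DataFrame({"year": years, **out})
    return frame
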