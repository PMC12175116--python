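"""Per-population trend fitting, model selection and nine-type classification.

Each population series is fitted with linear and second-order polynomial
regressions of abundance on year under three error families:

* ``gaussian_ln`` — ordinary least squares on ln(abundance + 1);
* ``poisson``     — Poisson GLM (log link) on abundances rounded to integers;
* ``negbin``      — negative binomial (log link, ML dispersion) on the same
  rounded counts, the fallback when Poisson counts are overdispersed.

Gaussian and Poisson fits are screened for normality (Shapiro–Wilk) and
homoscedasticity (Breusch–Pagan) of residuals, Poisson additionally for
overdispersion (Pearson χ² test). Among valid fits with a significant trend
term the most parsimonious model is chosen by AIC, and the population is
assigned one of nine trend types: neutral; positive/negative linear;
positive/negative accelerating/decelerating; or unimodal (positive-to-negative
/ negative-to-positive), the latter confirmed by the Mitchell-Olds & Shaw
(MOS) test that the fitted extremum lies strictly inside the observed period.

Fitting uses years centered on the first observed year. Classification
depends only on coefficient signs and significance, which are invariant to
the centering.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.stats.diagnostic import het_breuschpagan

from .data_model import PopulationSeries

FAMILIES = ("gaussian_ln", "poisson", "negbin")
_FAMILY_ORDER = {f: i for i, f in enumerate(FAMILIES)}

TREND_TYPES = (
    "neutral",
    "positive_linear",
    "negative_linear",
    "positive_accelerating",
    "positive_decelerating",
    "negative_accelerating",
    "negative_decelerating",
    "unimodal_pos_to_neg",
    "unimodal_neg_to_pos",
)

ALPHA = 0.05


@dataclasses.dataclass
class CandidateFit:
    """One fitted candidate model for a population series."""

    family: str
    degree: int
    beta0: float = np.nan
    beta1: float = np.nan
    beta2: float | None = None
    se_beta1: float = np.nan
    se_beta2: float | None = None
    cov_b1b2: float | None = None
    slope_p: float = np.nan
    aic: float = np.nan
    #: AIC on a common (original-response) scale, used for cross-family
    #: comparison; equals ``aic`` for count families.
    comparable_aic: float = np.nan
    nb_alpha: float | None = None
    converged: bool = False
    skip_reason: str | None = None
    normality_ok: bool | None = None
    homoscedasticity_ok: bool | None = None
    overdispersion_ok: bool | None = None
    residuals: np.ndarray | None = dataclasses.field(default=None, repr=False)
    fitted_linpred: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def valid(self) -> bool:
        """True iff the fit converged and all applicable assumption checks
        passed (unset checks are not applicable for this family)."""
        if not self.converged:
            return False
        flags = (self.normality_ok, self.homoscedasticity_ok, self.overdispersion_ok)
        return all(f is not False for f in flags)

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.slope_p) and self.slope_p < ALPHA)

    def linpred(self, t: np.ndarray | float) -> np.ndarray | float:
        """Fitted linear predictor at centered year(s) ``t``."""
        eta = self.beta0 + self.beta1 * np.asarray(t, dtype=float)
        if self.degree == 2:
            eta = eta + self.beta2 * np.asarray(t, dtype=float) ** 2
        return eta

    def derivative(self, t: np.ndarray | float):
        """d(linear predictor)/dt at centered year(s) ``t``."""
        if self.degree == 1:
            return np.broadcast_to(self.beta1, np.shape(t)).astype(float) if np.ndim(t) else self.beta1
        return self.beta1 + 2.0 * self.beta2 * np.asarray(t, dtype=float)


@dataclasses.dataclass
class MosResult:
    is_unimodal: bool
    mode_year: float | None
    p: float


@dataclasses.dataclass
class TrendClassification:
    """Classification outcome for one population, with fit provenance."""

    station_id: str
    taxon_id: str
    component: str
    n_obs: int
    span: int
    first_year: int
    trend_type: str
    chosen: CandidateFit | None
    mode_year: float | None
    any_valid_model: bool
    fits: list[CandidateFit] = dataclasses.field(default_factory=list, repr=False)

    @property
    def gaussian_linear(self) -> CandidateFit | None:
        """The gaussian_ln degree-1 fit (the meta-analysis effect source)."""
        for f in self.fits:
            if f.family == "gaussian_ln" and f.degree == 1:
                return f
        return None


# ---------------------------------------------------------------------------
# Candidate fitting


def _design(t: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(t), t]
    if degree == 2:
        cols.append(t * t)
    return np.column_stack(cols)


def _fit_gaussian_ln(y: np.ndarray, X: np.ndarray, degree: int) -> CandidateFit:
    z = np.log(y + 1.0)
    res = sm.OLS(z, X).fit()
    fit = CandidateFit(family="gaussian_ln", degree=degree, converged=True)
    _fill_coefficients(fit, res.params, res.bse, res.cov_params(), res.pvalues)
    if np.ptp(z) < 1e-10:
        # constant response: coefficients and SEs are floating-point noise
        # and the Wald test is meaningless — there is no trend to detect
        fit.beta1, fit.slope_p = 0.0, 1.0
        if degree == 2:
            fit.beta2 = 0.0
    fit.aic = float(res.aic)
    # Jacobian of z = ln(y+1): log-density on the original response scale
    # differs by -sum(ln(y+1)), hence AIC by +2*sum(ln(y+1)).
    fit.comparable_aic = fit.aic + 2.0 * float(np.sum(z))
    fit.residuals = np.asarray(res.resid)
    fit.fitted_linpred = np.asarray(res.fittedvalues)
    return fit


def _fit_poisson(y: np.ndarray, X: np.ndarray, degree: int) -> CandidateFit:
    counts = np.rint(y)
    fit = CandidateFit(family="poisson", degree=degree)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    except Exception as exc:  # pragma: no cover - defensive
        fit.skip_reason = f"poisson fit failed: {exc}"
        return fit
    fit.converged = bool(res.converged) if res.converged is not None else True
    _fill_coefficients(fit, res.params, res.bse, res.cov_params(), res.pvalues)
    fit.aic = fit.comparable_aic = float(res.aic)
    fit.residuals = np.asarray(res.resid_pearson)
    fit.fitted_linpred = np.asarray(X @ res.params)
    # Pearson dispersion test against the chi-square reference
    df_resid = max(int(res.df_resid), 1)
    pearson_chi2 = float(np.sum(res.resid_pearson**2))
    fit.overdispersion_ok = bool(stats.chi2.sf(pearson_chi2, df_resid) >= ALPHA)
    return fit


def _fit_negbin(y: np.ndarray, X: np.ndarray, degree: int) -> CandidateFit:
    counts = np.rint(y)
    fit = CandidateFit(family="negbin", degree=degree)
    params = bse = cov = pvals = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = NegativeBinomial(counts, X).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.all(np.isfinite(res.bse)):
                k = X.shape[1]
                params, bse = res.params[:k], res.bse[:k]
                cov, pvals = res.cov_params()[:k, :k], res.pvalues[:k]
                fit.nb_alpha = float(res.params[-1])
                fit.aic = fit.comparable_aic = float(res.aic)
                fit.fitted_linpred = np.asarray(X @ params)
                fit.converged = True
    except Exception:
        pass
    if not fit.converged:
        # ML dispersion failed: method-of-moments alpha from a Poisson fit,
        # then a GLM with that dispersion held fixed.
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pois = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
                mu = np.asarray(pois.mu)
                alpha = float(np.sum((counts - mu) ** 2 - mu) / np.sum(mu**2))
                alpha = max(alpha, 1e-8)
                res = sm.GLM(
                    counts, X, family=sm.families.NegativeBinomial(alpha=alpha)
                ).fit()
            params, bse = res.params, res.bse
            cov, pvals = res.cov_params(), res.pvalues
            fit.nb_alpha = alpha
            # +1 parameter for the moment-estimated dispersion
            fit.aic = fit.comparable_aic = float(res.aic) + 2.0
            fit.fitted_linpred = np.asarray(X @ params)
            fit.converged = True
        except Exception as exc:
            fit.skip_reason = f"negbin fit failed: {exc}"
            return fit
    _fill_coefficients(fit, params, bse, cov, pvals)
    return fit


def _fill_coefficients(fit: CandidateFit, params, bse, cov, pvalues) -> None:
    params = np.asarray(params, dtype=float)
    bse = np.asarray(bse, dtype=float)
    fit.beta0, fit.beta1 = float(params[0]), float(params[1])
    fit.se_beta1 = float(bse[1])
    if fit.degree == 2:
        fit.beta2 = float(params[2])
        fit.se_beta2 = float(bse[2])
        fit.cov_b1b2 = float(np.asarray(cov)[1, 2])
        fit.slope_p = float(np.asarray(pvalues)[2])
    else:
        fit.slope_p = float(np.asarray(pvalues)[1])


def fit_candidates(
    series: PopulationSeries,
    families: tuple[str, ...] = FAMILIES,
    degrees: tuple[int, ...] = (1, 2),
) -> list[CandidateFit]:
    """Fit the candidate model grid to one population series.

    Returns up to ``len(families) × len(degrees)`` fits. A candidate whose
    degree requires more distinct years than observed (3 for linear, 4 for
    quadratic) is returned unconverged with a ``skip_reason`` rather than
    dropped silently.
    """
    t = series.centered_years
    y = series.values
    fits: list[CandidateFit] = []
    for degree in degrees:
        min_years = 3 if degree == 1 else 4
        if np.unique(t).size < min_years:
            for family in families:
                fits.append(
                    CandidateFit(
                        family=family,
                        degree=degree,
                        skip_reason=f"fewer than {min_years} distinct years",
                    )
                )
            continue
        X = _design(t, degree)
        poisson_fit: CandidateFit | None = None
        for family in families:
            if family == "gaussian_ln":
                fits.append(_fit_gaussian_ln(y, X, degree))
            elif family == "poisson":
                poisson_fit = _fit_poisson(y, X, degree)
                fits.append(poisson_fit)
            elif family == "negbin":
                # the negative binomial is the overdispersion fallback: it
                # enters the candidate set only when the same-degree Poisson
                # fit is overdispersed (or failed outright)
                if (
                    "poisson" in families
                    and poisson_fit is not None
                    and poisson_fit.converged
                    and poisson_fit.overdispersion_ok is not False
                ):
                    fits.append(
                        CandidateFit(
                            family="negbin",
                            degree=degree,
                            skip_reason="Poisson fit not overdispersed",
                        )
                    )
                else:
                    fits.append(_fit_negbin(y, X, degree))
            else:
                raise ValueError(f"unknown family {family!r}")
    return fits


# ---------------------------------------------------------------------------
# Assumption checks


def check_assumptions(fit: CandidateFit, series: PopulationSeries) -> CandidateFit:
    """Fill normality / homoscedasticity flags on a converged fit.

    Normality is Shapiro–Wilk and homoscedasticity Breusch–Pagan, both at
    α=0.05, applied to raw residuals for Gaussian fits and Pearson residuals
    for Poisson. Negative binomial fits carry no residual screens (they are
    the overdispersion fallback). Degenerate (constant) residuals make the
    normality test inapplicable and are treated as a pass.
    """
    if not fit.converged or fit.family == "negbin":
        return fit
    resid = fit.residuals
    if resid is None:
        return fit
    X = _design(series.centered_years, fit.degree)
    if np.ptp(resid) < 1e-12:
        fit.normality_ok = True  # not applicable: no variation to test
        fit.homoscedasticity_ok = True
        return fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit.normality_ok = bool(stats.shapiro(resid).pvalue >= ALPHA)
        _, bp_p, _, _ = het_breuschpagan(resid, X)
    fit.homoscedasticity_ok = bool(bp_p >= ALPHA)
    return fit


# ---------------------------------------------------------------------------
# Model selection


def select_model(fits: list[CandidateFit]) -> CandidateFit | None:
    """Most parsimonious (lowest-AIC) valid fit with a significant trend term.

    Significance is the Wald test of the year term for linear fits and of the
    quadratic term for polynomial fits. AICs are compared on a common
    original-response scale (``comparable_aic``); exact ties break to the
    lower degree, then to family order gaussian_ln < poisson < negbin.
    Returns ``None`` when no valid fit shows a significant trend (a neutral
    population).
    """
    eligible = [f for f in fits if f.converged and f.valid and f.significant]
    if not eligible:
        return None
    best = min(
        eligible,
        key=lambda f: (
            round(f.comparable_aic / 1e-9) * 1e-9,
            f.degree,
            _FAMILY_ORDER[f.family],
        ),
    )
    return best


# ---------------------------------------------------------------------------
# MOS test and classification


def mos_test(fit: CandidateFit, series: PopulationSeries) -> MosResult:
    """Mitchell-Olds & Shaw test: does the fitted quadratic's extremum lie
    strictly inside the observed year range?

    The extremum of η(t) = β0 + β1·t + β2·t² sits at t* = −β1/(2β2). The
    trend is called unimodal when β1 and β2 have opposite signs, t* falls in
    the observed range, and the fitted derivative η'(t) = β1 + 2β2·t is
    significantly different from zero with opposite signs at both range
    endpoints — i.e. the curve demonstrably rises on one side of the mode and
    falls on the other.
    """
    if fit.degree != 2 or fit.beta2 is None or abs(fit.beta2) < 1e-300:
        return MosResult(is_unimodal=False, mode_year=None, p=1.0)
    t_first, t_last = 0.0, float(series.years[-1] - series.years[0])
    t_star = -fit.beta1 / (2.0 * fit.beta2)
    mode_year = float(series.years[0] + t_star)

    opposite_signs = fit.beta1 * fit.beta2 < 0
    inside = t_first <= t_star <= t_last

    ps, signs = [], []
    for t in (t_first, t_last):
        deriv = fit.beta1 + 2.0 * fit.beta2 * t
        var = (
            fit.se_beta1**2
            + 4.0 * t * (fit.cov_b1b2 or 0.0)
            + 4.0 * t * t * (fit.se_beta2 or 0.0) ** 2
        )
        if var <= 0:
            # noiseless fit: derivative is exact, zero p unless the
            # derivative itself vanishes at the endpoint
            ps.append(0.0 if deriv != 0 else 1.0)
        else:
            z = deriv / np.sqrt(var)
            ps.append(float(2.0 * stats.norm.sf(abs(z))))
        signs.append(np.sign(deriv))
    endpoint_ok = ps[0] < ALPHA and ps[1] < ALPHA and signs[0] * signs[1] < 0
    is_unimodal = bool(opposite_signs and inside and endpoint_ok)
    return MosResult(
        is_unimodal=is_unimodal,
        mode_year=mode_year if inside else None,
        p=float(max(ps)),
    )


def _classify_quadratic(fit: CandidateFit, series: PopulationSeries) -> tuple[str, float | None]:
    mos = mos_test(fit, series)
    if mos.is_unimodal:
        ttype = "unimodal_pos_to_neg" if fit.beta2 < 0 else "unimodal_neg_to_pos"
        return ttype, mos.mode_year
    # Accelerating/decelerating: net direction over the observed range and
    # whether the trend's magnitude grows or shrinks towards the end.
    t_last = float(series.years[-1] - series.years[0])
    net = fit.linpred(t_last) - fit.linpred(0.0)
    direction = "positive" if net >= 0 else "negative"
    accel = abs(fit.derivative(t_last)) > abs(fit.derivative(0.0))
    pace = "accelerating" if accel else "decelerating"
    return f"{direction}_{pace}", None


def classify_trend(
    series: PopulationSeries,
    families: tuple[str, ...] = FAMILIES,
    degrees: tuple[int, ...] = (1, 2),
) -> TrendClassification:
    """Fit, screen, select and classify one population series.

    Decision tree: no valid significant model → ``neutral``; a linear best
    model → positive/negative linear by the sign of its slope; a quadratic
    best model → unimodal when the MOS test confirms an interior extremum
    with opposite-sign coefficients, otherwise accelerating/decelerating by
    the net direction and the change in trend magnitude over the period.
    Populations for which *no* candidate passed the assumption screens are
    neutral with ``any_valid_model=False`` (they drop out of the duration
    analysis denominators).
    """
    fits = fit_candidates(series, families=families, degrees=degrees)
    for f in fits:
        check_assumptions(f, series)
    chosen = select_model(fits)
    any_valid = any(f.converged and f.valid for f in fits)

    mode_year: float | None = None
    if chosen is None:
        trend_type = "neutral"
    elif chosen.degree == 1:
        trend_type = "positive_linear" if chosen.beta1 > 0 else "negative_linear"
    else:
        trend_type, mode_year = _classify_quadratic(chosen, series)

    return TrendClassification(
        station_id=series.station_id,
        taxon_id=series.taxon_id,
        component=series.component,
        n_obs=series.n_obs,
        span=series.span,
        first_year=int(series.years[0]),
        trend_type=trend_type,
        chosen=chosen,
        mode_year=mode_year,
        any_valid_model=any_valid,
        fits=fits,
    )


def classifications_to_frame(classifications: list[TrendClassification]):
    """Tidy one-row-per-population table (the trends.csv layout)."""
    import pandas as pd

    rows = []
    for c in classifications:
        ch = c.chosen
        rows.append(
            {
                "station": c.station_id,
                "taxon": c.taxon_id,
                "component": c.component,
                "n_obs": c.n_obs,
                "span": c.span,
                "family": ch.family if ch else "",
                "degree": ch.degree if ch else 0,
                "beta0": ch.beta0 if ch else np.nan,
                "beta1": ch.beta1 if ch else np.nan,
                "beta2": (ch.beta2 if ch and ch.beta2 is not None else np.nan),
                "se_beta1": ch.se_beta1 if ch else np.nan,
                "slope_p": ch.slope_p if ch else np.nan,
                "aic": ch.comparable_aic if ch else np.nan,
                "trend_type": c.trend_type,
                "mode_year": c.mode_year if c.mode_year is not None else np.nan,
                "any_valid_model": c.any_valid_model,
            }
        )
    return pd.DataFrame(rows)
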