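"""Time-specific trend directions: yearly states, group timelines and the
predominant-state classification.

Each classified population gets a *state* for every calendar year of its
monitoring period: the sign of the derivative of its fitted trend in that
year (a linear trend is always one sign; a quadratic trend can flip at its
vertex; neutral populations are neutral throughout). Within a taxonomic
group, a mixed multinomial logit of state on year (species and station
random intercepts, baseline state neutral) estimates the probability of
positive and negative states over time; cluster-bootstrap CIs over
populations then support a per-year verdict: *cancelled* when the positive
and negative CIs overlap (offsetting trends), *neutral* when both
probabilities stay below one half, otherwise the state with the higher
probability.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .glmm_engine import (
    GlmmFit,
    GlmmSpec,
    fit_glmm,
    predict_state_probabilities,
    select_polynomial,
)
from .trend_fitting import TrendClassification

#: exact-zero tolerance for the fitted rate of change
RATE_ZERO_TOL = 1e-12


def yearly_states(classification: TrendClassification) -> pd.DataFrame:
    """Per-year rate of change and trend state for one population.

    The rate is the derivative of the chosen model's linear predictor,
    r(t) = beta1 (+ 2*beta2*t on the centered year scale); the state is its
    sign, with neutral for |r| below tolerance or for populations classified
    neutral. Covers every calendar year of the monitoring period.
    """
    years = np.arange(
        classification.first_year, classification.first_year + classification.span
    )
    t = (years - classification.first_year).astype(float)
    fit = classification.chosen
    if fit is None or classification.trend_type == "neutral":
        rate = np.zeros_like(t)
    else:
        rate = np.asarray(fit.derivative(t), dtype=float)
    state = np.where(
        np.abs(rate) <= RATE_ZERO_TOL,
        "neutral",
        np.where(rate > 0, "positive", "negative"),
    )
    return pd.DataFrame(
        {
            "station": classification.station_id,
            "species": classification.taxon_id,
            "population": f"{classification.station_id}::{classification.taxon_id}",
            "year": years,
            "rate": rate,
            "state": state,
        }
    )


def states_table(classifications: list[TrendClassification]) -> pd.DataFrame:
    """Stacked yearly states for many populations."""
    return pd.concat(
        [yearly_states(c) for c in classifications], ignore_index=True
    )


@dataclasses.dataclass
class TimelineModel:
    """A fitted (or rejected) state-vs-year model for one taxon group."""

    group: str
    fit: GlmmFit | None
    significant: bool
    reason: str = ""


def fit_group_timeline(
    states: pd.DataFrame,
    group_label: str = "",
    alpha: float = 0.05,
) -> TimelineModel:
    """Mixed logit of yearly state on calendar year for one group.

    Uses the three-state multinomial when all of negative/neutral/positive
    occur, the binomial sub-model when only two do; the quadratic year term
    is kept when it lowers AIC. The model is retained only when year
    significantly predicts the state (likelihood-ratio test).
    """
    observed = set(states["state"].unique())
    if len(observed) < 2:
        return TimelineModel(group_label, None, False, "single observed state")
    kind = "multinomial3" if len(observed) == 3 else "binomial"
    spec = GlmmSpec(
        response_kind=kind,
        random_groups=("species", "station"),
        reference_state="neutral",
    )
    try:
        _, fit = select_polynomial(spec, states)
    except RuntimeError as exc:
        return TimelineModel(group_label, None, False, str(exc))
    if fit.year_p is None or fit.year_p >= alpha:
        return TimelineModel(
            group_label, fit, False, f"year not significant (p={fit.year_p:.3g})"
        )
    return TimelineModel(group_label, fit, True)


def bootstrap_timeline(
    fit: GlmmFit,
    states: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
    years: np.ndarray | None = None,
    *,
    reestimate_variances: bool = False,
    max_failure_rate: float = 0.2,
) -> pd.DataFrame:
    """Cluster-bootstrap percentile CIs for the per-year state probabilities.

    Populations (species x station clusters) are resampled with
    replacement; the model is refitted on each replicate and the predicted
    probabilities collected. By default the variance components are held at
    the full-sample estimates during replicate refits (the fixed effects and
    random modes are fully re-estimated); set ``reestimate_variances`` to
    re-optimize them per replicate. More than ``max_failure_rate``
    non-converged replicates raises.
    """
    if B < 200:
        raise ValueError("B must be at least 200 for stable percentile CIs")
    rng = np.random.default_rng(seed)
    if years is None:
        years = np.arange(int(states["year"].min()), int(states["year"].max()) + 1)
    clusters = states["population"].unique()
    by_cluster = {c: states[states["population"] == c] for c in clusters}

    draws_pos = np.empty((B, len(years)))
    draws_neg = np.empty((B, len(years)))
    failures = 0
    for b in range(B):
        picked = rng.choice(clusters, size=len(clusters), replace=True)
        sample = pd.concat([by_cluster[c] for c in picked], ignore_index=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                refit = fit_glmm(
                    fit.spec,
                    sample,
                    warm_start=fit,
                    compute_year_p=False,
                    fixed_sigma2=None if reestimate_variances else fit.sigma2,
                )
            if not refit.converged:
                raise RuntimeError("replicate did not converge")
            pred = predict_state_probabilities(refit, years)
            draws_pos[b] = pred["pi_positive"].to_numpy()
            draws_neg[b] = pred["pi_negative"].to_numpy()
        except Exception:
            failures += 1
            draws_pos[b] = np.nan
            draws_neg[b] = np.nan
    if failures > max_failure_rate * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap replicates failed to converge; "
            "the group model is too fragile for interval estimation"
        )

    point = predict_state_probabilities(fit, years)
    out = pd.DataFrame(
        {
            "year": years,
            "pi_positive": point["pi_positive"].to_numpy(),
            "pi_positive_lo": np.nanpercentile(draws_pos, 2.5, axis=0),
            "pi_positive_hi": np.nanpercentile(draws_pos, 97.5, axis=0),
            "pi_negative": point["pi_negative"].to_numpy(),
            "pi_negative_lo": np.nanpercentile(draws_neg, 2.5, axis=0),
            "pi_negative_hi": np.nanpercentile(draws_neg, 97.5, axis=0),
        }
    )
    return out


def classify_timeline(
    timeline: pd.DataFrame,
    *,
    overlap_first: bool = True,
) -> pd.DataFrame:
    """Per-year predominant-direction verdict from probabilities and CIs.

    Rules, in order: (1) the positive and negative CIs overlap → *cancelled*
    (offsetting trends); (2) both probabilities below 0.5 → *neutral*;
    (3) otherwise the state with the higher point probability. With
    ``overlap_first=False`` the 0.5 threshold is checked before overlap.
    """
    verdicts = []
    for _, row in timeline.iterrows():
        overlap = (
            row["pi_positive_lo"] <= row["pi_negative_hi"]
            and row["pi_negative_lo"] <= row["pi_positive_hi"]
        )
        below = max(row["pi_positive"], row["pi_negative"]) < 0.5
        directional = (
            "positive" if row["pi_positive"] > row["pi_negative"] else "negative"
        )
        if overlap_first:
            verdict = "cancelled" if overlap else ("neutral" if below else directional)
        else:
            verdict = "neutral" if below else ("cancelled" if overlap else directional)
        verdicts.append(verdict)
    out = timeline.copy()
    out["verdict"] = verdicts
    return out


def group_timelines(
    classifications: list[TrendClassification],
    group_of: dict[str, str],
    B: int = 1000,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """End-to-end timelines for taxon groups.

    ``group_of`` maps taxon_id to a group label (e.g. its class or family).
    Groups whose state model is not significantly predicted by year are
    omitted, mirroring how non-significant models are dropped from timeline
    reporting.
    """
    states = states_table(classifications)
    states["group"] = states["species"].map(group_of)
    out: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng(seed)
    for group, sub in states.groupby("group", sort=True):
        model = fit_group_timeline(sub, str(group))
        if not model.significant or model.fit is None:
            continue
        timeline = bootstrap_timeline(
            model.fit, sub, B=B, seed=int(rng.integers(2**31 - 1))
        )
        out[str(group)] = classify_timeline(timeline)
    return out
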