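"""Year-weighted vote count of trend types and the two duration analyses.

The vote count summarises the classified trends as percentage shares of five
groups — positive (all positive directional types pooled), negative (all
negative directional types pooled), the two unimodal types, and neutral —
with each trend weighted by its number of observation years, so that a
30-year trend counts six times a 5-year one.

The duration analyses ask, across populations, whether (a) the probability
of detecting a non-neutral trend and (b) the probability that any candidate
model met its assumptions change with monitoring duration. Both are binomial
mixed logits with station and species as crossed random intercepts.
"""

from __future__ import annotations

import pandas as pd

from .glmm_engine import GlmmFit, GlmmSpec, fit_glmm
from .trend_fitting import TrendClassification

TREND_GROUPS = (
    "positive",
    "negative",
    "unimodal_pos_to_neg",
    "unimodal_neg_to_pos",
    "neutral",
)

_GROUP_MAP = {
    "positive_linear": "positive",
    "positive_accelerating": "positive",
    "positive_decelerating": "positive",
    "negative_linear": "negative",
    "negative_accelerating": "negative",
    "negative_decelerating": "negative",
    "unimodal_pos_to_neg": "unimodal_pos_to_neg",
    "unimodal_neg_to_pos": "unimodal_neg_to_pos",
    "neutral": "neutral",
}


def group_trend_types(trend_type: str) -> str:
    """Map the nine trend types onto the five vote-count groups."""
    try:
        return _GROUP_MAP[trend_type]
    except KeyError:
        raise ValueError(f"unknown trend type {trend_type!r}") from None


def weighted_vote_count(
    classifications: list[TrendClassification],
    *,
    by_component: bool = False,
) -> pd.DataFrame:
    """Percentage share of each trend group, weighted by observation years.

    Shares within a scope (overall, or one ecosystem component when
    ``by_component``) sum to 100. The weight of each trend is its number of
    years with observations (``n_obs``), not its span.
    """
    if not classifications:
        raise ValueError("no classifications to count")
    df = pd.DataFrame(
        {
            "scope": [c.component if by_component else "all" for c in classifications],
            "group": [group_trend_types(c.trend_type) for c in classifications],
            "weight": [c.n_obs for c in classifications],
        }
    )
    rows = []
    for scope, sub in df.groupby("scope", sort=True):
        total = float(sub["weight"].sum())
        if total <= 0:
            raise ValueError(f"zero total weight in scope {scope!r}")
        for group in TREND_GROUPS:
            g = sub[sub["group"] == group]
            rows.append(
                {
                    "scope": scope,
                    "trend_group": group,
                    "weighted_share": 100.0 * float(g["weight"].sum()) / total,
                    "n_trends": int(len(g)),
                    "total_weight": float(g["weight"].sum()),
                }
            )
    return pd.DataFrame(rows)


def _duration_frame(
    classifications: list[TrendClassification],
    outcome: str,
    duration: str,
) -> pd.DataFrame:
    if duration not in ("span", "n_obs"):
        raise ValueError("duration must be 'span' or 'n_obs'")
    rows = []
    for c in classifications:
        if outcome == "detection":
            if not c.any_valid_model:
                continue  # no assumption-conforming model: outside the rule
            state = "directional" if c.trend_type != "neutral" else "neutral"
        else:
            state = "valid" if c.any_valid_model else "invalid"
        rows.append(
            {
                "state": state,
                "year": float(getattr(c, duration)),
                "species": c.taxon_id,
                "station": c.station_id,
            }
        )
    return pd.DataFrame(rows)


def detection_vs_duration(
    classifications: list[TrendClassification],
    duration: str = "span",
) -> GlmmFit:
    """Probability of detecting a non-neutral trend vs monitoring duration.

    Binomial mixed logit of indicator(directional) on duration with station
    and species random intercepts; only populations with at least one
    assumption-conforming model enter. The fitted duration coefficient (on
    the raw year scale) and its Wald 95% CI come from
    :meth:`GlmmFit.coef_original_scale` / :meth:`GlmmFit.slope_ci`.
    """
    data = _duration_frame(classifications, "detection", duration)
    if data.empty:
        raise ValueError("no populations with a valid model")
    spec = GlmmSpec(
        response_kind="binomial",
        random_groups=("station", "species"),
        reference_state="neutral",
    )
    return fit_glmm(spec, data)


def validity_vs_duration(
    classifications: list[TrendClassification],
    duration: str = "span",
) -> GlmmFit:
    """Probability that any candidate model met assumptions vs duration.

    Same binomial mixed logit, with outcome ``any_valid_model``, over *all*
    classified populations.
    """
    data = _duration_frame(classifications, "validity", duration)
    spec = GlmmSpec(
        response_kind="binomial",
        random_groups=("station", "species"),
        reference_state="invalid",
    )
    return fit_glmm(spec, data)
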