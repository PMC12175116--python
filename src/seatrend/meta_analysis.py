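"""Multilevel random-effects meta-analysis of population trend slopes.

Each eligible population contributes its Gaussian linear-model slope as the
effect size y_i and the squared standard error of that slope as a *known*
sampling variance v_i, so reliable trends (typically from longer series)
carry more weight. The model is

    y_i = x_i' beta + u_{station(i)} + e_i,
    u_s ~ N(0, sigma2_station),   e_i ~ N(0, v_i),

with the between-station variance estimated by restricted maximum
likelihood (REML) and the fixed effects by generalized least squares at the
REML variance. Moderators (ecosystem component, or a taxonomic rank in a
no-intercept model) yield per-level pooled slopes; a taxon is a *winner*
when its 95% CI lies entirely above zero and a *loser* when entirely below.
Repeating the overall analysis on |y_i| diagnoses cancellation: a signed
mean near zero together with a clearly positive absolute mean indicates
offsetting positive and negative trends rather than stasis.

The station blocks make V = diag(v) + sigma2 * J block-diagonal, so all REML
quantities are accumulated per station in closed form (Sherman–Morrison /
determinant lemma) — no dense solves.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import TAXONOMIC_RANKS, TaxonomyEntry
from .trend_fitting import TrendClassification

#: Component subsets on which the order/family/genus winner–loser runs are
#: performed (zooplankton rides with macrozoobenthos for sample size).
RANK_SUBSET_GROUPS: dict[str, tuple[str, ...]] = {
    "plants": ("plants",),
    "phytoplankton": ("phytoplankton",),
    "fish": ("fish",),
    "birds": ("birds",),
    "macrozoobenthos_zooplankton": ("macrozoobenthos", "zooplankton"),
}


@dataclasses.dataclass
class EffectSize:
    """One meta-analysis row: a population's linear slope and its variance."""

    slope: float
    variance: float
    station_id: str
    taxon_id: str
    component: str
    taxonomy: dict[str, str] = dataclasses.field(default_factory=dict)
    taxonomy_missing: bool = False

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError("sampling variance must be positive")


@dataclasses.dataclass
class MetaResult:
    """Pooled or per-moderator-level estimate with Wald-z inference."""

    level: str
    estimate: float
    se: float
    zval: float
    ci_lower: float
    ci_upper: float
    p: float
    sigma2_station: float
    k: int
    n_species: int

    @property
    def call(self) -> str:
        if self.ci_lower > 0:
            return "winner"
        if self.ci_upper < 0:
            return "loser"
        return "neutral"


@dataclasses.dataclass
class WinnerLoserCall:
    label: str
    rank: str
    call: str
    estimate: float
    ci_lower: float
    ci_upper: float
    k: int


def build_effect_table(
    classifications: list[TrendClassification],
    taxonomy: dict[str, TaxonomyEntry] | None = None,
) -> list[EffectSize]:
    """Extract effect sizes from trend classifications.

    A population is eligible iff its Gaussian linear fit converged and met
    the residual assumption checks — regardless of whether a polynomial or a
    count-family model won the AIC selection. Populations without a
    taxonomy entry are kept but flagged (they drop out of rank-moderated
    runs only).
    """
    effects: list[EffectSize] = []
    for c in classifications:
        fit = c.gaussian_linear
        if fit is None or not (fit.converged and fit.valid):
            continue
        if not np.isfinite(fit.se_beta1) or fit.se_beta1 <= 0:
            continue
        entry = taxonomy.get(c.taxon_id) if taxonomy else None
        labels: dict[str, str] = {}
        if entry is not None:
            labels = dict(zip(TAXONOMIC_RANKS, entry.rank_path()))
        effects.append(
            EffectSize(
                slope=fit.beta1,
                variance=fit.se_beta1**2,
                station_id=c.station_id,
                taxon_id=c.taxon_id,
                component=c.component,
                taxonomy=labels,
                taxonomy_missing=entry is None,
            )
        )
    return effects


# ---------------------------------------------------------------------------
# REML core


def _station_blocks(stations: np.ndarray) -> list[np.ndarray]:
    order: dict[str, list[int]] = {}
    for i, s in enumerate(stations):
        order.setdefault(s, []).append(i)
    return [np.array(ix) for ix in order.values()]


def restricted_loglik(
    sigma2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray, blocks: list[np.ndarray]
) -> float:
    """REML log-likelihood (up to an additive constant) at a given
    between-station variance, accumulated blockwise.

    Within one station, V_b = diag(v_b) + sigma2 * J; its inverse and
    determinant follow from the Sherman–Morrison identity.
    """
    p = X.shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    yViy = 0.0
    logdetV = 0.0
    for ix in blocks:
        vb, yb, Xb = v[ix], y[ix], X[ix]
        d = 1.0 / vb
        c = sigma2 / (1.0 + sigma2 * d.sum())
        logdetV += float(np.sum(np.log(vb)) + np.log1p(sigma2 * d.sum()))
        dy, dX = d * yb, d[:, None] * Xb
        yViy += float(yb @ dy - c * (d @ yb) ** 2)
        XtViy += dX.T @ yb - c * (d @ yb) * (dX.T @ np.ones_like(yb))
        s1X = dX.sum(axis=0)
        XtViX += Xb.T @ dX - c * np.outer(s1X, s1X)
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, XtViy)
    quad = yViy - beta @ XtViy
    return -0.5 * (logdetV + logdetXtViX + quad)


def _gls_at(
    sigma2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray, blocks: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    p = X.shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    for ix in blocks:
        vb, yb, Xb = v[ix], y[ix], X[ix]
        d = 1.0 / vb
        c = sigma2 / (1.0 + sigma2 * d.sum())
        dX = d[:, None] * Xb
        XtViy += dX.T @ yb - c * (d @ yb) * dX.sum(axis=0)
        s1X = dX.sum(axis=0)
        XtViX += Xb.T @ dX - c * np.outer(s1X, s1X)
    cov = np.linalg.inv(XtViX)
    beta = cov @ XtViy
    return beta, cov


def _fit_reml(
    y: np.ndarray, v: np.ndarray, X: np.ndarray, stations: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    blocks = _station_blocks(stations)
    upper = max(float(np.var(y)) * 10.0, float(np.max(v)) * 10.0, 1e-8)
    res = optimize.minimize_scalar(
        lambda s2: -restricted_loglik(s2, y, v, X, blocks),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": 1e-10},
    )
    sigma2 = float(res.x)
    # the optimizer cannot sit exactly on the boundary; prefer 0 when it is
    # at least as good (observed dispersion within the sampling variances)
    if restricted_loglik(0.0, y, v, X, blocks) >= -res.fun - 1e-10:
        sigma2 = 0.0
    beta, cov = _gls_at(sigma2, y, v, X, blocks)
    return sigma2, beta, cov


def _wald_rows(
    names: list[str],
    beta: np.ndarray,
    cov: np.ndarray,
    sigma2: float,
    ks: list[int],
    n_species: list[int],
) -> list[MetaResult]:
    z975 = stats.norm.ppf(0.975)
    out = []
    for j, name in enumerate(names):
        se = float(np.sqrt(cov[j, j]))
        est = float(beta[j])
        z = est / se if se > 0 else np.inf * np.sign(est)
        out.append(
            MetaResult(
                level=name,
                estimate=est,
                se=se,
                zval=float(z),
                ci_lower=est - z975 * se,
                ci_upper=est + z975 * se,
                p=float(2.0 * stats.norm.sf(abs(z))),
                sigma2_station=sigma2,
                k=ks[j],
                n_species=n_species[j],
            )
        )
    return out


def reml_multilevel(
    effects: list[EffectSize],
    moderator: str | None = None,
    intercept: bool = True,
    *,
    use_absolute: bool = False,
) -> list[MetaResult]:
    """Multilevel random-effects meta-analysis with station random effect.

    ``moderator`` may be ``None`` (overall mean), ``"component"`` or a
    taxonomic rank name; with ``intercept=False`` the moderator levels are
    coded as indicators so each coefficient is that level's pooled mean.
    Effects lacking the moderator label (missing taxonomy) are dropped from
    moderated runs.
    """
    effs = list(effects)
    if moderator not in (None, "component"):
        effs = [
            e for e in effs if not e.taxonomy_missing and e.taxonomy.get(moderator)
        ]
    if len(effs) < 2:
        raise ValueError("need at least two effects")
    y = np.array([abs(e.slope) if use_absolute else e.slope for e in effs])
    v = np.array([e.variance for e in effs])
    stations = np.array([e.station_id for e in effs])

    def label(e: EffectSize) -> str:
        if moderator is None:
            return "overall"
        if moderator == "component":
            return e.component
        return e.taxonomy[moderator]

    if moderator is None:
        X = np.ones((len(effs), 1))
        names = ["overall" if not use_absolute else "overall_absolute"]
        ks = [len(effs)]
        nsp = [len({e.taxon_id for e in effs})]
    else:
        labels = [label(e) for e in effs]
        levels = sorted(set(labels))
        if intercept:
            names = [levels[0]] + [f"{lv} - {levels[0]}" for lv in levels[1:]]
            X = np.column_stack(
                [np.ones(len(effs))]
                + [[1.0 if la == lv else 0.0 for la in labels] for lv in levels[1:]]
            )
        else:
            names = levels
            X = np.column_stack(
                [[1.0 if la == lv else 0.0 for la in labels] for lv in levels]
            )
        ks = [sum(la == lv for la in labels) for lv in levels]
        nsp = [
            len({e.taxon_id for e, la in zip(effs, labels) if la == lv})
            for lv in levels
        ]
        if not intercept and min(ks) == 0:
            raise ValueError("empty moderator level")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(f"collinear moderator design over levels {levels}")
        if intercept:
            ks = [len(effs)] + ks[1:]
            nsp = [len({e.taxon_id for e in effs})] + nsp[1:]

    sigma2, beta, cov = _fit_reml(y, v, X, stations)
    return _wald_rows(names, beta, cov, sigma2, ks, nsp)


def absolute_slope_meta(effects: list[EffectSize]) -> MetaResult:
    """Overall meta-analysis on |slope|: the cancellation diagnostic."""
    return reml_multilevel(effects, moderator=None, use_absolute=True)[0]


def winners_losers(results: list[MetaResult], rank: str = "class") -> list[WinnerLoserCall]:
    """Winner/loser/neutral call per moderator level from the 95% CIs."""
    return [
        WinnerLoserCall(
            label=r.level,
            rank=rank,
            call=r.call,
            estimate=r.estimate,
            ci_lower=r.ci_lower,
            ci_upper=r.ci_upper,
            k=r.k,
        )
        for r in results
    ]


def rank_winners_losers(
    effects: list[EffectSize],
    ranks: tuple[str, ...] = ("class", "order", "family", "genus"),
    min_effects_per_level: int = 2,
) -> list[WinnerLoserCall]:
    """Winner/loser calls across taxonomic ranks.

    The class-level run uses the full effect table; order, family and genus
    run on the component subsets in :data:`RANK_SUBSET_GROUPS`. Levels with
    fewer than ``min_effects_per_level`` effects are skipped.
    """
    calls: list[WinnerLoserCall] = []
    for rank in ranks:
        if rank == "class":
            subsets = [effects]
        else:
            subsets = [
                [e for e in effects if e.component in comps]
                for comps in RANK_SUBSET_GROUPS.values()
            ]
        seen: set[str] = set()
        for sub in subsets:
            sub = [
                e
                for e in sub
                if not e.taxonomy_missing and e.taxonomy.get(rank)
            ]
            counts = pd.Series([e.taxonomy[rank] for e in sub]).value_counts()
            keep = set(counts[counts >= min_effects_per_level].index)
            sub = [e for e in sub if e.taxonomy[rank] in keep]
            if len(sub) < 2 or len({e.taxonomy[rank] for e in sub}) < 1:
                continue
            try:
                res = reml_multilevel(sub, moderator=rank, intercept=False)
            except ValueError:
                continue
            for call in winners_losers(res, rank=rank):
                if call.label not in seen:
                    seen.add(call.label)
                    calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# Dendrogram export


def annotate_taxonomy_tree(
    calls: list[WinnerLoserCall],
    taxonomy: dict[str, TaxonomyEntry],
) -> "dendropy.Tree":
    """Taxonomy hierarchy (kingdom → genus) as a dendropy tree whose node
    labels carry the winner/loser call.

    Branch lengths are all 1 — the dendrogram encodes classification, not
    evolutionary distance. Node labels are ``name|positive``,
    ``name|negative`` or ``name|none``.
    """
    import dendropy

    call_map = {(c.rank, c.label): c.call for c in calls}
    translate = {"winner": "positive", "loser": "negative", "neutral": "none"}

    tree = dendropy.Tree()
    root = tree.seed_node
    root.label = "root|none"
    nodes: dict[tuple[str, ...], "dendropy.Node"] = {(): root}
    ranks = TAXONOMIC_RANKS[:6]  # kingdom..genus
    for entry in taxonomy.values():
        path = entry.rank_path()[:6]
        for depth in range(1, 7):
            prefix = path[:depth]
            if not prefix[-1]:
                break
            if prefix in nodes:
                continue
            parent = nodes[prefix[:-1]]
            node = parent.new_child(edge_length=1.0)
            rank = ranks[depth - 1]
            call = call_map.get((rank, prefix[-1]), None)
            label = translate.get(call, "none") if call else "none"
            node.label = f"{prefix[-1]}|{label}"
            if not node.taxon and depth == 6:
                node.taxon = None
            nodes[prefix] = node
    return tree


def write_tree(tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        suppress_leaf_node_labels=False,
    )


def meta_results_frame(results: list[MetaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "level": [r.level for r in results],
            "estimate": [r.estimate for r in results],
            "se": [r.se for r in results],
            "zval": [r.zval for r in results],
            "ci_lower": [r.ci_lower for r in results],
            "ci_upper": [r.ci_upper for r in results],
            "p": [r.p for r in results],
            "sigma2_station": [r.sigma2_station for r in results],
            "k": [r.k for r in results],
            "n_species": [r.n_species for r in results],
        }
    )


def calls_frame(calls: list[WinnerLoserCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": [c.rank for c in calls],
            "label": [c.label for c in calls],
            "call": [c.call for c in calls],
            "estimate": [c.estimate for c in calls],
            "ci_lower": [c.ci_lower for c in calls],
            "ci_upper": [c.ci_upper for c in calls],
            "k": [c.k for c in calls],
        }
    )
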