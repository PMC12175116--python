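"""Synthetic monitoring-data generator with known ground truth.

Emulates the statistical structure the trend-synthesis pipeline assumes:
several ecosystem components monitored at multiple stations, population
series of 5–91 years (median near 30), trend shapes drawn from the nine
archetypes (defined on the ln(abundance+1) or log-count scale), and noise
from a Gaussian-on-log, Poisson, or overdispersed (gamma-Poisson) family.
Every generated population carries its generating archetype and parameters,
so classification, meta-analysis and timeline recovery can all be scored
against truth.

Presets: ``null`` (all neutral — the calibration scenario), ``mixed`` (a
vote-count-like mixture of all nine archetypes across six components),
``classbias`` (two taxonomic classes with opposite true mean slopes ±0.05,
the meta-analysis recovery scenario), and ``flip`` (all populations peak and
reverse at a programmed year, the timeline scenario).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import KNOWN_COMPONENTS, PopulationSeries

ARCHETYPES = (
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

#: archetype mixture echoing the observed distribution of trend types in
#: large multi-program monitoring syntheses: ~61% neutral, more negative
#: than positive directional trends, a minority of unimodal reversals
MIXED_ARCHETYPE_MIX = {
    "neutral": 0.609,
    "positive_linear": 0.050,
    "positive_accelerating": 0.030,
    "positive_decelerating": 0.036,
    "negative_linear": 0.080,
    "negative_accelerating": 0.050,
    "negative_decelerating": 0.056,
    "unimodal_pos_to_neg": 0.055,
    "unimodal_neg_to_pos": 0.034,
}

DEFAULT_NOISE_BY_COMPONENT = {
    "phytoplankton": "lognormal",
    "zooplankton": "poisson",
    "macrozoobenthos": "negbin",
    "fish": "negbin",
    "birds": "poisson",
    "plants": "lognormal",
}


def archetype_params(
    archetype: str,
    span: float,
    *,
    slope: float = 0.1,
    amplitude: float = 1.5,
    baseline: float = 3.0,
    vertex_frac: float = 0.5,
) -> tuple[float, float, float]:
    """Polynomial coefficients (b0, b1, b2) on the log scale for one
    archetype over a period of ``span`` years.

    ``slope`` is the per-year log-scale rate of the directional archetypes,
    ``amplitude`` the rise (or dip) of the unimodal archetypes between an
    endpoint and the vertex, placed at ``vertex_frac`` of the period.
    Decelerating trends put the vertex at 1.25x the period, safely outside
    the observed range; baselines of declining archetypes are raised so the
    series ends near ``baseline``.
    """
    T = float(max(span, 1.0))
    if archetype == "neutral":
        return baseline, 0.0, 0.0
    if archetype == "positive_linear":
        return baseline, slope, 0.0
    if archetype == "negative_linear":
        return baseline + slope * T, -slope, 0.0
    if archetype == "positive_accelerating":
        return baseline, slope / 4.0, slope / (2.0 * T)
    if archetype == "negative_accelerating":
        return baseline + 0.75 * slope * T, -slope / 4.0, -slope / (2.0 * T)
    if archetype == "positive_decelerating":
        # vertex at 1.25 T: still rising at the end, but ever more slowly
        return baseline, slope, -0.4 * slope / T
    if archetype == "negative_decelerating":
        return baseline + 0.6 * slope * T, -slope, 0.4 * slope / T
    if archetype == "unimodal_pos_to_neg":
        b2 = -amplitude / (vertex_frac * T) ** 2
        b1 = -2.0 * b2 * vertex_frac * T
        return baseline, b1, b2
    if archetype == "unimodal_neg_to_pos":
        b2 = amplitude / (vertex_frac * T) ** 2
        b1 = -2.0 * b2 * vertex_frac * T
        return baseline + amplitude, b1, b2
    raise ValueError(f"unknown archetype {archetype!r}")


def simulate_population(
    archetype: str,
    years: np.ndarray,
    noise_family: str = "lognormal",
    rng: np.random.Generator | None = None,
    *,
    sigma: float = 0.3,
    nb_dispersion: float = 0.5,
    station_id: str = "s1",
    taxon_id: str = "t1",
    component: str = "",
    **params,
) -> tuple[PopulationSeries, dict]:
    """Simulate one population series plus its ground truth.

    The mean curve mu(t) is the archetype polynomial on the ln(x+1) scale
    (lognormal family: abundance exp(mu + sigma*eps) - 1) or the log-count
    scale (count families: mean exp(mu)). ``sigma=0`` with the lognormal
    family gives the exact noiseless curve.
    """
    rng = rng or np.random.default_rng()
    years = np.asarray(years, dtype=int)
    t = (years - years[0]).astype(float)
    b0, b1, b2 = archetype_params(archetype, t[-1] if len(t) > 1 else 1.0, **params)
    mu = b0 + b1 * t + b2 * t * t
    if np.any(mu < -30):
        raise ValueError("archetype parameters drive the log-mean below floor")

    if noise_family == "lognormal":
        eps = rng.normal(0.0, sigma, size=len(t)) if sigma > 0 else 0.0
        values = np.maximum(np.exp(mu + eps) - 1.0, 0.0)
    elif noise_family == "poisson":
        values = rng.poisson(np.exp(mu)).astype(float)
    elif noise_family == "negbin":
        mean = np.exp(mu)
        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, mean * nb_dispersion)
        values = rng.poisson(lam).astype(float)
    else:
        raise ValueError(f"unknown noise family {noise_family!r}")

    series = PopulationSeries(
        station_id=station_id,
        taxon_id=taxon_id,
        years=years,
        values=values,
        component=component,
    )
    vertex = None
    if b2 != 0.0:
        vertex = float(years[0] - b1 / (2.0 * b2))
    truth = {
        "archetype": archetype,
        "b0": b0,
        "b1": b1,
        "b2": b2,
        "vertex_year": vertex,
        "noise_family": noise_family,
        "sigma": sigma,
    }
    return series, truth


# ---------------------------------------------------------------------------
# Seascape-scale scenarios


@dataclasses.dataclass
class ScenarioConfig:
    """Shape and intensity parameters of a simulated seascape."""

    components: tuple[str, ...] = KNOWN_COMPONENTS
    stations_per_component: int = 3
    species_per_component: int = 15
    classes_per_component: int = 1
    archetype_mix: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(MIXED_ARCHETYPE_MIX)
    )
    #: series lengths: log-normal with this median, clipped to the range
    length_range: tuple[int, int] = (5, 91)
    length_median: int = 30
    length_log_sd: float = 0.42
    fixed_length: int | None = None
    end_year: int = 2020
    gap_rate: float = 0.1
    slope: float = 0.1
    amplitude: float = 1.5
    baseline: float = 3.0
    sigma: float = 0.3
    nb_dispersion: float = 0.5
    noise_by_component: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_NOISE_BY_COMPONENT)
    )
    #: per-class true mean slope (linear archetypes drawn around it); when
    #: set, overrides the archetype mix with linear trends
    class_mean_slopes: dict[str, float] | None = None
    slope_sd: float = 0.02
    vertex_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype mix sums to {total}, not 1")
        if self.length_range[0] < 5:
            raise ValueError("minimum series length is 5")


@dataclasses.dataclass
class SeascapeData:
    monitoring: pd.DataFrame
    taxonomy: pd.DataFrame
    truth: pd.DataFrame
    config: ScenarioConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.monitoring.to_csv(outdir / "monitoring.csv", index=False)
        self.taxonomy.to_csv(outdir / "taxonomy.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)


def _balanced_taxonomy(config: ScenarioConfig) -> pd.DataFrame:
    """Abstractly-labelled balanced taxonomy (no real taxon names)."""
    rows = []
    for ci, comp in enumerate(config.components):
        kingdom = f"Kingdom_{'AB'[ci % 2]}"
        phylum = f"Phylum_{comp}"
        n = config.species_per_component
        for si in range(n):
            cls = f"Class_{comp}_{si % config.classes_per_component}"
            rows.append(
                {
                    "taxon_id": f"{comp}_sp{si:03d}",
                    "kingdom": kingdom,
                    "phylum": phylum,
                    "class": cls,
                    "order": f"Order_{comp}_{si // 8}",
                    "family": f"Family_{comp}_{si // 4}",
                    "genus": f"Genus_{comp}_{si // 2}",
                    "species": f"{comp}_sp{si:03d}",
                }
            )
    return pd.DataFrame(rows)


def _sample_years(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.length_range
    if config.fixed_length is not None:
        length = config.fixed_length
    else:
        length = int(
            np.clip(
                np.rint(np.exp(rng.normal(np.log(config.length_median), config.length_log_sd))),
                lo,
                hi,
            )
        )
    start = config.end_year - length + 1
    years = np.arange(start, config.end_year + 1)
    if config.gap_rate > 0 and length > 6:
        # drop interior years at the gap rate, keeping endpoints (span) and
        # at least 50% presence so the series still passes inclusion
        interior = years[1:-1]
        max_drop = length - max(5, int(np.ceil(length / 2.0)))
        drop = rng.random(len(interior)) < config.gap_rate
        if drop.sum() > max_drop:
            keep_ix = rng.choice(np.where(drop)[0], size=int(drop.sum() - max_drop), replace=False)
            drop[keep_ix] = False
        years = np.concatenate([[years[0]], interior[~drop], [years[-1]]])
    return years


def simulate_seascape(config: ScenarioConfig) -> SeascapeData:
    """Generate a full long-format monitoring table, taxonomy and truth.

    Deterministic for a given config (including its seed): identical CSV
    output byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    taxonomy = _balanced_taxonomy(config)
    class_of = dict(zip(taxonomy["taxon_id"], taxonomy["class"]))
    archetypes = list(config.archetype_mix)
    probs = np.array([config.archetype_mix[a] for a in archetypes])

    monitor_rows = []
    truth_rows = []
    for comp in config.components:
        noise = config.noise_by_component.get(comp, "lognormal")
        for st in range(config.stations_per_component):
            station = f"{comp}_st{st:02d}"
            for si in range(config.species_per_component):
                taxon = f"{comp}_sp{si:03d}"
                years = _sample_years(config, rng)
                kwargs = dict(
                    slope=config.slope,
                    amplitude=config.amplitude,
                    baseline=config.baseline,
                    vertex_frac=config.vertex_frac,
                )
                if config.class_mean_slopes is not None:
                    mean = config.class_mean_slopes.get(class_of[taxon], 0.0)
                    drawn = rng.normal(mean, config.slope_sd)
                    archetype = (
                        "positive_linear" if drawn >= 0 else "negative_linear"
                    )
                    kwargs["slope"] = abs(drawn)
                else:
                    archetype = archetypes[rng.choice(len(archetypes), p=probs)]
                series, truth = simulate_population(
                    archetype,
                    years,
                    noise,
                    rng,
                    sigma=config.sigma,
                    nb_dispersion=config.nb_dispersion,
                    station_id=station,
                    taxon_id=taxon,
                    component=comp,
                    **kwargs,
                )
                for y, val in zip(series.years, series.values):
                    monitor_rows.append(
                        {
                            "station": station,
                            "taxon": taxon,
                            "year": int(y),
                            "abundance": float(val),
                            "component": comp,
                        }
                    )
                truth_rows.append(
                    {
                        "station": station,
                        "taxon": taxon,
                        "component": comp,
                        "class": class_of[taxon],
                        "n_obs": series.n_obs,
                        "span": series.span,
                        "first_year": int(series.years[0]),
                        **truth,
                    }
                )
    return SeascapeData(
        monitoring=pd.DataFrame(monitor_rows),
        taxonomy=taxonomy,
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def preset_config(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Named study scenarios.

    ``null``: every population neutral — directional classifications are
    pure type-I error. ``mixed``: the nine-archetype mixture over all six
    components. ``classbias``: one component, two classes with true mean
    slopes +0.05 and -0.05 across 30 stations. ``flip``: one bird-like
    component whose populations all rise then decline with the vertex at a
    programmed year of a 31-year window.
    """
    if name == "null":
        cfg = ScenarioConfig(
            archetype_mix={"neutral": 1.0},
            seed=seed,
        )
    elif name == "mixed":
        cfg = ScenarioConfig(seed=seed)
    elif name == "classbias":
        cfg = ScenarioConfig(
            components=("macrozoobenthos",),
            stations_per_component=30,
            species_per_component=8,
            classes_per_component=2,
            noise_by_component={"macrozoobenthos": "lognormal"},
            class_mean_slopes={
                "Class_macrozoobenthos_0": 0.05,
                "Class_macrozoobenthos_1": -0.05,
            },
            sigma=0.2,
            fixed_length=31,
            gap_rate=0.0,
            seed=seed,
        )
    elif name == "flip":
        cfg = ScenarioConfig(
            components=("birds",),
            stations_per_component=2,
            species_per_component=10,
            archetype_mix={"unimodal_pos_to_neg": 1.0},
            noise_by_component={"birds": "lognormal"},
            sigma=0.3,
            amplitude=1.5,
            fixed_length=31,
            gap_rate=0.0,
            vertex_frac=0.5,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return dataclasses.replace(cfg, **overrides)
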