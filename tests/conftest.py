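import numpy as np
import pytest

from seatrend.data_model import PopulationSeries
from seatrend.trend_fitting import CandidateFit, TrendClassification


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_series(values, start_year=2000, station="s1", taxon="t1", component="fish"):
    values = np.asarray(values, dtype=float)
    return PopulationSeries(
        station_id=station,
        taxon_id=taxon,
        years=np.arange(start_year, start_year + len(values)),
        values=values,
        component=component,
    )


def make_classification(
    trend_type="neutral",
    n_obs=20,
    span=20,
    station="s1",
    taxon="t1",
    component="fish",
    any_valid=True,
    beta1=0.0,
    beta2=None,
    se_beta1=0.02,
    first_year=2000,
    gaussian_valid=True,
):
    """Hand-built classification for downstream-stage tests."""
    degree = 1 if beta2 is None else 2
    chosen = None
    if trend_type != "neutral":
        chosen = CandidateFit(
            family="gaussian_ln",
            degree=degree,
            beta0=2.0,
            beta1=beta1,
            beta2=beta2,
            se_beta1=se_beta1,
            se_beta2=0.005 if degree == 2 else None,
            slope_p=0.001,
            converged=True,
            normality_ok=True,
            homoscedasticity_ok=True,
        )
    glin = CandidateFit(
        family="gaussian_ln",
        degree=1,
        beta0=2.0,
        beta1=beta1,
        se_beta1=se_beta1,
        slope_p=0.001 if trend_type != "neutral" else 0.5,
        converged=True,
        normality_ok=gaussian_valid,
        homoscedasticity_ok=True,
    )
    fits = [glin] + ([chosen] if chosen is not None and degree == 2 else [])
    if chosen is not None and degree == 1:
        fits = [chosen]
    return TrendClassification(
        station_id=station,
        taxon_id=taxon,
        component=component,
        n_obs=n_obs,
        span=span,
        first_year=first_year,
        trend_type=trend_type,
        chosen=chosen,
        mode_year=None,
        any_valid_model=any_valid,
        fits=fits,
    )
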