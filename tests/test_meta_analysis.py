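"""REML multilevel meta-analysis, winner/loser calls, dendrogram export."""

import dendropy
import numpy as np
import pytest

from seatrend.data_model import TaxonomyEntry
from seatrend.meta_analysis import (
    EffectSize,
    WinnerLoserCall,
    _station_blocks,
    absolute_slope_meta,
    annotate_taxonomy_tree,
    build_effect_table,
    reml_multilevel,
    restricted_loglik,
    winners_losers,
)

from conftest import make_classification


def effect(slope, v=0.01, station="s1", taxon="t1", component="fish", cls="C1"):
    return EffectSize(
        slope=slope,
        variance=v,
        station_id=station,
        taxon_id=taxon,
        component=component,
        taxonomy={"class": cls},
    )


def grid_reml_estimate(effects, step=1e-6, upper=0.02):
    """Brute-force REML: densest 1-D grid over the between-station variance."""
    y = np.array([e.slope for e in effects])
    v = np.array([e.variance for e in effects])
    X = np.ones((len(effects), 1))
    blocks = _station_blocks(np.array([e.station_id for e in effects]))
    grid = np.arange(0.0, upper, step)
    lls = np.array([restricted_loglik(s2, y, v, X, blocks) for s2 in grid])
    s2 = grid[np.argmax(lls)]
    # GLS mean at the grid-optimal variance
    w = 1.0 / (v + s2)  # one effect per station in the oracle instances
    return float(np.sum(w * y) / np.sum(w)), float(s2)


class TestRemlCore:
    def test_zero_heterogeneity_recovers_common_value(self):
        effects = [effect(0.1, v=0.01, station=f"s{i}", taxon=f"t{i}") for i in range(3)]
        (res,) = reml_multilevel(effects)
        assert res.estimate == pytest.approx(0.1, abs=1e-10)
        assert res.sigma2_station == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_oracle_on_small_instances(self, rng):
        for _ in range(5):
            k = int(rng.integers(4, 9))
            effects = [
                effect(
                    float(rng.normal(0.05, 0.05)),
                    v=float(rng.uniform(1e-4, 1e-3)),
                    station=f"s{i}",
                    taxon=f"t{i}",
                )
                for i in range(k)
            ]
            (res,) = reml_multilevel(effects)
            oracle_mean, _ = grid_reml_estimate(effects)
            assert res.estimate == pytest.approx(oracle_mean, abs=1e-5)

    def test_estimate_equivariant_under_slope_shift(self, rng):
        effects = [
            effect(float(rng.normal(0, 0.05)), v=5e-4, station=f"s{i}", taxon=f"t{i}")
            for i in range(10)
        ]
        shifted = [
            effect(e.slope + 0.3, v=e.variance, station=e.station_id, taxon=e.taxon_id)
            for e in effects
        ]
        (a,) = reml_multilevel(effects)
        (b,) = reml_multilevel(shifted)
        assert b.estimate - a.estimate == pytest.approx(0.3, abs=1e-8)
        assert b.sigma2_station == pytest.approx(a.sigma2_station, abs=1e-8)

    def test_sigma2_zero_when_dispersion_within_sampling_variance(self, rng):
        # slopes drawn with spread well below their sampling SDs
        effects = [
            effect(float(rng.normal(0, 0.001)), v=0.01, station=f"s{i}", taxon=f"t{i}")
            for i in range(12)
        ]
        (res,) = reml_multilevel(effects)
        assert res.sigma2_station == 0.0

    def test_moderator_without_intercept_gives_level_means(self, rng):
        effects = []
        for i in range(20):
            effects.append(
                effect(
                    float(rng.normal(0.05, 0.01)), v=2e-4,
                    station=f"s{i % 6}", taxon=f"a{i}", cls="A",
                )
            )
            effects.append(
                effect(
                    float(rng.normal(-0.05, 0.01)), v=2e-4,
                    station=f"s{i % 6}", taxon=f"b{i}", cls="B",
                )
            )
        res = reml_multilevel(effects, moderator="class", intercept=False)
        by = {r.level: r for r in res}
        assert by["A"].estimate == pytest.approx(0.05, abs=0.02)
        assert by["B"].estimate == pytest.approx(-0.05, abs=0.02)
        assert by["A"].k == 20 and by["A"].n_species == 20


class TestAbsoluteSlopeMeta:
    def test_sign_cancellation_collapses_under_absolute_value(self):
        effects = [
            effect(-0.1, v=0.001, station="s1", taxon="a"),
            effect(0.1, v=0.001, station="s2", taxon="b"),
        ]
        res = absolute_slope_meta(effects)
        assert res.estimate == pytest.approx(0.1, abs=1e-8)

    def test_all_zero_slopes(self):
        effects = [effect(0.0, station=f"s{i}", taxon=f"t{i}") for i in range(3)]
        assert absolute_slope_meta(effects).estimate == pytest.approx(0.0, abs=1e-10)


class TestWinnersLosers:
    def test_calls_follow_ci_signs(self):
        from seatrend.meta_analysis import MetaResult

        mk = lambda lo, hi: MetaResult(
            "x", (lo + hi) / 2, 0.01, 1.0, lo, hi, 0.05, 0.0, 5, 3
        )
        assert winners_losers([mk(0.01, 0.05)])[0].call == "winner"
        assert winners_losers([mk(-0.02, 0.03)])[0].call == "neutral"
        assert winners_losers([mk(-0.09, -0.01)])[0].call == "loser"

    def test_antisymmetric_under_slope_negation(self, rng):
        effects = [
            effect(float(rng.normal(0.08, 0.01)), v=2e-4, station=f"s{i}", taxon=f"t{i}")
            for i in range(10)
        ]
        negated = [
            effect(-e.slope, v=e.variance, station=e.station_id, taxon=e.taxon_id)
            for e in effects
        ]
        call_pos = winners_losers(reml_multilevel(effects))[0].call
        call_neg = winners_losers(reml_multilevel(negated))[0].call
        assert {call_pos, call_neg} == {"winner", "loser"}


class TestEffectTable:
    def test_invalid_gaussian_linear_excluded(self):
        cs = [
            make_classification("positive_linear", beta1=0.1, taxon="a"),
            make_classification("neutral", taxon="b", gaussian_valid=False),
        ]
        effects = build_effect_table(cs)
        assert [e.taxon_id for e in effects] == ["a"]

    def test_variance_is_squared_se(self):
        cs = [make_classification("positive_linear", beta1=0.1, se_beta1=0.02)]
        (e,) = build_effect_table(cs)
        assert e.variance == pytest.approx(4e-4)

    def test_slope_taken_from_gaussian_linear_even_if_not_chosen(self):
        # best model is quadratic, but the (valid) linear Gaussian slope enters
        c = make_classification("unimodal_pos_to_neg", beta1=0.07, beta2=-0.01)
        (e,) = build_effect_table([c])
        assert e.slope == pytest.approx(0.07)

    def test_missing_taxonomy_flagged_and_dropped_from_rank_runs(self):
        cs = [
            make_classification("positive_linear", beta1=0.1, taxon=f"t{i}", station=f"s{i}")
            for i in range(4)
        ]
        taxonomy = {
            "t0": TaxonomyEntry("t0", "K", "P", "C", "O", "F", "G", "t0"),
            "t1": TaxonomyEntry("t1", "K", "P", "C", "O", "F", "G", "t1"),
        }
        effects = build_effect_table(cs, taxonomy)
        assert sum(e.taxonomy_missing for e in effects) == 2
        res = reml_multilevel(effects, moderator="class", intercept=False)
        assert res[0].k == 2


class TestDendrogram:
    taxonomy = {
        "t1": TaxonomyEntry("t1", "K", "P", "C1", "O1", "F1", "G1", "t1"),
        "t2": TaxonomyEntry("t2", "K", "P", "C1", "O1", "F2", "G2", "t2"),
    }

    def test_winner_label_attached(self):
        calls = [WinnerLoserCall("G1", "genus", "winner", 0.1, 0.05, 0.15, 4)]
        tree = annotate_taxonomy_tree(calls, self.taxonomy)
        labels = {n.label for n in tree if n.label}
        assert "G1|positive" in labels
        assert "G2|none" in labels

    def test_unit_branch_lengths(self):
        tree = annotate_taxonomy_tree([], self.taxonomy)
        assert all(
            e.length == 1.0 for e in tree.edges() if e.head_node is not tree.seed_node
        )

    def test_newick_round_trip_topology(self, tmp_path):
        from seatrend.meta_analysis import write_tree

        tree = annotate_taxonomy_tree([], self.taxonomy)
        p = tmp_path / "tree.nwk"
        write_tree(tree, p)
        back = dendropy.Tree.get(path=str(p), schema="newick")
        assert len(back.leaf_nodes()) == len(tree.leaf_nodes())
        labels = {
            (n.taxon.label if n.taxon else n.label) for n in back
        }
        assert labels >= {"G1|none", "G2|none"}
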