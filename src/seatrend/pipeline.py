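"""End-to-end orchestration: monitoring table in, result tables out."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import meta_analysis, temporal_trends, trend_fitting, vote_and_duration
from .data_model import (
    MonitoringRecord,
    aggregate_annual_means,
    inclusion_filter,
    read_monitoring_csv,
    read_taxonomy_csv,
    write_table,
)

logger = logging.getLogger("seatrend")


def records_from_frame(df: pd.DataFrame) -> list[MonitoringRecord]:
    return [
        MonitoringRecord(
            station_id=str(r.station),
            taxon_id=str(r.taxon),
            year=int(r.year),
            abundance=float(r.abundance),
            component=str(getattr(r, "component", "")),
        )
        for r in df.itertuples()
    ]


def classify_all(
    records: list[MonitoringRecord],
    families=trend_fitting.FAMILIES,
) -> list[trend_fitting.TrendClassification]:
    """Aggregate, filter and classify every population in the dataset."""
    series = aggregate_annual_means(records)
    kept = [s for s in series if inclusion_filter(s)]
    logger.info("classifying %d/%d populations", len(kept), len(series))
    return [trend_fitting.classify_trend(s, families=families) for s in kept]


def run_pipeline(
    monitoring_csv: str | Path,
    taxonomy_csv: str | Path | None,
    outdir: str | Path,
    *,
    schema: dict | None = None,
    timeline_rank: str = "class",
    bootstrap_B: int = 1000,
    seed: int = 0,
) -> dict:
    """Full synthesis: classification, vote count, duration models,
    meta-analysis with winner/loser calls, and group timelines.

    Writes trends.csv, votecount.csv, effects.csv, meta.csv, calls.csv,
    timeline.csv, duration_models.json and tree.nwk under ``outdir``; returns
    the in-memory results keyed by stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, report = read_monitoring_csv(monitoring_csv, schema)
    taxonomy = read_taxonomy_csv(taxonomy_csv) if taxonomy_csv else None

    classifications = classify_all(records)
    trends = trend_fitting.classifications_to_frame(classifications)
    write_table(trends, outdir / "trends.csv")

    votes = pd.concat(
        [
            vote_and_duration.weighted_vote_count(classifications),
            vote_and_duration.weighted_vote_count(classifications, by_component=True),
        ],
        ignore_index=True,
    )
    write_table(votes, outdir / "votecount.csv")

    detection = vote_and_duration.detection_vs_duration(classifications)
    validity = vote_and_duration.validity_vs_duration(classifications)
    (outdir / "duration_models.json").write_text(
        '{"detection": %s, "validity": %s}' % (detection.to_json(), validity.to_json())
    )

    effects = meta_analysis.build_effect_table(classifications, taxonomy)
    effects_df = pd.DataFrame(
        {
            "station": [e.station_id for e in effects],
            "taxon": [e.taxon_id for e in effects],
            "component": [e.component for e in effects],
            "slope": [e.slope for e in effects],
            "variance": [e.variance for e in effects],
        }
    )
    write_table(effects_df, outdir / "effects.csv")

    meta_rows = meta_analysis.reml_multilevel(effects)
    meta_rows.append(meta_analysis.absolute_slope_meta(effects))
    if len({e.component for e in effects}) > 1:
        meta_rows += meta_analysis.reml_multilevel(
            effects, moderator="component", intercept=False
        )
    meta_df = meta_analysis.meta_results_frame(meta_rows)
    write_table(meta_df, outdir / "meta.csv")

    calls = []
    if taxonomy is not None:
        calls = meta_analysis.rank_winners_losers(effects)
        write_table(meta_analysis.calls_frame(calls), outdir / "calls.csv")
        tree = meta_analysis.annotate_taxonomy_tree(calls, taxonomy)
        meta_analysis.write_tree(tree, outdir / "tree.nwk")

    group_of = {}
    if taxonomy is not None:
        rank_attr = {"class": "class_"}.get(timeline_rank, timeline_rank)
        group_of = {
            tid: getattr(entry, rank_attr) for tid, entry in taxonomy.items()
        }
    else:
        group_of = {c.taxon_id: c.component for c in classifications}
    timelines = temporal_trends.group_timelines(
        classifications, group_of, B=bootstrap_B, seed=seed
    )
    if timelines:
        timeline_df = pd.concat(
            [df.assign(group=g) for g, df in timelines.items()], ignore_index=True
        )
        write_table(timeline_df, outdir / "timeline.csv")

    return {
        "ingest_report": report,
        "classifications": classifications,
        "votes": votes,
        "detection": detection,
        "validity": validity,
        "effects": effects,
        "meta": meta_rows,
        "calls": calls,
        "timelines": timelines,
    }
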