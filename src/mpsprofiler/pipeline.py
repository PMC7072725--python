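"""End-to-end orchestration: quantification, testing, profiling, overlaps.

``run_pipeline`` wires the stages in order and returns a ``ResultBundle``
holding every output table; ``ResultBundle.write`` serialises them as TSVs
with a fixed column order.  Given identical inputs the bundle is
deterministic, and the serialised files are byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .crosstype import extreme_genes, pairwise_overlaps, recurrence_table
from .design import RunConfig, SampleSheet
from .diffexp import DEResults, DifferentialExpressionModel
from .io import write_table
from .ontology import (
    GoAnnotationSet,
    GoDag,
    assign_to_processes,
    profile_processes,
    strong_processes,
)
from .quantify import ExpressionMatrix

__all__ = ["run_pipeline", "ResultBundle"]

log = logging.getLogger(__name__)


@dataclass
class ResultBundle:
    """All output tables of one pipeline run."""

    config: RunConfig
    de: DEResults
    de_table: pd.DataFrame
    skipped: pd.DataFrame
    counts_by_tier: dict[str, pd.DataFrame]
    calls_by_tier: dict[str, pd.DataFrame]
    profiles_by_tier: dict[str, pd.DataFrame]
    strong: pd.DataFrame
    overlaps_long: pd.DataFrame
    overlap_matrices: dict[str, pd.DataFrame]
    extreme_counts: pd.DataFrame
    recurrence: pd.DataFrame
    unassigned_features: pd.DataFrame

    def write(self, outdir) -> list[Path]:
        """Serialise every table as TSV under ``outdir``; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def emit(df: pd.DataFrame, name: str, index: bool = False):
            p = outdir / name
            write_table(df, p, index=index)
            written.append(p)

        emit(self.de_table.reset_index(), "de_table.tsv")
        emit(self.skipped, "skipped_features.tsv")
        for tier, df in sorted(self.counts_by_tier.items()):
            emit(df.reset_index(), f"counts_{tier}.tsv")
        for tier, df in sorted(self.calls_by_tier.items()):
            emit(df, f"calls_{tier}.tsv")
        for tier, df in sorted(self.profiles_by_tier.items()):
            emit(df, f"process_profile_{tier}.tsv")
        emit(self.strong, "strong_processes.tsv")
        emit(self.overlaps_long, "overlaps_chord.tsv")
        emit(self.extreme_counts.reset_index(), "extreme_counts.tsv")
        emit(self.recurrence, "recurrence.tsv")
        emit(self.unassigned_features, "unassigned_features.tsv")
        return written


def run_pipeline(
    config: RunConfig,
    counts: ExpressionMatrix,
    lengths: Mapping[str, int],
    sheet: SampleSheet,
    dag: GoDag,
    annotations: GoAnnotationSet,
    feature_to_gene: Optional[Mapping[str, str]] = None,
) -> ResultBundle:
    """Run quantification, testing, GO profiling and cross-type analyses."""
    if counts.counts is None:
        raise ValueError("pipeline requires a counts layer")
    f2g = dict(feature_to_gene) if (
        feature_to_gene is not None and config.counting_unit == "gene"
    ) else None

    log.info("quantification: %d features x %d samples",
             counts.n_features, len(sheet))
    model = DifferentialExpressionModel.from_counts(
        counts.counts, lengths, sheet,
        tiers=config.tiers, pseudocount=config.pseudocount,
    )
    de = model.fit()
    log.info("diffexp: %d tested, %d skipped, %d contrasts",
             len(de.table), len(de.skipped), len(de.groups))

    counts_by_tier = {t.name: de.counts(t) for t in config.tiers}
    calls_by_tier = {t.name: de.calls(t) for t in config.tiers}

    children = dag.direct_children()
    assignment, _unassigned_genes = assign_to_processes(
        annotations, dag, children
    )
    log.info("go_profiling: %d direct children of %s, %d annotated genes",
             len(children), dag.root, len(annotations.genes))

    profiles = {}
    for tier in config.tiers:
        prof = profile_processes(calls_by_tier[tier.name], assignment, f2g)
        profiles[tier.name] = prof

    tier2 = config.tier("tier2") if _has_tier(config, "tier2") else config.tiers[-1]
    strong = strong_processes(profiles[tier2.name], config.strong_process_min)
    log.info("strong processes (>=%d changed at %s): %d rows",
             config.strong_process_min, tier2.name, len(strong))

    groups = sheet.noncontrol_groups
    tier2_calls = calls_by_tier[tier2.name]
    mats: dict[str, pd.DataFrame] = {}
    longs = []
    for process in children:
        members = assignment[process]
        sets = {}
        for g in groups:
            feats = tier2_calls.loc[tier2_calls["group"] == g, "feature"]
            genes = {f2g.get(f, f) for f in feats} if f2g else set(feats)
            sets[g] = {x for x in genes if x in members}
        mat, long = pairwise_overlaps(sets, process=process)
        mats[process] = mat
        longs.append(long)
    overlaps_long = (
        pd.concat(longs, ignore_index=True)
        if longs else pd.DataFrame(columns=["process", "group_a", "group_b",
                                            "n_common"])
    )
    log.info("cross_type: overlap matrices for %d processes", len(mats))

    tier3 = config.tier("tier3") if _has_tier(config, "tier3") else config.tiers[-1]
    extreme, extreme_counts = extreme_genes(de.table, tier3, groups, f2g)
    recurrence = recurrence_table(extreme, config.recurrence_min_types)
    log.info("extreme genes at %s: %d total calls; %d recurrent genes",
             tier3.name, int(extreme_counts["n_total"].sum()), len(recurrence))

    tested = set(de.table.index)
    assigned_any = set().union(*assignment.values()) if assignment else set()
    feats_as_genes = {
        f: (f2g.get(f, f) if f2g else f) for f in tested
    }
    unassigned = sorted(
        f for f, g in feats_as_genes.items() if g not in assigned_any
    )
    unassigned_df = pd.DataFrame({"feature": unassigned})

    return ResultBundle(
        config=config,
        de=de,
        de_table=de.table,
        skipped=de.skipped,
        counts_by_tier=counts_by_tier,
        calls_by_tier=calls_by_tier,
        profiles_by_tier=profiles,
        strong=strong,
        overlaps_long=overlaps_long,
        overlap_matrices=mats,
        extreme_counts=extreme_counts,
        recurrence=recurrence,
        unassigned_features=unassigned_df,
    )


def _has_tier(config: RunConfig, name: str) -> bool:
    return any(t.name == name for t in config.tiers)
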