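"""Cross-type comparisons: common changed genes between disease groups
(chord-diagram matrices), extreme fold-change genes and their recurrence
across types.

Overlaps are computed at the gene level and are direction-agnostic by
default: a gene changed up in one type and down in another still counts as
common (direction is retained in the recurrence marks instead).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import SignificanceTier

__all__ = [
    "changed_sets",
    "pairwise_overlaps",
    "extreme_genes",
    "recurrence_table",
]


def _collapse(features, feature_to_gene: Optional[Mapping[str, str]]):
    if feature_to_gene is None:
        return set(features)
    return {feature_to_gene.get(f, f) for f in features}


def changed_sets(
    calls: pd.DataFrame,
    assignment: Mapping[str, set[str]],
    process: str,
    groups: Sequence[str],
    feature_to_gene: Optional[Mapping[str, str]] = None,
    direction_matched: Optional[str] = None,
) -> dict[str, set[str]]:
    """Per-group sets of genes assigned to ``process`` and called significant.

    ``direction_matched`` restricts to "up" or "down" calls; the default keeps
    any direction (the common-gene counts are direction-agnostic).
    """
    if process not in assignment:
        raise KeyError(f"unknown process {process!r}")
    members = assignment[process]
    work = calls
    if direction_matched is not None:
        work = work[work["direction"] == direction_matched]
    out: dict[str, set[str]] = {}
    for g in groups:
        feats = work.loc[work["group"] == g, "feature"]
        genes = _collapse(feats, feature_to_gene)
        out[g] = genes & members if feature_to_gene is None else {
            gene for gene in genes if gene in members
        }
    return out


def pairwise_overlaps(
    sets: Mapping[str, set[str]], process: Optional[str] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact pairwise intersection cardinalities between group gene sets.

    Returns the symmetric matrix (diagonal = set sizes) and a long-format
    chord table (process, group_a, group_b, n_common) over unordered pairs
    with ``group_a < group_b`` in the given group order.
    """
    groups = list(sets)
    if len(groups) < 2:
        raise ValueError("need at least two groups for pairwise overlaps")
    mat = pd.DataFrame(0, index=pd.Index(groups, name="group"), columns=groups)
    rows = []
    for i, a in enumerate(groups):
        mat.loc[a, a] = len(sets[a])
        for b in groups[i + 1:]:
            n = len(sets[a] & sets[b])
            mat.loc[a, b] = n
            mat.loc[b, a] = n
            rows.append({
                "process": process if process is not None else "",
                "group_a": a,
                "group_b": b,
                "n_common": n,
            })
    long = pd.DataFrame(rows, columns=["process", "group_a", "group_b", "n_common"])
    return mat, long


def extreme_genes(
    table: pd.DataFrame,
    tier: SignificanceTier,
    groups: Sequence[str],
    feature_to_gene: Optional[Mapping[str, str]] = None,
) -> tuple[dict[str, dict[str, set[str]]], pd.DataFrame]:
    """Per-group up/down gene lists at the extreme tier.

    The fold-change gate is strict: ``|log2fc| > tier.lfc_min`` (a gene at
    exactly the threshold is excluded).  Returns ``{group: {"up": set,
    "down": set}}`` plus a counts table (group, n_up, n_down, n_total).
    """
    lists: dict[str, dict[str, set[str]]] = {}
    q = table["q_bh"].to_numpy()
    rows = []
    for g in groups:
        lfc = table[f"log2fc_{g}"].to_numpy()
        gate = (q < tier.fdr_max) & (table[f"p_bonf_{g}"].to_numpy() < tier.p_max)
        up_feats = table.index[gate & (lfc > tier.lfc_min)]
        down_feats = table.index[gate & (lfc < -tier.lfc_min)]
        up = _collapse(up_feats, feature_to_gene)
        down = _collapse(down_feats, feature_to_gene)
        lists[g] = {"up": up, "down": down}
        rows.append({
            "group": g,
            "n_up": len(up),
            "n_down": len(down),
            "n_total": len(up | down),
        })
    counts = pd.DataFrame(rows).set_index("group")
    return lists, counts


def recurrence_table(
    extreme: Mapping[str, Mapping[str, set[str]]],
    min_types: int = 2,
) -> pd.DataFrame:
    """Genes extreme in at least ``min_types`` groups, with direction marks.

    Output: one row per recurrent gene, per-group mark columns in
    {"up", "down", "none"} and a ``recurrence`` column (number of non-none
    marks); sorted by recurrence descending, then gene id.  A gene both up
    and down in the same group (possible only after transcript collapse) is
    marked by the direction set in which it appears first (up).
    """
    if min_types < 2:
        raise ValueError("min_types must be >= 2")
    groups = list(extreme)
    marks: dict[str, dict[str, str]] = {}
    for g in groups:
        for direction in ("up", "down"):
            for gene in extreme[g][direction]:
                marks.setdefault(gene, {})
                marks[gene].setdefault(g, direction)
    rows = []
    for gene, gm in marks.items():
        rec = len(gm)
        if rec >= min_types:
            row = {"gene": gene, "recurrence": rec}
            for g in groups:
                row[g] = gm.get(g, "none")
            rows.append(row)
    cols = ["gene", "recurrence"] + groups
    out = pd.DataFrame(rows, columns=cols)
    if not out.empty:
        out = out.sort_values(
            ["recurrence", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return out
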