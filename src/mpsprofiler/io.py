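"""Readers and writers for every external format the pipeline touches.

All tabular outputs are TSV with a fixed column order; floats are serialised
with 6 significant digits so that re-runs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import obonet
import pandas as pd

from .design import SampleSheet
from .ontology import DEFAULT_ROOT, GoAnnotationSet, GoDag
from .qpcr import DEFAULT_REFERENCES, CtTable
from .quantify import ExpressionMatrix

__all__ = [
    "read_sample_sheet",
    "write_sample_sheet",
    "read_counts",
    "write_counts",
    "read_lengths",
    "write_lengths",
    "read_go",
    "write_go_edges",
    "write_annotations",
    "read_ct_table",
    "write_table",
]

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_sample_sheet(path: PathLike, control_group: str) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    return SampleSheet(df, control_group=control_group)


def write_sample_sheet(sheet: SampleSheet, path: PathLike) -> None:
    sheet.samples.to_csv(path, sep="\t", index=False)


def read_counts(path: PathLike, sheet: SampleSheet) -> ExpressionMatrix:
    """Read a feature x sample count TSV (header = sample ids).

    Columns are reordered to the sheet order; every sheet sample must be
    present, and every cell must be a non-negative integer.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in sheet.sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"count matrix missing sheet samples: {missing}")
    df = df[sheet.sample_ids]
    try:
        values = df.astype("int64")
    except (ValueError, TypeError) as exc:
        bad = df.map(lambda v: not float(v).is_integer() if _is_number(v) else True)
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise ValueError(
            f"non-integer count at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        ) from exc
    if (values.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative values")
    return ExpressionMatrix(values, sheet)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_counts(expr: ExpressionMatrix, path: PathLike) -> None:
    if expr.counts is None:
        raise ValueError("no counts layer to write")
    expr.counts.to_csv(path, sep="\t", index_label="feature")


def read_lengths(path: PathLike) -> dict[str, int]:
    """Feature lengths from a two-column TSV or a minimal GTF.

    GTF input (detected by the ``.gtf`` suffix or a 9-column body): feature
    length = sum of exon spans, coordinates 1-based inclusive, feature id
    taken from the ``transcript_id`` (falling back to ``gene_id``) attribute.
    Conflicting duplicate lengths raise.
    """
    path = Path(path)
    if path.suffix.lower() == ".gtf":
        return _lengths_from_gtf(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 9:
        return _lengths_from_gtf(path)
    if df.shape[1] < 2:
        raise ValueError("length table needs two columns: feature, length")
    # tolerate an optional header row
    if not str(df.iloc[0, 1]).lstrip("-").isdigit():
        df = df.iloc[1:]
    out: dict[str, int] = {}
    for feat, length in zip(df.iloc[:, 0], df.iloc[:, 1]):
        length = int(length)
        if length <= 0:
            raise ValueError(f"non-positive length for feature {feat!r}")
        if feat in out and out[feat] != length:
            raise ValueError(
                f"conflicting duplicate lengths for feature {feat!r}: "
                f"{out[feat]} vs {length}"
            )
        out[str(feat)] = length
    return out


def _lengths_from_gtf(path: Path) -> dict[str, int]:
    import re

    sums: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GTF line: {line.strip()!r}")
            feature_type = parts[2]
            if feature_type != "exon":
                continue
            start, end = int(parts[3]), int(parts[4])
            if end < start:
                raise ValueError(f"GTF exon with end < start: {line.strip()!r}")
            attrs = parts[8]
            m = re.search(r'transcript_id "([^"]+)"', attrs)
            if m is None:
                m = re.search(r'gene_id "([^"]+)"', attrs)
            if m is None:
                raise ValueError(f"GTF exon without transcript/gene id: {attrs!r}")
            sums[m.group(1)] = sums.get(m.group(1), 0) + (end - start + 1)
    if not sums:
        raise ValueError(f"no exon records found in {path}")
    return sums


def write_lengths(lengths: Mapping[str, int], path: PathLike) -> None:
    pd.Series(lengths, name="length").rename_axis("feature").to_csv(
        path, sep="\t"
    )


def read_go(
    obo_or_edges: PathLike,
    gaf_like: PathLike,
    root: str = DEFAULT_ROOT,
) -> tuple[GoDag, GoAnnotationSet]:
    """Load the ontology (OBO file or child/parent edge TSV) and annotations.

    Annotation rows are (gene_id, term_id); annotations to terms absent from
    the ontology are dropped with a warning.
    """
    path = Path(obo_or_edges)
    if path.suffix.lower() == ".obo" or _looks_like_obo(path):
        graph = obonet.read_obo(path)
        dag = GoDag.from_obonet(graph, root=root)
    else:
        edges_df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if edges_df.shape[1] < 2:
            raise ValueError("edge table needs columns: child, parent[, rel]")
        if str(edges_df.iloc[0, 0]).lower() in ("child", "term", "child_id"):
            edges_df = edges_df.iloc[1:]
        if edges_df.shape[1] >= 3:
            edges_df = edges_df[edges_df.iloc[:, 2] == "is_a"]
        edges = list(zip(edges_df.iloc[:, 0], edges_df.iloc[:, 1]))
        dag = GoDag(edges, root=root)
    annot_df = pd.read_csv(gaf_like, sep="\t", header=None, comment="#")
    if str(annot_df.iloc[0, 1]).lower() in ("term", "go_id", "term_id"):
        annot_df = annot_df.iloc[1:]
    pairs = list(zip(annot_df.iloc[:, 0], annot_df.iloc[:, 1]))
    annotations = GoAnnotationSet(pairs, dag)
    return dag, annotations


def _looks_like_obo(path: Path) -> bool:
    with open(path) as fh:
        head = fh.read(2048)
    return "[Term]" in head or head.startswith("format-version")


def write_go_edges(dag: GoDag, path: PathLike) -> None:
    rows = sorted(dag.graph.edges)
    pd.DataFrame(rows, columns=["child", "parent"]).assign(rel="is_a").to_csv(
        path, sep="\t", index=False, header=False
    )


def write_annotations(annotations: GoAnnotationSet, path: PathLike) -> None:
    annotations.table.sort_values(["gene", "term"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_ct_table(
    path: PathLike,
    sheet: SampleSheet,
    reference_genes: Sequence[str] = DEFAULT_REFERENCES,
) -> CtTable:
    """Ct measurements from a CSV with columns gene, sample, ct."""
    df = pd.read_csv(path)
    if {"gene", "sample", "ct"} - set(df.columns):
        raise ValueError("Ct CSV needs columns gene, sample, ct")
    return CtTable(df[["gene", "sample", "ct"]], sheet, reference_genes)


def write_table(df: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    """TSV writer with 6-significant-digit floats for reproducible output."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
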