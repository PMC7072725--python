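"""Gene Ontology profiling against the direct children of a root process.

Changed transcripts are bucketed into the direct-child terms of a root
("cellular process", GO:0009987, by default): a feature belongs to a child
process when any of its annotated terms equals that child or reaches it
through a chain of ``is_a`` edges.  Propagation uses ``is_a`` only.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "GoDag",
    "GoAnnotationSet",
    "direct_children",
    "assign_to_processes",
    "profile_processes",
    "strong_processes",
    "DEFAULT_ROOT",
]

log = logging.getLogger(__name__)

DEFAULT_ROOT = "GO:0009987"


class GoDag:
    """``is_a`` ontology graph (edges child -> parent) with a root term."""

    def __init__(self, edges: Iterable[tuple[str, str]], root: str = DEFAULT_ROOT):
        g = nx.DiGraph()
        g.add_node(root)
        for child, parent in edges:
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle through edge {cycle[0]}")
        if root not in g:
            raise ValueError(f"root term {root!r} absent from the ontology")
        self.graph = g
        self.root = root

    @classmethod
    def from_obonet(cls, obo_graph: nx.MultiDiGraph, root: str = DEFAULT_ROOT) -> "GoDag":
        """Build from an ``obonet``-parsed OBO graph, keeping ``is_a`` edges."""
        edges = [
            (c, p)
            for c, p, key in obo_graph.edges(keys=True)
            if key == "is_a"
        ]
        return cls(edges, root=root)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` along is_a edges (excl. itself)."""
        if term not in self.graph:
            raise KeyError(f"unknown term {term!r}")
        return set(nx.descendants(self.graph, term))

    def direct_children(self, root: Optional[str] = None) -> list[str]:
        return direct_children(self, self.root if root is None else root)

    def __repr__(self) -> str:
        return (
            f"GoDag({self.graph.number_of_nodes()} terms, "
            f"{self.graph.number_of_edges()} is_a edges, root={self.root!r})"
        )


class GoAnnotationSet:
    """Gene -> term assignments, restricted to terms present in a DAG.

    Annotations to unknown terms are dropped with a warning (tolerates
    ontology/annotation version skew).
    """

    def __init__(self, pairs: Iterable[tuple[str, str]], dag: GoDag):
        known, dropped = [], []
        for gene, term in pairs:
            (known if term in dag else dropped).append((gene, term))
        if dropped:
            log.warning(
                "dropping %d annotations to terms absent from the ontology "
                "(e.g. %s)", len(dropped), dropped[0][1]
            )
        self.table = pd.DataFrame(known, columns=["gene", "term"]).drop_duplicates()
        self.dropped = pd.DataFrame(dropped, columns=["gene", "term"])
        self.dag = dag

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene"])

    def terms_of(self, gene: str) -> set[str]:
        return set(self.table.loc[self.table["gene"] == gene, "term"])

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:
        return (
            f"GoAnnotationSet({len(self.table)} annotations, "
            f"{self.table['gene'].nunique()} genes)"
        )


def direct_children(dag: GoDag, root: str) -> list[str]:
    """Terms with an ``is_a`` edge directly to ``root``, sorted by term id."""
    if root not in dag:
        raise KeyError(f"root term {root!r} absent from the ontology")
    return sorted(dag.graph.predecessors(root))


def assign_to_processes(
    annotations: GoAnnotationSet,
    dag: GoDag,
    children: Sequence[str],
) -> tuple[dict[str, set[str]], set[str]]:
    """Bucket annotated genes into the given child processes.

    A gene lands in child ``C`` iff some annotated term equals ``C`` or has
    ``C`` among its is_a ancestors; multi-membership is allowed.  Returns the
    ``process -> gene set`` map plus the set of annotated genes that reached
    no child (annotations outside the profiled subtree).
    """
    unknown = [c for c in children if c not in dag]
    if unknown:
        raise KeyError(f"child terms absent from the ontology: {unknown}")
    child_set = set(children)
    # term -> set of children it reaches (itself included when it is a child)
    reach: dict[str, set[str]] = {}
    for term in set(annotations.table["term"]):
        up = dag.ancestors(term) | {term}
        reach[term] = up & child_set
    assignment: dict[str, set[str]] = {c: set() for c in children}
    assigned_genes: set[str] = set()
    for gene, term in annotations.table.itertuples(index=False):
        for c in reach[term]:
            assignment[c].add(gene)
            assigned_genes.add(gene)
    unassigned = annotations.genes - assigned_genes
    return assignment, unassigned


def profile_processes(
    calls: pd.DataFrame,
    assignment: Mapping[str, set[str]],
    feature_to_gene: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Count up-/down-regulated features per (process, group).

    ``calls`` is the long significance-call table (feature, group, direction)
    produced at one tier.  With a ``feature_to_gene`` map, transcripts
    collapse to genes before counting (a gene with both up and down
    transcripts in a group takes the direction of the largest |log2fc|).
    Returns a table (process, group, n_up, n_down) covering every process in
    the assignment and every group appearing in the calls.
    """
    work = calls.copy()
    if feature_to_gene is not None:
        work["feature"] = work["feature"].map(
            lambda f: feature_to_gene.get(f, f)
        )
        work["_abs"] = work["log2fc"].abs()
        work = (
            work.sort_values("_abs", kind="mergesort")
            .drop_duplicates(["feature", "group"], keep="last")
            .drop(columns="_abs")
        )
    groups = sorted(work["group"].unique()) if not work.empty else []
    rows = []
    for process in sorted(assignment):
        members = assignment[process]
        for g in groups:
            sub = work[(work["group"] == g) & work["feature"].isin(members)]
            rows.append({
                "process": process,
                "group": g,
                "n_up": int((sub["direction"] == "up").sum()),
                "n_down": int((sub["direction"] == "down").sum()),
            })
    prof = pd.DataFrame(rows, columns=["process", "group", "n_up", "n_down"])
    prof["n_total"] = prof["n_up"] + prof["n_down"]
    return prof


def strong_processes(
    profile: pd.DataFrame, min_transcripts: int = 30
) -> pd.DataFrame:
    """Processes with at least ``min_transcripts`` changed features, per group.

    The cut is inclusive ("at least"): a process with exactly
    ``min_transcripts`` changed features is kept.  Rows are ordered by group,
    then descending total change, then process id.
    """
    if min_transcripts < 1:
        raise ValueError("min_transcripts must be >= 1")
    keep = profile[profile["n_total"] >= min_transcripts].copy()
    keep = keep.sort_values(
        ["group", "n_total", "process"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return keep
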