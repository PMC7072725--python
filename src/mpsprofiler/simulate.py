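"""Synthetic data with known ground truth for the full analysis path.

The generator emulates the study design the pipeline assumes: one control
fibroblast line plus 11 disease groups, four biological replicates each,
negative-binomial counts with per-feature baseline abundances, per-sample
library sizes and planted per-group log2 effects (optionally shared across a
cluster of groups, mirroring the observation that several disease types
share changed gene sets).

Count model, for feature g in sample s of group G:

    count ~ NegBin(mean = L_s * lambda_g * 2**beta_{g,G},  var = mu + phi*mu^2)

with ``lambda_g`` the baseline relative abundance, ``L_s`` the library size
and ``beta`` the planted log2 effect matrix (zero for the control and for
null features).  Library sizes default to 1e5-2e5: FPKM is scale-invariant
in the library size, so desk-scale libraries exercise the identical analysis
path as the tens of millions of reads of a real experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_CONTROL,
    DEFAULT_GROUPS,
    SampleSheet,
    make_sample_sheet,
)
from .ontology import DEFAULT_ROOT, GoAnnotationSet, GoDag
from .qpcr import DEFAULT_REFERENCES, CtTable
from .quantify import ExpressionMatrix

__all__ = [
    "SimDesign",
    "PlantedEffect",
    "SyntheticTruth",
    "generate_counts",
    "generate_go_fixture",
    "generate_qpcr",
    "cluster_effects",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A signed log2 effect on one feature in a set of disease groups."""

    feature_id: str
    affected_groups: frozenset[str]
    log2_effect: float

    def __init__(self, feature_id, affected_groups, log2_effect):
        object.__setattr__(self, "feature_id", feature_id)
        object.__setattr__(self, "affected_groups", frozenset(affected_groups))
        object.__setattr__(self, "log2_effect", float(log2_effect))


@dataclass
class SimDesign:
    """Parameters of the synthetic study.

    ``baseline_log2_mean_range`` is the per-feature log2 relative abundance
    ``log2(lambda_g)``; with the default library sizes this yields mean
    counts between roughly 1.5 and 400 per feature.
    """

    groups: Sequence[str] = (DEFAULT_CONTROL, *DEFAULT_GROUPS)
    control_group: str = DEFAULT_CONTROL
    reps_per_group: int = 4
    n_features: int = 5000
    baseline_log2_mean_range: tuple[float, float] = (-16.0, -8.0)
    dispersion: float = 0.05
    library_size_range: tuple[int, int] = (100_000, 200_000)
    length_range: tuple[int, int] = (200, 10_000)
    effects: Sequence[PlantedEffect] = ()
    seed: int = 0

    def __post_init__(self):
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if self.control_group not in self.groups:
            raise ValueError("control group must be listed in groups")
        if self.reps_per_group < 2:
            raise ValueError("reps_per_group must be >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for e in self.effects:
            if self.control_group in e.affected_groups:
                raise ValueError(
                    f"effect on {e.feature_id} targets the control group"
                )

    @property
    def feature_ids(self) -> list[str]:
        width = len(str(self.n_features))
        return [f"T{idx:0{width}d}" for idx in range(1, self.n_features + 1)]


@dataclass
class SyntheticTruth:
    """Generating parameters behind a synthetic count matrix."""

    effects: pd.DataFrame          # feature x group planted log2 effects
    library_sizes: pd.Series       # per sample
    baseline_log2: pd.Series       # per feature, log2 lambda
    lengths: pd.Series             # per feature, bp
    dispersion: float

    def true_de_features(self, group: str) -> set[str]:
        col = self.effects[group]
        return set(col.index[col != 0])

    def direction(self, feature: str, group: str) -> str:
        e = self.effects.loc[feature, group]
        return "none" if e == 0 else ("up" if e > 0 else "down")


def cluster_effects(
    feature_ids: Sequence[str],
    cluster_groups: Sequence[str],
    log2_effect: float,
) -> list[PlantedEffect]:
    """Helper: one shared effect on each feature across a group cluster."""
    return [
        PlantedEffect(f, frozenset(cluster_groups), log2_effect)
        for f in feature_ids
    ]


def generate_counts(
    design: SimDesign,
) -> tuple[ExpressionMatrix, dict[str, int], SampleSheet, SyntheticTruth]:
    """Draw a negative-binomial count matrix with the design's planted truth.

    Reproducible for a fixed seed; independent child streams are used for
    lengths, baselines, library sizes and counts so that changing one
    parameter leaves the other draws untouched.
    """
    root = np.random.default_rng(design.seed)
    rng_len, rng_base, rng_lib, rng_counts = root.spawn(4)

    features = design.feature_ids
    sheet = make_sample_sheet(design.groups, design.reps_per_group,
                              design.control_group)
    lengths = pd.Series(
        rng_len.integers(*design.length_range, size=design.n_features,
                         endpoint=True),
        index=features, name="length",
    )
    lo, hi = design.baseline_log2_mean_range
    baseline_log2 = pd.Series(
        rng_base.uniform(lo, hi, size=design.n_features),
        index=features, name="baseline_log2",
    )
    lib = pd.Series(
        rng_lib.integers(*design.library_size_range, size=len(sheet),
                         endpoint=True),
        index=sheet.sample_ids, name="library_size",
    )

    effects = pd.DataFrame(
        0.0, index=pd.Index(features, name="feature"), columns=list(design.groups)
    )
    for e in design.effects:
        if e.feature_id not in effects.index:
            raise KeyError(f"planted effect on unknown feature {e.feature_id!r}")
        unknown = e.affected_groups - set(design.groups)
        if unknown:
            raise KeyError(f"planted effect on unknown groups {sorted(unknown)}")
        for g in e.affected_groups:
            effects.loc[e.feature_id, g] = e.log2_effect

    lam = 2.0 ** baseline_log2.to_numpy()
    group_of = sheet.samples.set_index("sample_id")["group"]
    mean = np.empty((design.n_features, len(sheet)))
    for j, s in enumerate(sheet.sample_ids):
        g = group_of[s]
        mean[:, j] = lib[s] * lam * 2.0 ** effects[g].to_numpy()
    if np.log2(mean.max()) > 31:
        raise ValueError(
            "generating mean exceeds 2**31; shrink library sizes, baselines "
            "or effects"
        )

    # NB with var = mu + phi mu^2  <=>  shape n = 1/phi, p = n / (n + mu)
    n_shape = 1.0 / design.dispersion
    p = n_shape / (n_shape + mean)
    counts = rng_counts.negative_binomial(n_shape, p)
    counts_df = pd.DataFrame(
        counts, index=pd.Index(features, name="feature"),
        columns=sheet.sample_ids,
    )
    truth = SyntheticTruth(
        effects=effects,
        library_sizes=lib,
        baseline_log2=baseline_log2,
        lengths=lengths,
        dispersion=design.dispersion,
    )
    expr = ExpressionMatrix(counts_df, sheet)
    return expr, lengths.to_dict(), sheet, truth


def generate_go_fixture(
    n_processes: int,
    genes_per_process: int,
    depth: int,
    seed: int,
    genes: Optional[Sequence[str]] = None,
    root: str = DEFAULT_ROOT,
) -> tuple[GoDag, GoAnnotationSet]:
    """A small single-rooted is_a DAG plus leaf-level gene annotations.

    The root gets exactly ``n_processes`` direct children; under each child
    hangs a chain of ``depth - 1`` further terms, and annotations are placed
    on the deepest term of each chain so that profiling must propagate along
    is_a edges rather than read direct annotations.  Each gene is annotated
    into 1-3 processes.
    """
    if n_processes < 1 or depth < 1:
        raise ValueError("n_processes and depth must be >= 1")
    if genes_per_process < 1:
        raise ValueError("genes_per_process must be >= 1")
    rng = np.random.default_rng(seed)
    edges = []
    leaves = []
    for i in range(1, n_processes + 1):
        child = f"GO:{1000000 + i:07d}"
        edges.append((child, root))
        prev = child
        for d in range(1, depth):
            term = f"GO:{1000000 + 1000 * d + i:07d}"
            edges.append((term, prev))
            prev = term
        leaves.append(prev)
    dag = GoDag(edges, root=root)

    if genes is None:
        total = n_processes * genes_per_process
        genes = [f"gene{j:05d}" for j in range(1, total + 1)]
    genes = list(genes)
    pairs = []
    for gene in genes:
        k = int(rng.integers(1, min(3, n_processes) + 1))
        chosen = rng.choice(n_processes, size=k, replace=False)
        for idx in sorted(chosen):
            pairs.append((gene, leaves[idx]))
    annotations = GoAnnotationSet(pairs, dag)
    return dag, annotations


def generate_qpcr(
    truth_log2fc: Mapping[str, Mapping[str, float]],
    sheet: SampleSheet,
    n_reps: Optional[int] = None,
    baseline_ct: float = 24.0,
    ref_ct: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CtTable:
    """Build a Ct plate whose ddCt analysis recovers the given truth.

    ``truth_log2fc`` maps target gene -> {disease group: log2 fold change};
    the control group is implicitly at fold change 1.  Target Ct in a group
    is ``baseline_ct - log2fc + Normal(0, noise_sd)``; the two reference
    genes sit at ``ref_ct`` independent of group (plus the same noise).  At
    ``noise_sd = 0`` the ddCt pipeline returns the truth exactly.
    """
    rng = np.random.default_rng(seed)
    if n_reps is not None:
        counts = sheet.samples["group"].value_counts()
        if (counts < n_reps).any():
            raise ValueError("sheet has fewer replicates than n_reps")
    control = sheet.control_group
    rows = []

    def noisy(x: float) -> float:
        return float(x + rng.normal(0.0, noise_sd)) if noise_sd > 0 else float(x)

    for s in sheet.sample_ids:
        for ref in DEFAULT_REFERENCES:
            rows.append({"gene": ref, "sample": s, "ct": noisy(ref_ct)})
    group_of = sheet.samples.set_index("sample_id")["group"]
    for gene, per_group in truth_log2fc.items():
        wanted = set(per_group) | {control}
        for s in sheet.sample_ids:
            g = group_of[s]
            if g not in wanted:
                continue
            lfc = per_group.get(g, 0.0)
            rows.append({"gene": gene, "sample": s,
                         "ct": noisy(baseline_ct - lfc)})
    measured = pd.DataFrame(rows, columns=["gene", "sample", "ct"])
    return CtTable(measured, sheet, DEFAULT_REFERENCES)
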