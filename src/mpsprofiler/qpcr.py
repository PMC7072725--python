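"""Relative quantification of qPCR Ct tables by the 2^-ddCt method.

Per sample, the target gene's Ct is normalised against the arithmetic mean of
two housekeeping (reference) gene Cts (dCt); per disease group, ddCt is the
difference of group-mean dCt from the control's, so relative expression is
``2**-ddCt`` and the log2 fold change is ``-ddCt``.  Group differences are
tested with a two-group one-way ANOVA on the per-replicate dCt values
(equivalent to the pooled t-test).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import SampleSheet
from .diffexp import anova_oneway

__all__ = [
    "CtTable",
    "delta_ct",
    "ddct_fold",
    "relative_expression",
    "compare_with_rnaseq",
    "DEFAULT_REFERENCES",
]

DEFAULT_REFERENCES = ("GAPDH", "G6PD")


class CtTable:
    """Long-format Ct measurements with a design and two reference genes."""

    def __init__(
        self,
        measurements: pd.DataFrame,
        design: SampleSheet,
        reference_genes: Sequence[str] = DEFAULT_REFERENCES,
    ):
        required = {"gene", "sample", "ct"}
        if required - set(measurements.columns):
            raise ValueError("Ct table needs columns gene, sample, ct")
        refs = tuple(reference_genes)
        if len(refs) != 2:
            raise ValueError("exactly two reference genes are required")
        df = measurements.reset_index(drop=True).copy()
        ct = df["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or (ct <= 0).any():
            raise ValueError("Ct values must be finite and positive")
        for ref in refs:
            have = set(df.loc[df["gene"] == ref, "sample"])
            missing = [s for s in design.sample_ids if s not in have]
            if missing:
                raise ValueError(
                    f"reference gene {ref!r} unmeasured in samples {missing}"
                )
        self.measurements = df
        self.design = design
        self.reference_genes = refs

    def ct(self, gene: str, sample: str) -> float:
        sub = self.measurements[
            (self.measurements["gene"] == gene)
            & (self.measurements["sample"] == sample)
        ]
        if sub.empty:
            raise KeyError(f"no Ct for gene {gene!r} in sample {sample!r}")
        return float(sub["ct"].iloc[0])

    @property
    def target_genes(self) -> list[str]:
        refs = set(self.reference_genes)
        return sorted(set(self.measurements["gene"]) - refs)

    def __repr__(self) -> str:
        return (
            f"CtTable({len(self.measurements)} wells, "
            f"targets={self.target_genes}, refs={list(self.reference_genes)})"
        )


def delta_ct(table: CtTable, gene: str, sample: str) -> float:
    """dCt = Ct_gene - mean(Ct of the two reference genes), one sample."""
    r1, r2 = table.reference_genes
    return table.ct(gene, sample) - 0.5 * (
        table.ct(r1, sample) + table.ct(r2, sample)
    )


def _group_dcts(table: CtTable, gene: str, group: str) -> np.ndarray:
    samples = table.design.samples_of(group)
    return np.array([delta_ct(table, gene, s) for s in samples])


def ddct_fold(
    table: CtTable, gene: str, group: str, control_group: Optional[str] = None
) -> dict:
    """ddCt quantification of one gene in one group vs control.

    Returns a dict with ``ddct``, ``fold`` (= 2**-ddct), ``log2fc``
    (= -ddct) and ``p_anova`` from the two-group ANOVA on replicate dCts.
    """
    control = control_group or table.design.control_group
    if control not in table.design.groups:
        raise KeyError(f"control group {control!r} not in design")
    grp = _group_dcts(table, gene, group)
    ctrl = _group_dcts(table, gene, control)
    ddct = float(grp.mean() - ctrl.mean())
    try:
        _, p = anova_oneway([grp, ctrl])
    except ValueError:  # all dCts identical: no evidence of change
        p = 1.0
    return {
        "gene": gene,
        "group": group,
        "ddct": ddct,
        "fold": 2.0 ** (-ddct),
        "log2fc": -ddct,
        "p_anova": p,
    }


def relative_expression(
    table: CtTable, control_group: Optional[str] = None
) -> pd.DataFrame:
    """ddCt quantification of every target gene in every disease group."""
    control = control_group or table.design.control_group
    groups = [g for g in table.design.groups if g != control]
    measured = set(zip(table.measurements["gene"], table.measurements["sample"]))
    rows = []
    for gene in table.target_genes:
        for group in groups:
            wanted = table.design.samples_of(group) + table.design.samples_of(control)
            if all((gene, s) in measured for s in wanted):
                rows.append(ddct_fold(table, gene, group, control))
    return pd.DataFrame(
        rows, columns=["gene", "group", "ddct", "fold", "log2fc", "p_anova"]
    )


def compare_with_rnaseq(
    rel: pd.DataFrame,
    de_table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    feature_to_gene: Optional[dict] = None,
) -> pd.DataFrame:
    """Side-by-side RNA-seq vs qPCR log2 fold changes for selected pairs.

    ``sign_agreement`` is a strict sign match (zero counts as no change and
    agrees with nothing but zero).  Raises listing any pair missing from
    either platform.
    """
    de_genes = de_table.index if feature_to_gene is None else pd.Index(
        [feature_to_gene.get(f, f) for f in de_table.index]
    )
    rel_keys = set(zip(rel["gene"], rel["group"]))
    missing = []
    rows = []
    for gene, group in pairs:
        col = f"log2fc_{group}"
        in_de = gene in set(de_genes) and col in de_table.columns
        in_rel = (gene, group) in rel_keys
        if not (in_de and in_rel):
            missing.append((gene, group))
            continue
        if feature_to_gene is None:
            seq_lfc = float(de_table.loc[gene, col])
        else:
            feats = [f for f in de_table.index
                     if feature_to_gene.get(f, f) == gene]
            sub = de_table.loc[feats, col]
            seq_lfc = float(sub.iloc[sub.abs().argmax()])
        q_lfc = float(
            rel.loc[(rel["gene"] == gene) & (rel["group"] == group),
                    "log2fc"].iloc[0]
        )
        agree = np.sign(seq_lfc) == np.sign(q_lfc)
        rows.append({
            "gene": gene,
            "group": group,
            "log2fc_rnaseq": seq_lfc,
            "log2fc_qpcr": q_lfc,
            "sign_agreement": bool(agree),
        })
    if missing:
        raise KeyError(f"pairs missing from RNA-seq or qPCR results: {missing}")
    return pd.DataFrame(
        rows,
        columns=["gene", "group", "log2fc_rnaseq", "log2fc_qpcr",
                 "sign_agreement"],
    )
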