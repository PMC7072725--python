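"""Multi-group differential expression: one-way ANOVA with BH FDR and
post-hoc contrasts vs the control group.

The model follows the classic multi-group fibroblast comparison recipe:

* per feature, a one-way ANOVA across all groups on ``log2(1 + FPKM)``;
* Benjamini–Hochberg step-up adjustment of the ANOVA p-values across all
  tested features (the feature-level FDR);
* per disease group, a pooled-variance (Student's) two-sample t contrast
  against the control, Bonferroni-corrected across the family of
  vs-control contrasts;
* log2 fold changes of group mean FPKM vs control mean FPKM with a
  pseudocount;
* tiered significance calls combining the three gates.

`DifferentialExpressionModel` is built from an :class:`ExpressionMatrix`
carrying the ``log_fpkm`` layer (and ``fpkm`` for fold changes); ``fit()``
returns a :class:`DEResults` holding the per-feature statistics table,
significance calls per tier and a text ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DEFAULT_TIERS, SampleSheet, SignificanceTier
from .quantify import ExpressionMatrix, fpkm as _fpkm, log_transform

__all__ = [
    "DifferentialExpressionModel",
    "DEResults",
    "anova_oneway",
    "bh_adjust",
    "posthoc_contrast",
    "log2_fold_change",
    "call_significance",
]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over ``k`` groups of replicate values.

    Returns ``(F, p)`` with the standard between/within mean-square ratio on
    ``(k - 1, N - k)`` degrees of freedom.  Conventions for degenerate input:
    zero within-group variance with unequal group means gives ``F = inf,
    p = 0``; all values identical raises ``ValueError`` (the feature is
    untestable and must be excluded upstream).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least two replicates")
    allv = np.concatenate(arrs)
    if np.ptp(allv) == 0:
        raise ValueError("all values identical: untestable feature")
    k = len(arrs)
    N = allv.size
    grand = allv.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = k - 1, N - k
    if ss_within == 0:
        return math.inf, 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` clipped to 1, where the ordering is
    by ascending p over the ``m`` tested features.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def posthoc_contrast(
    group: Sequence[float], control: Sequence[float], m: int
) -> tuple[float, float, float]:
    """Pooled-variance two-sided Student's t contrast of a group vs control.

    Returns ``(t, p_t, p_bonf)`` with ``df = n1 + n2 - 2`` and
    ``p_bonf = min(1, m * p_t)`` for a Bonferroni family of ``m`` contrasts.
    Degenerate input: zero pooled variance with equal means gives
    ``t = 0, p = 1``; with unequal means, ``t = +/-inf, p = 0``.
    """
    a = np.asarray(group, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two replicates")
    if m < 1:
        raise ValueError("Bonferroni family size must be >= 1")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0, 1.0
        t = math.inf if diff > 0 else -math.inf
        return t, 0.0, 0.0
    t = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p_t = float(2 * stats.t.sf(abs(t), df))
    return float(t), p_t, min(1.0, m * p_t)


def log2_fold_change(
    mean_fpkm_grp: float, mean_fpkm_ctrl: float, pseudocount: float = 1.0
) -> float:
    """log2((mean_grp + c) / (mean_ctrl + c)) on the FPKM scale."""
    if mean_fpkm_grp < 0 or mean_fpkm_ctrl < 0:
        raise ValueError("mean FPKM must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return float(
        np.log2((mean_fpkm_grp + pseudocount) / (mean_fpkm_ctrl + pseudocount))
    )


def call_significance(
    table: pd.DataFrame,
    tier: SignificanceTier,
    groups: Sequence[str],
) -> pd.DataFrame:
    """Tiered significance calls from a fitted per-feature statistics table.

    A feature is called in group ``G`` iff ``q_bh < fdr_max`` and
    ``p_bonf_G < p_max`` and ``|log2fc_G| > lfc_min``; direction is the sign
    of the fold change.  Returns a long table (feature, group, direction,
    log2fc, tier) containing only ``up``/``down`` rows.
    """
    frames = []
    q = table["q_bh"].to_numpy()
    for g in groups:
        lfc = table[f"log2fc_{g}"].to_numpy()
        hit = (
            (q < tier.fdr_max)
            & (table[f"p_bonf_{g}"].to_numpy() < tier.p_max)
            & (np.abs(lfc) > tier.lfc_min)
            & (lfc != 0)
        )
        if hit.any():
            frames.append(pd.DataFrame({
                "feature": table.index[hit],
                "group": g,
                "direction": np.where(lfc[hit] > 0, "up", "down"),
                "log2fc": lfc[hit],
                "tier": tier.name,
            }))
    if not frames:
        return pd.DataFrame(
            columns=["feature", "group", "direction", "log2fc", "tier"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["group", "feature"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class DifferentialExpressionModel:
    """ANOVA-based multi-group differential expression model.

    Parameters
    ----------
    expr
        Expression matrix with the ``log_fpkm`` layer (and ``fpkm`` for the
        fold changes).  Build one from counts with :meth:`from_counts`.
    tiers
        Significance tiers evaluated by the results object.
    pseudocount
        Added to mean FPKM in the fold-change ratio.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        tiers: Sequence[SignificanceTier] = DEFAULT_TIERS,
        pseudocount: float = 1.0,
    ):
        if expr.log_fpkm is None:
            raise ValueError("expression matrix must carry the log_fpkm layer")
        if expr.fpkm is None:
            raise ValueError("expression matrix must carry the fpkm layer")
        self.expr = expr
        self.design = expr.design
        self.tiers = tuple(tiers)
        self.pseudocount = float(pseudocount)

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        lengths: Mapping[str, int],
        sheet: SampleSheet,
        tiers: Sequence[SignificanceTier] = DEFAULT_TIERS,
        pseudocount: float = 1.0,
    ) -> "DifferentialExpressionModel":
        """Quantify (classic FPKM + log transform) and build the model."""
        expr = ExpressionMatrix(counts, sheet)
        expr = log_transform(_fpkm(expr, lengths))
        return cls(expr, tiers=tiers, pseudocount=pseudocount)

    def fit(self) -> "DEResults":
        design = self.design
        control = design.control_group
        groups = design.noncontrol_groups
        m = len(groups)

        log_vals = self.expr.log_fpkm
        fpkm_vals = self.expr.fpkm
        counts = self.expr.counts

        # untestable features: all-zero counts, or zero variance overall
        vals = log_vals.to_numpy(dtype=float)
        span = vals.max(axis=1) - vals.min(axis=1)
        untestable = span == 0
        skipped = pd.DataFrame({
            "feature": log_vals.index[untestable],
            "reason": [
                "all_zero_counts"
                if counts is not None
                and not counts.loc[f].to_numpy().any()
                else "zero_variance"
                for f in log_vals.index[untestable]
            ],
        })

        tested = log_vals.index[~untestable]
        X = vals[~untestable]

        col_groups = design.samples["group"].to_numpy()
        group_order = [control] + groups
        masks = {g: col_groups == g for g in group_order}
        sizes = {g: int(masks[g].sum()) for g in group_order}
        k = len(group_order)
        N = X.shape[1]

        # one-way ANOVA, vectorised over features
        gmeans = {g: X[:, masks[g]].mean(axis=1) for g in group_order}
        grand = X.mean(axis=1)
        ss_b = np.zeros(X.shape[0])
        ss_w = np.zeros(X.shape[0])
        for g in group_order:
            sub = X[:, masks[g]]
            ss_b += sizes[g] * (gmeans[g] - grand) ** 2
            ss_w += ((sub - gmeans[g][:, None]) ** 2).sum(axis=1)
        df_b, df_w = k - 1, N - k
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_b / df_b) / (ss_w / df_w)
        degenerate = ss_w == 0
        F[degenerate] = np.inf
        p_anova = np.where(degenerate, 0.0, stats.f.sf(np.where(degenerate, 1.0, F), df_b, df_w))
        q_bh = bh_adjust(p_anova)

        table = pd.DataFrame(index=pd.Index(tested, name="feature"))
        table["F"] = F
        table["p_anova"] = p_anova
        table["q_bh"] = q_bh
        table["zero_within_variance"] = degenerate

        fp = fpkm_vals.loc[tested]
        ctrl_fpkm_mean = fp.loc[:, design.samples_of(control)].mean(axis=1)
        table[f"mean_log_{control}"] = gmeans[control]

        ctrl_X = X[:, masks[control]]
        n2 = sizes[control]
        ctrl_dev = ((ctrl_X - gmeans[control][:, None]) ** 2).sum(axis=1)
        c = self.pseudocount
        for g in groups:
            sub = X[:, masks[g]]
            n1 = sizes[g]
            df = n1 + n2 - 2
            dev = ((sub - gmeans[g][:, None]) ** 2).sum(axis=1)
            sp2 = (dev + ctrl_dev) / df
            diff = gmeans[g] - gmeans[control]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            zero_sp = sp2 == 0
            t = np.where(zero_sp & (diff == 0), 0.0, t)
            t = np.where(zero_sp & (diff > 0), np.inf, t)
            t = np.where(zero_sp & (diff < 0), -np.inf, t)
            p_t = np.where(
                np.isinf(t), 0.0,
                np.where(np.isnan(t), 1.0, 2 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df)),
            )
            p_t = np.where(zero_sp & (diff == 0), 1.0, p_t)
            p_bonf = np.minimum(1.0, m * p_t)
            grp_fpkm_mean = fp.loc[:, design.samples_of(g)].mean(axis=1)
            lfc = np.log2((grp_fpkm_mean + c) / (ctrl_fpkm_mean + c))
            table[f"mean_log_{g}"] = gmeans[g]
            table[f"log2fc_{g}"] = lfc
            table[f"t_{g}"] = t
            table[f"p_t_{g}"] = p_t
            table[f"p_bonf_{g}"] = p_bonf

        return DEResults(self, table, skipped)


class DEResults:
    """Fitted differential-expression results.

    Attributes
    ----------
    table
        Per-feature statistics: ``F``, ``p_anova``, ``q_bh`` and, per
        non-control group, ``mean_log``, ``log2fc``, ``t``, ``p_t``,
        ``p_bonf``.
    skipped
        Features excluded from testing (all-zero counts / zero variance),
        with the exclusion reason; they are absent from ``table`` and from
        the BH denominator.
    """

    def __init__(self, model: DifferentialExpressionModel,
                 table: pd.DataFrame, skipped: pd.DataFrame):
        self.model = model
        self.design = model.design
        self.table = table
        self.skipped = skipped

    @property
    def groups(self) -> list[str]:
        return self.design.noncontrol_groups

    def calls(self, tier: SignificanceTier) -> pd.DataFrame:
        """Long table of up/down calls at a tier."""
        return call_significance(self.table, tier, self.groups)

    def counts(self, tier: SignificanceTier) -> pd.DataFrame:
        """Per-group numbers of up- and down-regulated features at a tier."""
        calls = self.calls(tier)
        out = pd.DataFrame(0, index=pd.Index(self.groups, name="group"),
                           columns=["n_up", "n_down"])
        if not calls.empty:
            tab = calls.pivot_table(index="group", columns="direction",
                                    values="feature", aggfunc="count",
                                    fill_value=0)
            for col, name in (("up", "n_up"), ("down", "n_down")):
                if col in tab.columns:
                    out.loc[tab.index, name] = tab[col].astype(int)
        out["n_total"] = out["n_up"] + out["n_down"]
        return out

    def summary(self) -> str:
        lines = [
            "Multi-group differential expression (one-way ANOVA + BH FDR)",
            f"  control group : {self.design.control_group}",
            f"  disease groups: {len(self.groups)}",
            f"  features tested: {len(self.table)}"
            f" (skipped: {len(self.skipped)})",
            "",
            "  tier      FDR<      p<     |log2FC|>   up   down",
        ]
        for tier in self.model.tiers:
            cnt = self.counts(tier)
            lines.append(
                f"  {tier.name:<8} {tier.fdr_max:<9g} {tier.p_max:<7g} "
                f"{tier.lfc_min:<9g} {int(cnt['n_up'].sum()):>5} "
                f"{int(cnt['n_down'].sum()):>6}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"DEResults({len(self.table)} features, "
            f"{len(self.groups)} contrasts vs {self.design.control_group!r})"
        )
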