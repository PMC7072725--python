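"""Shared fixtures: small synthetic studies with known ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mpsprofiler as mp


@pytest.fixture(scope="session")
def small_sheet() -> mp.SampleSheet:
    """Three groups (control + 2), three replicates each."""
    return mp.make_sample_sheet(("HDFa", "I", "II"), reps_per_group=3)


@pytest.fixture(scope="session")
def full_sheet() -> mp.SampleSheet:
    """The standard 12-group x 4-replicate design."""
    return mp.make_sample_sheet()


def build_recovery_study(seed: int, n_features: int = 5000, n_effects: int = 200):
    """Synthetic study with planted |log2|=3 effects on expressed features.

    Effects are planted on features in the upper half of the baseline
    abundance range (a multiplicative effect on a feature with near-zero
    counts is not recoverable at n=4 and would measure the abundance
    distribution rather than the method), each shared by 1-3 cyclically
    chosen disease groups, signs alternating.

    Returns (expr, lengths, sheet, truth, planted) with ``planted`` a set of
    (feature, group, sign) triples.
    """
    groups = list(mp.DEFAULT_GROUPS)
    base = mp.SimDesign(n_features=n_features, seed=seed)
    _, _, _, truth0 = mp.generate_counts(base)
    lo, hi = base.baseline_log2_mean_range
    mid = (lo + hi) / 2
    expressed = truth0.baseline_log2[truth0.baseline_log2 >= mid].index.tolist()
    feats = expressed[:n_effects]
    effects, planted = [], set()
    for i, f in enumerate(feats):
        k = 1 + (i % 3)
        gs = {groups[(i + j) % len(groups)] for j in range(k)}
        sign = 1 if i % 2 == 0 else -1
        effects.append(mp.PlantedEffect(f, gs, sign * 3.0))
        planted.update((f, g, sign) for g in gs)
    design = mp.SimDesign(n_features=n_features, seed=seed, effects=effects)
    expr, lengths, sheet, truth = mp.generate_counts(design)
    return expr, lengths, sheet, truth, planted


@pytest.fixture(scope="session")
def recovery_study():
    return build_recovery_study(seed=1)


@pytest.fixture(scope="session")
def recovery_results(recovery_study):
    expr, lengths, sheet, truth, planted = recovery_study
    model = mp.DifferentialExpressionModel.from_counts(
        expr.counts, lengths, sheet
    )
    return model.fit(), planted


@pytest.fixture()
def toy_de_table(full_sheet) -> pd.DataFrame:
    """Hand-built per-feature statistics table for call/extreme logic tests.

    Four features: f_extreme passes every tier-3 gate in group I (up) and
    is down-extreme in IX; f_boundary sits exactly at |log2fc| = 2.5;
    f_weak passes tier1 only; f_null passes nothing.
    """
    groups = full_sheet.noncontrol_groups
    idx = pd.Index(["f_extreme", "f_boundary", "f_weak", "f_null"],
                   name="feature")
    tab = pd.DataFrame(index=idx)
    tab["F"] = [90.0, 80.0, 9.0, 1.0]
    tab["p_anova"] = [1e-12, 1e-12, 1e-3, 0.5]
    tab["q_bh"] = [1e-10, 1e-10, 5e-2, 0.7]
    for g in groups:
        tab[f"mean_log_{g}"] = 1.0
        tab[f"log2fc_{g}"] = 0.0
        tab[f"t_{g}"] = 0.0
        tab[f"p_t_{g}"] = 1.0
        tab[f"p_bonf_{g}"] = 1.0
    tab.loc["f_extreme", "log2fc_I"] = 3.1
    tab.loc["f_extreme", "p_bonf_I"] = 1e-4
    tab.loc["f_extreme", "log2fc_IX"] = -2.6
    tab.loc["f_extreme", "p_bonf_IX"] = 1e-4
    tab.loc["f_boundary", "log2fc_I"] = 2.5
    tab.loc["f_boundary", "p_bonf_I"] = 1e-4
    tab.loc["f_weak", "log2fc_I"] = 1.0
    tab.loc["f_weak", "p_bonf_I"] = 0.05
    return tab
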