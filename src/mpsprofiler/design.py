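"""Experimental design and run configuration.

The study layout is one control fibroblast line (HDFa by default) plus a set
of disease groups (the 11 MPS types/subtypes), each measured in several
biological replicates.  ``SampleSheet`` carries that mapping; ``RunConfig``
carries the thresholds that drive the tiered significance calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "SampleSheet",
    "SignificanceTier",
    "RunConfig",
    "TIER1",
    "TIER2",
    "TIER3",
    "DEFAULT_TIERS",
    "DEFAULT_GROUPS",
    "DEFAULT_CONTROL",
]

DEFAULT_CONTROL = "HDFa"
#: 11 MPS types/subtypes in the conventional order, after the control.
DEFAULT_GROUPS = (
    "I", "II", "IIIA", "IIIB", "IIIC", "IIID", "IVA", "IVB", "VI", "VII", "IX",
)


class SampleSheet:
    """Sample-to-group assignment with a designated control group.

    Parameters
    ----------
    samples
        DataFrame with columns ``sample_id``, ``group``, ``replicate``.
    control_group
        Label of the control group; must occur in ``samples``.
    """

    def __init__(self, samples: pd.DataFrame, control_group: str = DEFAULT_CONTROL):
        required = {"sample_id", "group", "replicate"}
        missing = required - set(samples.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        samples = samples.reset_index(drop=True).copy()
        if samples["sample_id"].duplicated().any():
            dupes = samples.loc[samples["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
        if (samples["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        groups = samples["group"].unique().tolist()
        if control_group not in groups:
            raise ValueError(f"control group {control_group!r} not in sample sheet")
        sizes = samples["group"].value_counts()
        small = sorted(g for g in groups if g != control_group and sizes[g] < 2)
        if small:
            raise ValueError(
                f"groups with fewer than 2 samples (contrast needs within-group "
                f"variance): {small}"
            )
        self.samples = samples
        self.control_group = control_group

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order, control first."""
        seen = self.samples["group"].unique().tolist()
        return [self.control_group] + [g for g in seen if g != self.control_group]

    @property
    def noncontrol_groups(self) -> list[str]:
        return [g for g in self.groups if g != self.control_group]

    def samples_of(self, group: str) -> list[str]:
        sub = self.samples.loc[self.samples["group"] == group, "sample_id"]
        if sub.empty:
            raise KeyError(f"unknown group {group!r}")
        return sub.tolist()

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SampleSheet)
            and self.control_group == other.control_group
            and self.samples.equals(other.samples)
        )

    def __repr__(self) -> str:
        return (
            f"SampleSheet({len(self)} samples, {len(self.groups)} groups, "
            f"control={self.control_group!r})"
        )


@dataclass(frozen=True)
class SignificanceTier:
    """A named set of thresholds applied jointly.

    A feature is called in a group when the feature-level BH-adjusted ANOVA
    q-value is below ``fdr_max``, the Bonferroni-adjusted per-group contrast
    p-value is below ``p_max`` and |log2 fold change| strictly exceeds
    ``lfc_min`` (``lfc_min = 0`` disables the fold-change gate in the sense
    that any nonzero change passes; direction still requires a sign).
    """

    name: str
    fdr_max: float
    p_max: float
    lfc_min: float = 0.0

    def __post_init__(self):
        if not (0 < self.fdr_max <= 1) or not (0 < self.p_max <= 1):
            raise ValueError("fdr_max and p_max must lie in (0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")


TIER1 = SignificanceTier("tier1", fdr_max=0.1, p_max=0.1)
TIER2 = SignificanceTier("tier2", fdr_max=1e-6, p_max=0.1)
TIER3 = SignificanceTier("tier3", fdr_max=1e-6, p_max=0.01, lfc_min=2.5)
DEFAULT_TIERS = (TIER1, TIER2, TIER3)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``strong_process_min`` is the minimum number of changed transcripts a
    process must gather (at the stringent tier) to count as strongly changed;
    ``lfc_threshold`` is the extreme-gene fold-change gate on the log2 scale.
    """

    control_group: str = DEFAULT_CONTROL
    tiers: tuple[SignificanceTier, ...] = DEFAULT_TIERS
    lfc_threshold: float = 2.5
    strong_process_min: int = 30
    counting_unit: str = "transcript"
    pseudocount: float = 1.0
    recurrence_min_types: int = 2
    seed: int = 0

    def __post_init__(self):
        if not self.tiers:
            raise ValueError("tiers must be non-empty")
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be > 0")
        if self.strong_process_min < 1:
            raise ValueError("strong_process_min must be >= 1")
        if self.counting_unit not in ("transcript", "gene"):
            raise ValueError("counting_unit must be 'transcript' or 'gene'")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        self.tiers = tuple(self.tiers)

    def tier(self, name: str) -> SignificanceTier:
        for t in self.tiers:
            if t.name == name:
                return t
        raise KeyError(f"no tier named {name!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tiers_raw = raw.pop("tiers", None)
        if tiers_raw is not None:
            raw["tiers"] = tuple(SignificanceTier(**t) for t in tiers_raw)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "control_group": self.control_group,
            "tiers": [
                {"name": t.name, "fdr_max": t.fdr_max, "p_max": t.p_max,
                 "lfc_min": t.lfc_min}
                for t in self.tiers
            ],
            "lfc_threshold": self.lfc_threshold,
            "strong_process_min": self.strong_process_min,
            "counting_unit": self.counting_unit,
            "pseudocount": self.pseudocount,
            "recurrence_min_types": self.recurrence_min_types,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def make_sample_sheet(
    groups: Sequence[str] = (DEFAULT_CONTROL, *DEFAULT_GROUPS),
    reps_per_group: int = 4,
    control_group: str = DEFAULT_CONTROL,
) -> SampleSheet:
    """Build the standard balanced sheet: every group with the same number
    of replicates, sample ids ``<group>_r<k>``."""
    rows = [
        {"sample_id": f"{g}_r{k}", "group": g, "replicate": k}
        for g in groups
        for k in range(1, reps_per_group + 1)
    ]
    return SampleSheet(pd.DataFrame(rows), control_group=control_group)
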