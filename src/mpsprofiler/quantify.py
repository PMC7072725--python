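"""Expression container and classic-FPKM quantification.

FPKM (fragments per kilobase of feature per million mapped reads) is computed
from a raw count matrix and annotated feature lengths as

    FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * N[s])

where ``N[s]`` is the total count in sample ``s`` (the classic library-size
normalisation; no fragment-length correction).  Downstream testing operates on
``log2(1 + FPKM)`` values.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .design import SampleSheet

__all__ = ["ExpressionMatrix", "fpkm", "log_transform"]


class ExpressionMatrix:
    """Feature-by-sample expression with up to three layers.

    Layers: ``counts`` (non-negative integers), ``fpkm`` and ``log_fpkm``
    (non-negative floats, with ``log_fpkm = log2(1 + fpkm)`` elementwise).
    Columns always follow the sample-sheet order.
    """

    def __init__(
        self,
        counts: Optional[pd.DataFrame],
        design: SampleSheet,
        fpkm: Optional[pd.DataFrame] = None,
        log_fpkm: Optional[pd.DataFrame] = None,
    ):
        layers = {"counts": counts, "fpkm": fpkm, "log_fpkm": log_fpkm}
        present = {k: v for k, v in layers.items() if v is not None}
        if not present:
            raise ValueError("at least one layer required")
        ref = next(iter(present.values()))
        for name, layer in present.items():
            if list(layer.columns) != design.sample_ids:
                layer = layer.reindex(columns=design.sample_ids)
                if layer.isna().any().any():
                    raise ValueError(
                        f"layer {name!r} missing design samples"
                    )
                present[name] = layer
            if (layer.to_numpy() < 0).any():
                raise ValueError(f"layer {name!r} contains negative values")
            if not layer.index.equals(ref.index):
                raise ValueError("layers must share the feature index")
        self.counts = present.get("counts")
        self.fpkm = present.get("fpkm")
        self.log_fpkm = present.get("log_fpkm")
        self.design = design

    @property
    def feature_ids(self) -> list[str]:
        for layer in (self.counts, self.fpkm, self.log_fpkm):
            if layer is not None:
                return layer.index.tolist()
        raise AssertionError("empty ExpressionMatrix")

    @property
    def sample_ids(self) -> list[str]:
        return self.design.sample_ids

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def __repr__(self) -> str:
        layers = [
            n for n, l in (("counts", self.counts), ("fpkm", self.fpkm),
                           ("log_fpkm", self.log_fpkm)) if l is not None
        ]
        return (
            f"ExpressionMatrix({self.n_features} features x "
            f"{len(self.sample_ids)} samples, layers={layers})"
        )


def fpkm(expr: ExpressionMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Add the FPKM layer computed from the counts layer.

    Raises if any feature lacks a length, if a length is non-positive, or if
    any sample column sums to zero (library size undefined).
    """
    if expr.counts is None:
        raise ValueError("counts layer required to compute FPKM")
    counts = expr.counts
    missing = [f for f in counts.index if f not in lengths]
    if missing:
        raise KeyError(f"features without length: {missing[:10]}")
    L = np.array([lengths[f] for f in counts.index], dtype=float)
    if (L <= 0).any():
        bad = [f for f in counts.index if lengths[f] <= 0]
        raise ValueError(f"non-positive feature lengths: {bad[:10]}")
    N = counts.sum(axis=0).to_numpy(dtype=float)
    zero = counts.columns[N == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample columns (library size 0): {zero}")
    values = counts.to_numpy(dtype=float) * 1e9 / (L[:, None] * N[None, :])
    layer = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    return ExpressionMatrix(expr.counts, expr.design, fpkm=layer,
                            log_fpkm=expr.log_fpkm)


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Add the ``log2(1 + FPKM)`` working layer."""
    if expr.fpkm is None:
        raise ValueError("fpkm layer required for log transform")
    if (expr.fpkm.to_numpy() < 0).any():
        raise ValueError("fpkm layer contains negative values")
    layer = np.log2(1.0 + expr.fpkm)
    return ExpressionMatrix(expr.counts, expr.design, fpkm=expr.fpkm,
                            log_fpkm=layer)
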