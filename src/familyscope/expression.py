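"""Expression filtering and transform for FPKM matrices.

A gene counts as expressed when its FPKM reaches the detection threshold
(0.5, inclusive) in at least one sample; all-zero genes are reported
separately as not detected.  Plotting-scale values use log2(FPKM + 1), the
pseudocount keeping zeros at zero and every value nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FPKM_THRESHOLD = 0.5


@dataclass(frozen=True)
class ExpressionCall:
    expressed: frozenset[str]
    below_threshold: frozenset[str]
    not_detected: frozenset[str]

    def status(self, gene: str) -> str:
        if gene in self.expressed:
            return "expressed"
        if gene in self.not_detected:
            return "not_detected"
        if gene in self.below_threshold:
            return "below_threshold"
        raise KeyError(gene)


def _validate(m: pd.DataFrame) -> pd.DataFrame:
    if m.isna().any().any():
        raise ValueError("FPKM matrix contains missing values")
    if (m.to_numpy() < 0).any():
        raise ValueError("FPKM values must be nonnegative")
    return m


def expressed_genes(m: pd.DataFrame, threshold: float = FPKM_THRESHOLD) -> ExpressionCall:
    """Partition genes into expressed / below-threshold / not-detected."""
    _validate(m)
    arr = m.to_numpy(dtype=float)
    maxima = arr.max(axis=1) if arr.size else np.zeros(len(m))
    expressed = frozenset(m.index[maxima >= threshold])
    not_detected = frozenset(m.index[maxima == 0.0])
    below = frozenset(m.index) - expressed - not_detected
    return ExpressionCall(expressed, frozenset(below), not_detected)


def log_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(FPKM + 1)."""
    _validate(m)
    return np.log2(m.astype(float) + 1.0)


def read_fpkm(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path, sep="\t", index_col=0))


def write_fpkm(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t")
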