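"""Labelled symmetric river-by-river matrices shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PairwiseMatrix:
    """Symmetric matrix of a pairwise statistic with river-code labels."""

    labels: list[str]
    values: np.ndarray
    statistic_name: str = ""
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if v.shape[0] != len(self.labels):
            raise ValueError("labels length must match matrix size")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (i<j) values as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: list[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        sub = self.values[np.ix_(idx, idx)]
        p = self.p_values[np.ix_(idx, idx)] if self.p_values is not None else None
        return PairwiseMatrix(list(labels), sub, self.statistic_name, p)
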