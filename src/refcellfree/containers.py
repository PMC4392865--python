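"""In-memory containers for methylation matrices and phenotype designs.

A beta value is the methylated fraction at a CpG locus, constrained to
[0, 1].  A study ships two aligned objects: an m x n beta matrix (CpGs by
samples) and an n x d design matrix whose first column is the intercept.
Both carry their identifiers so that downstream alignment is always by id,
never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BetaMatrix", "DesignMatrix"]


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class BetaMatrix:
    """m x n matrix of methylation beta values with row/column identifiers.

    Parameters
    ----------
    values
        Float array of shape (m, n); entries in [0, 1], NaN marks a
        missing measurement.
    cpg_ids
        m unique CpG identifiers.
    sample_ids
        n unique sample identifiers.
    """

    values: np.ndarray
    cpg_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("beta values must be a 2-d array")
        m, n = self.values.shape
        if m < 1 or n < 2:
            raise ValueError(f"need at least 1 CpG and 2 samples, got {m} x {n}")
        if not self.cpg_ids:
            self.cpg_ids = [f"cg{i:08d}" for i in range(m)]
        if not self.sample_ids:
            self.sample_ids = [f"S{i:04d}" for i in range(n)]
        self.cpg_ids = list(self.cpg_ids)
        self.sample_ids = list(self.sample_ids)
        if len(self.cpg_ids) != m:
            raise ValueError("cpg_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match column count")
        _check_unique(self.cpg_ids, "CpG ids")
        _check_unique(self.sample_ids, "sample ids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)


@dataclass
class DesignMatrix:
    """n x d design matrix; column 0 is the all-ones intercept.

    Non-intercept conventions elsewhere in the package index columns
    1..d-1, so the intercept position is part of the contract.
    """

    values: np.ndarray
    column_names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design values must be a 2-d array")
        n, d = self.values.shape
        if d < 1:
            raise ValueError("design needs at least the intercept column")
        if not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("first design column must be the all-ones intercept")
        if not self.column_names:
            self.column_names = ["(Intercept)"] + [f"x{i}" for i in range(1, d)]
        self.column_names = list(self.column_names)
        if len(self.column_names) != d:
            raise ValueError("column_names length does not match design width")
        _check_unique(self.column_names, "design column names")
        if d > n or np.linalg.matrix_rank(self.values) < d:
            cols = self.collinear_columns()
            raise ValueError(
                "design matrix is rank deficient; collinear columns: "
                f"{cols if cols else self.column_names}"
            )

    def collinear_columns(self) -> list:
        """Names of columns involved in an exact linear dependence."""
        n, d = self.values.shape
        bad = []
        for j in range(1, d):
            others = np.delete(self.values, j, axis=1)
            rank_wo = np.linalg.matrix_rank(others)
            if np.linalg.matrix_rank(self.values) == rank_wo:
                bad.append(self.column_names[j])
        return bad

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def intercept_index(self) -> int:
        return 0
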