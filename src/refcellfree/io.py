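"""Readers, writers and locus filtering.

Formats are plain text: beta/design/annotation/coefficient tables as
TSV or CSV (auto-detected by extension), gene sets as GMT.  Readers
validate rather than coerce: out-of-range betas, duplicate identifiers
and unknown vocabulary raise with the offending locus named.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BetaMatrix, DesignMatrix
from .enrichment import REGION_VOCABULARY, CpGAnnotation

__all__ = [
    "FilterReport",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_design",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_coefficient_table",
    "read_coefficient_table",
    "write_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Accounting of locus filtering: input m = retained + sum(dropped)."""

    input_m: int
    retained_m: int
    dropped_missing: int = 0
    dropped_excluded: int = 0
    dropped_chrom: int = 0

    def __post_init__(self):
        total = self.retained_m + self.dropped_missing + self.dropped_excluded + self.dropped_chrom
        if total != self.input_m:
            raise ValueError("filter report counts do not reconcile")

    def to_dict(self) -> dict:
        return {
            "input_m": self.input_m,
            "retained_m": self.retained_m,
            "dropped_missing": self.dropped_missing,
            "dropped_excluded": self.dropped_excluded,
            "dropped_chrom": self.dropped_chrom,
        }


def _sep_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_beta_matrix(
    path,
    max_missing: int = 5,
    exclude_list=None,
    drop_chroms=None,
    chrom_map: dict | None = None,
    sep: str | None = None,
) -> tuple[BetaMatrix, FilterReport]:
    """Read a CpG x sample beta matrix and apply locus filters.

    Filters, in order: loci with more than ``max_missing`` missing values
    dropped; loci named in ``exclude_list`` (a file of ids or an iterable;
    the usual slot for published cross-reactive/polymorphic probe lists)
    dropped; loci whose chromosome (via ``chrom_map``) is in
    ``drop_chroms`` (e.g. {"X", "Y"}) dropped.
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate CpG ids in {path}: {dups[:5]}")
    values = df.to_numpy(dtype=float)
    bad = np.isfinite(values) & ((values < 0) | (values > 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"beta value out of [0, 1] at locus {df.index[i]!r}, sample "
            f"{df.columns[j]!r}: {values[i, j]}"
        )
    input_m = len(df)

    missing_counts = (~np.isfinite(values)).sum(axis=1)
    keep_missing = missing_counts <= max_missing
    dropped_missing = int((~keep_missing).sum())
    df = df.loc[keep_missing]

    dropped_excluded = 0
    if exclude_list is not None:
        if isinstance(exclude_list, (str, bytes, os.PathLike)):
            with open(exclude_list) as fh:
                excluded = {line.strip() for line in fh if line.strip()}
        else:
            excluded = set(exclude_list)
        keep = ~df.index.isin(excluded)
        dropped_excluded = int((~keep).sum())
        df = df.loc[keep]

    dropped_chrom = 0
    if drop_chroms:
        if chrom_map is None:
            raise ValueError("drop_chroms requires a chrom_map (cpg -> chromosome)")
        drop = {str(c) for c in drop_chroms}
        keep = ~df.index.map(lambda c: str(chrom_map.get(c, "")) in drop).to_numpy()
        dropped_chrom = int((~keep).sum())
        df = df.loc[keep]

    report = FilterReport(
        input_m=input_m,
        retained_m=len(df),
        dropped_missing=dropped_missing,
        dropped_excluded=dropped_excluded,
        dropped_chrom=dropped_chrom,
    )
    logger.info("beta matrix %s: %s", path, report.to_dict())
    beta = BetaMatrix(
        values=df.to_numpy(dtype=float),
        cpg_ids=df.index.tolist(),
        sample_ids=[str(c) for c in df.columns],
    )
    return beta, report


def write_beta_matrix(beta: BetaMatrix, path, sep: str | None = None) -> None:
    beta.to_frame().to_csv(path, sep=_sep_for(path, sep), index_label="cpg")


def read_design(path, spec=None, sample_ids=None, sep: str | None = None) -> DesignMatrix:
    """Build a design matrix from a phenotype table.

    ``spec`` declares covariates in order, each as
    ``{"name": column, "kind": "categorical" | "continuous",
    "reference": level}`` (reference required for categorical; treatment
    coding expands the remaining levels to indicators named
    ``column=level``).  With ``spec=None``, a table already containing an
    ``(Intercept)`` column of ones is taken as a pre-expanded numeric
    design matrix; otherwise the design is intercept-only.  When
    ``sample_ids`` is given, rows are aligned to it by the table's first
    column (sample id); unmatched ids raise.
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    df.index = df.index.map(str)
    if sample_ids is not None:
        wanted = [str(s) for s in sample_ids]
        missing = [s for s in wanted if s not in df.index]
        if missing:
            raise ValueError(f"samples missing from design table: {missing[:10]}")
        df = df.loc[wanted]
    n = len(df)
    if spec is None and "(Intercept)" in df.columns:
        ordered = ["(Intercept)"] + [c for c in df.columns if c != "(Intercept)"]
        return DesignMatrix(
            values=df[ordered].to_numpy(dtype=float), column_names=ordered
        )
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for cov in spec or []:
        name = cov["name"]
        if name not in df.columns:
            raise ValueError(f"covariate column {name!r} not in phenotype table")
        kind = cov.get("kind", "continuous")
        if kind == "continuous":
            cols.append(df[name].to_numpy(dtype=float))
            names.append(name)
        elif kind == "categorical":
            ref = cov.get("reference")
            levels = pd.unique(df[name].astype(str)).tolist()
            if ref is None:
                raise ValueError(f"categorical covariate {name!r} needs a reference level")
            ref = str(ref)
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} not observed for {name!r}; levels: {levels}"
                )
            declared = cov.get("levels")
            if declared is not None:
                unseen = [l for l in df[name].astype(str) if l not in {str(x) for x in declared}]
                if unseen:
                    raise ValueError(f"unseen level(s) for {name!r}: {sorted(set(unseen))[:5]}")
            for level in [l for l in levels if l != ref]:
                cols.append((df[name].astype(str) == level).to_numpy(dtype=float))
                names.append(f"{name}={level}")
        else:
            raise ValueError(f"unknown covariate kind: {kind!r}")
    return DesignMatrix(values=np.column_stack(cols), column_names=names)


def read_gmt(path) -> dict:
    """Parse a GMT file into {set name: set of member ids}."""
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member ({len(fields)} fields found)"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(filter(None, fields[2:]))
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


_ISLAND_27K = {"Island", "Non-island"}
_ISLAND_450K = {"Island", "Shore", "Shelf", "OpenSea"}


def read_annotation(path, platform_mode: str = "450K", sep: str | None = None) -> CpGAnnotation:
    """Read a CpG annotation table (cpg, island_relation[, infinium_type],
    gene_region with semicolon-separated multi-labels)."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str).fillna("")
    required = {"cpg", "island_relation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing required column(s): {sorted(missing)}")
    if platform_mode == "450K" and "infinium_type" not in df.columns:
        raise ValueError("450K annotation requires an infinium_type column")
    if df["cpg"].duplicated().any():
        raise ValueError("duplicate CpG ids in annotation")
    island = {}
    itype = {}
    regions = {}
    for _, row in df.iterrows():
        cpg = row["cpg"]
        island[cpg] = row["island_relation"]
        if "infinium_type" in df.columns and row.get("infinium_type", ""):
            if row["infinium_type"] not in ("I", "II"):
                raise ValueError(
                    f"unknown Infinium type {row['infinium_type']!r} for {cpg}"
                )
            itype[cpg] = row["infinium_type"]
        labels = [t for t in str(row.get("gene_region", "")).split(";") if t]
        for lab in labels:
            if lab not in REGION_VOCABULARY:
                raise ValueError(f"unknown gene-region token {lab!r} for {cpg}")
        regions[cpg] = labels
    return CpGAnnotation(island_relation=island, infinium_type=itype, gene_region_labels=regions)


_COEF_COLUMNS = ["cpg", "covariate", "estimate", "se", "z", "p", "q"]


def write_coefficient_table(table: pd.DataFrame, path, sep: str | None = None) -> None:
    """Write a coefficient table with fixed column order and 12 significant
    digits."""
    missing = [c for c in _COEF_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"coefficient table missing column(s): {missing}")
    table[_COEF_COLUMNS].to_csv(
        path, sep=_sep_for(path, sep), index=False, float_format="%.12g"
    )


def read_coefficient_table(path, sep: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    missing = [c for c in _COEF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coefficient table missing column(s): {missing}")
    return df


def write_matrix(values: np.ndarray, row_ids, col_names, path, sep: str | None = None) -> None:
    """Generic labelled-matrix TSV export (Delta, B, ground-truth bundles)."""
    pd.DataFrame(values, index=row_ids, columns=col_names).to_csv(
        path, sep=_sep_for(path, sep), index_label="id", float_format="%.12g"
    )
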