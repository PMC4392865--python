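"""Stratified exact over-representation tests for gene sets.

Gene-set enrichment of significant CpGs on Infinium arrays is confounded
by genomic context: CpG-island probes, the two probe chemistries and
different gene regions have very different significance rates.  The test
here conditions on that context by stratifying the 2x2 classification
(significant x in-set) over context strata and running an exact
Mantel-Haenszel test: under the null of common odds ratio 1 with all
margins fixed, each stratum's in-set significant count a_s is
hypergeometric, so the null law of T = sum_s a_s is the convolution of
hypergeometric mass functions and p-values are exact tail (or
point-probability two-sided) sums.  When every stratum is degenerate the
strata collapse to a single table tested with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CpGAnnotation",
    "StratifiedTables",
    "EnrichmentResult",
    "resolve_gene_region",
    "build_strata",
    "stratified_tables",
    "exact_mh_test",
    "mh_odds_ratio",
    "enrichment_analysis",
]

#: Gene-region precedence, highest first; TSS1500/TSS200 collapse to "TSS".
REGION_PRECEDENCE = ["TSS", "1stExon", "Body", "5'UTR", "3'UTR"]
REGION_VOCABULARY = {"TSS1500", "TSS200", "1stExon", "Body", "5'UTR", "3'UTR"}


@dataclass
class CpGAnnotation:
    """Per-CpG genomic context used to build enrichment strata."""

    island_relation: dict
    infinium_type: dict = field(default_factory=dict)
    gene_region_labels: dict = field(default_factory=dict)

    def cpgs(self):
        return set(self.island_relation)


@dataclass
class StratifiedTables:
    """Per-stratum 2x2 counts.

    Rows: significant yes/no; columns: in-set yes/no.  ``a`` counts
    significant in-set CpGs, ``b`` significant out-of-set, ``c``
    non-significant in-set, ``d`` the rest.
    """

    labels: list
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        for arr in ("a", "b", "c", "d"):
            setattr(self, arr, np.asarray(getattr(self, arr), dtype=int))
        if (self.a < 0).any() or (self.b < 0).any() or (self.c < 0).any() or (self.d < 0).any():
            raise ValueError("negative cell counts")
        if (self.totals() < 1).any():
            raise ValueError("every stratum must contain at least one CpG")

    def totals(self) -> np.ndarray:
        return self.a + self.b + self.c + self.d

    @property
    def n_strata(self) -> int:
        return len(self.labels)


@dataclass
class EnrichmentResult:
    set_name: str
    p_value: float
    mh_odds_ratio: float
    n_strata_used: int
    method_used: str  # "exact-mh" | "fisher-fallback" | "not-testable"
    alternative: str
    n_overlap: int = 0


def resolve_gene_region(labels) -> str:
    """Collapse a CpG's (possibly multiple) gene-region labels to one.

    TSS1500 and TSS200 are combined as "TSS", which takes highest
    precedence; the remaining chain is 1stExon > Body > 5'UTR > 3'UTR.
    An empty label list maps to "null".
    """
    if not labels:
        return "null"
    resolved = set()
    for lab in labels:
        if lab not in REGION_VOCABULARY:
            raise ValueError(f"unknown gene-region label: {lab!r}")
        resolved.add("TSS" if lab in ("TSS1500", "TSS200") else lab)
    for region in REGION_PRECEDENCE:
        if region in resolved:
            return region
    return "null"


def build_strata(annotation: CpGAnnotation, cpg_ids, platform_mode: str) -> pd.Series:
    """One stratum label per CpG.

    27K mode stratifies by CpG-island status alone; 450K mode by the
    composite Infinium chemistry type x island relation x resolved gene
    region.
    """
    if platform_mode not in ("27K", "450K"):
        raise ValueError(f"unsupported platform mode: {platform_mode!r}")
    cpg_ids = list(cpg_ids)
    missing = [c for c in cpg_ids if c not in annotation.island_relation]
    if missing:
        raise ValueError(f"CpGs missing annotation: {missing[:10]}")
    if platform_mode == "27K":
        labels = [str(annotation.island_relation[c]) for c in cpg_ids]
    else:
        missing_t = [c for c in cpg_ids if c not in annotation.infinium_type]
        if missing_t:
            raise ValueError(f"CpGs missing Infinium type: {missing_t[:10]}")
        labels = [
            "|".join(
                (
                    str(annotation.infinium_type[c]),
                    str(annotation.island_relation[c]),
                    resolve_gene_region(annotation.gene_region_labels.get(c, [])),
                )
            )
            for c in cpg_ids
        ]
    return pd.Series(labels, index=cpg_ids, name="stratum")


def stratified_tables(significant, in_set, strata) -> StratifiedTables:
    """Tally one 2x2 table per observed stratum over the analysis universe."""
    significant = np.asarray(significant, dtype=bool)
    in_set = np.asarray(in_set, dtype=bool)
    strata = np.asarray(strata)
    if not (significant.size == in_set.size == strata.size):
        raise ValueError("significant, in_set and strata must have equal length")
    if significant.size == 0:
        raise ValueError("empty analysis universe")
    labels = sorted(pd.unique(strata).tolist())
    a, b, c, d = [], [], [], []
    for lab in labels:
        mask = strata == lab
        a.append(int(np.sum(mask & significant & in_set)))
        b.append(int(np.sum(mask & significant & ~in_set)))
        c.append(int(np.sum(mask & ~significant & in_set)))
        d.append(int(np.sum(mask & ~significant & ~in_set)))
    return StratifiedTables(labels=labels, a=a, b=b, c=c, d=d)


def _hypergeom_pmf_support(n1: int, m1: int, N: int):
    """Support and pmf of a_s given fixed margins (row n1, column m1)."""
    lo = max(0, n1 + m1 - N)
    hi = min(n1, m1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, m1, n1)
    return support, pmf


def null_distribution(tables: StratifiedTables) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of T = sum_s a_s by convolving per-stratum pmfs."""
    offset = 0
    pmf = np.array([1.0])
    for s in range(tables.n_strata):
        N = int(tables.totals()[s])
        n1 = int(tables.a[s] + tables.b[s])
        m1 = int(tables.a[s] + tables.c[s])
        support_s, pmf_s = _hypergeom_pmf_support(n1, m1, N)
        pmf = np.convolve(pmf, pmf_s)
        offset += int(support_s[0])
    support = np.arange(offset, offset + pmf.size)
    return support, pmf / pmf.sum()


def is_degenerate(tables: StratifiedTables) -> bool:
    """True when T is constant under H0 (every stratum margin-degenerate)."""
    support, _ = null_distribution(tables)
    return support.size == 1


def exact_mh_test(tables: StratifiedTables, alternative: str = "greater") -> float:
    """Exact Mantel-Haenszel p-value for common odds ratio = 1.

    ``greater`` returns P(T >= t_obs); ``two-sided`` uses the
    point-probability method, summing all outcomes with mass not exceeding
    that of the observed T.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    support, pmf = null_distribution(tables)
    t_obs = int(tables.a.sum())
    if alternative == "greater":
        return float(pmf[support >= t_obs].sum())
    p_obs = float(pmf[support == t_obs][0])
    return float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())


def mh_odds_ratio(tables: StratifiedTables) -> float:
    """Mantel-Haenszel common odds ratio sum(ad/N) / sum(bc/N).

    Returns ``inf`` when only the denominator vanishes and ``nan`` for
    the undefined 0/0 case.  No continuity correction by default.
    """
    N = tables.totals().astype(float)
    num = float(np.sum(tables.a * tables.d / N))
    den = float(np.sum(tables.b * tables.c / N))
    if den == 0.0:
        return np.inf if num > 0 else np.nan
    return num / den


def enrichment_analysis(
    coef_table: pd.DataFrame,
    gene_sets: dict,
    annotation: CpGAnnotation,
    alpha: float = 0.05,
    platform_mode: str = "450K",
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Test each gene set for over-representation of significant CpGs.

    ``coef_table`` is one covariate column of a coefficient table (columns
    ``cpg`` and ``q``); the analysis universe is exactly its CpGs.
    Significant means q < ``alpha``.  Sets with no overlap with the
    universe are flagged not-testable; degenerate stratifications fall
    back to an unstratified Fisher exact test.
    """
    cpgs = coef_table["cpg"].tolist()
    if len(set(cpgs)) != len(cpgs):
        raise ValueError("coefficient table must hold a single covariate column")
    significant = (coef_table["q"].to_numpy() < alpha)
    strata = build_strata(annotation, cpgs, platform_mode).to_numpy()
    universe = set(cpgs)
    results = []
    for name, members in gene_sets.items():
        overlap = universe & set(members)
        if not overlap:
            results.append(
                EnrichmentResult(name, np.nan, np.nan, 0, "not-testable", alternative, 0)
            )
            continue
        in_set = np.array([c in overlap for c in cpgs])
        tables = stratified_tables(significant, in_set, strata)
        if is_degenerate(tables) and tables.n_strata > 1:
            a = int(np.sum(significant & in_set))
            b = int(np.sum(significant & ~in_set))
            c = int(np.sum(~significant & in_set))
            d = int(np.sum(~significant & ~in_set))
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
            collapsed = StratifiedTables(labels=["all"], a=[a], b=[b], c=[c], d=[d])
            results.append(
                EnrichmentResult(
                    name, float(p), mh_odds_ratio(collapsed), 1,
                    "fisher-fallback", alternative, len(overlap),
                )
            )
            continue
        p = exact_mh_test(tables, alternative=alternative)
        results.append(
            EnrichmentResult(
                name, p, mh_odds_ratio(tables), tables.n_strata,
                "exact-mh", alternative, len(overlap),
            )
        )
    return results
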