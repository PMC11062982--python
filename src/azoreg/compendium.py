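"""Condition-stratified meta-analysis of percentile-rank expression compendia.

A *compendium* is a collection of independent expression datasets, each a
gene x sample matrix of percentile ranks (0-100, the cross-platform unit used
by public expression repositories), together with one metadata row per sample
describing how the culture was grown (strain, medium, growth phase, OD600,
glucose %, agitation, temperature).

The analysis asks, for one focal gene: under which culture conditions is its
percentile-rank expression shifted relative to the gene's overall behaviour?
Samples are stratified per condition into categories (numeric fields are
binned), and each category's values are compared against the grand median of
all values for that condition with a one-sample Wilcoxon signed-rank test,
Benjamini-Hochberg adjusted across the categories of that condition.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROWTH_PHASES = ("lag", "log", "stationary", "unknown")

#: Metadata fields that can carry a planted / tested condition effect.
CONDITION_KEYS = (
    "od600",
    "growth_phase",
    "medium",
    "glucose_pct",
    "agitation_rpm",
    "temperature_C",
)

METADATA_COLUMNS = ("dataset_id", "strain") + CONDITION_KEYS


class CompendiumError(ValueError):
    """Invalid compendium input (missing gene, malformed matrix, bad key)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """One dataset: a gene x sample matrix of percentile ranks."""

    dataset_id: str
    ranks: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.ranks.index.has_duplicates:
            dupes = self.ranks.index[self.ranks.index.duplicated()].unique()
            raise CompendiumError(
                f"dataset {self.dataset_id!r}: duplicate gene ids {list(dupes)[:5]}"
            )
        vals = self.ranks.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise CompendiumError(
                f"dataset {self.dataset_id!r}: percentile ranks outside [0, 100]"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ranks.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ranks.index)


@dataclass
class Compendium:
    """A set of expression datasets plus one metadata row per sample."""

    datasets: list[ExpressionDataset]
    metadata: pd.DataFrame  # index = sample id; columns METADATA_COLUMNS

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(ids) != len(set(ids)):
            raise CompendiumError("duplicate dataset ids in compendium")

    @property
    def n_samples(self) -> int:
        return int(sum(len(d.sample_ids) for d in self.datasets))

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    def dataset(self, dataset_id: str) -> ExpressionDataset:
        for d in self.datasets:
            if d.dataset_id == dataset_id:
                return d
        raise KeyError(dataset_id)

    def gene_values(self, gene: str) -> pd.Series:
        """Percentile ranks of one gene across every sample that measures it."""
        parts = [d.ranks.loc[gene] for d in self.datasets if gene in d.ranks.index]
        if not parts:
            raise CompendiumError(f"gene {gene!r} absent from every dataset")
        return pd.concat(parts)

    def subset_samples(self, sample_ids: Iterable[str]) -> "Compendium":
        keep = set(sample_ids)
        new_datasets = []
        for d in self.datasets:
            cols = [s for s in d.sample_ids if s in keep]
            if cols:
                new_datasets.append(ExpressionDataset(d.dataset_id, d.ranks[cols]))
        meta = self.metadata.loc[self.metadata.index.isin(keep)]
        return Compendium(new_datasets, meta)


# ---------------------------------------------------------------------------
# percentile-rank transform
# ---------------------------------------------------------------------------


def to_percentile_ranks(raw: pd.DataFrame) -> pd.DataFrame:
    """Convert a raw gene x sample matrix to within-sample percentile ranks.

    Each column (sample) is ranked independently with average ranks for ties;
    the percentile of a gene is ``average_rank / n_genes * 100``. The
    transform is order-preserving within each sample and idempotent up to
    re-ranking.
    """
    if raw.shape[0] < 1 or raw.shape[1] < 1:
        raise CompendiumError("matrix must have at least one gene and one sample")
    arr = raw.to_numpy(dtype=float)
    if np.isnan(arr).any():
        g, s = np.argwhere(np.isnan(arr))[0]
        raise CompendiumError(
            f"missing value at gene {raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    ranks = stats.rankdata(arr, axis=0, method="average")
    return pd.DataFrame(
        ranks / arr.shape[0] * 100.0, index=raw.index, columns=raw.columns
    )


# ---------------------------------------------------------------------------
# sample filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterResult:
    compendium: Compendium
    removed: dict[str, int]  # reason -> number of samples removed
    datasets_dropped: list[str]


def filter_compendium(
    compendium: Compendium,
    focal_gene: str,
    strain_pattern: str | None = None,
) -> FilterResult:
    """Drop samples lacking a focal-gene value (and optionally by strain).

    ``strain_pattern`` is a regular expression searched against the strain
    label (e.g. ``"K-12"`` retains every K-12 substrain). Datasets left with
    zero samples are removed; per-reason removal counts are returned.
    """
    has_focal: set[str] = set()
    any_focal = False
    for d in compendium.datasets:
        if focal_gene in d.ranks.index:
            any_focal = True
            row = d.ranks.loc[focal_gene]
            has_focal.update(row.index[row.notna()])
    if not any_focal:
        raise CompendiumError(f"focal gene {focal_gene!r} absent from every dataset")

    removed = {"missing_focal": 0, "strain_mismatch": 0}
    keep: list[str] = []
    pat = re.compile(strain_pattern) if strain_pattern else None
    for d in compendium.datasets:
        for s in d.sample_ids:
            if s not in has_focal:
                removed["missing_focal"] += 1
                continue
            if pat is not None:
                strain = compendium.metadata.at[s, "strain"] if s in compendium.metadata.index else None
                if not (isinstance(strain, str) and pat.search(strain)):
                    removed["strain_mismatch"] += 1
                    continue
            keep.append(s)
    sub = compendium.subset_samples(keep)
    dropped = sorted(
        {d.dataset_id for d in compendium.datasets}
        - {d.dataset_id for d in sub.datasets}
    )
    return FilterResult(sub, removed, dropped)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NumericBin:
    label: str
    lo: float
    hi: float
    lo_closed: bool = True
    hi_closed: bool = False

    def contains(self, x: float) -> bool:
        above = x > self.lo or (self.lo_closed and x == self.lo)
        below = x < self.hi or (self.hi_closed and x == self.hi)
        return bool(above and below)


_INF = math.inf

#: Default numeric binnings; the OD bins follow the reported low/mid/high
#: contrast (0.4 and 0.7 breakpoints), glucose the 0.02 / 0.1-0.4 / 0.5 %
#: contrast, agitation the slow (<=60 rpm) vs fast (200-300 rpm) contrast and
#: temperature the 25-30 vs 37 C contrast. Categorical fields use identity.
DEFAULT_BINNINGS: dict[str, tuple[NumericBin, ...] | None] = {
    "od600": (
        NumericBin("<0.4", -_INF, 0.4),
        NumericBin("0.4-0.7", 0.4, 0.7, hi_closed=True),
        NumericBin(">0.7", 0.7, _INF, lo_closed=False),
    ),
    "glucose_pct": (
        NumericBin("~0.02%", -_INF, 0.05),
        NumericBin("0.1-0.4%", 0.05, 0.45),
        NumericBin(">=0.5%", 0.45, _INF),
    ),
    "agitation_rpm": (
        NumericBin("<=60 rpm", -_INF, 60, hi_closed=True),
        NumericBin("61-199 rpm", 60, 200, lo_closed=False),
        NumericBin("200-300 rpm", 200, _INF),
    ),
    "temperature_C": (
        NumericBin("25-30 C", -_INF, 30, hi_closed=True),
        NumericBin("37 C", 30, _INF, lo_closed=False),
    ),
    "growth_phase": None,
    "medium": None,
    "strain": None,
}


def bin_label(
    condition_key: str,
    value,
    binnings: Mapping[str, tuple[NumericBin, ...] | None] | None = None,
) -> str | None:
    """Category label for one metadata value, or None if missing/unbinnable."""
    binnings = DEFAULT_BINNINGS if binnings is None else binnings
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    bins = binnings.get(condition_key)
    if bins is None:  # categorical: identity binning
        return str(value)
    x = float(value)
    for b in bins:
        if b.contains(x):
            return b.label
    return None


@dataclass
class StratifyResult:
    condition_key: str
    strata: list[tuple[str, np.ndarray]]  # (category label, percentile ranks)
    n_excluded: int
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def all_values(self) -> np.ndarray:
        if not self.strata:
            return np.array([], dtype=float)
        return np.concatenate([v for _, v in self.strata])


def stratify(
    compendium: Compendium,
    gene: str,
    condition_key: str,
    binnings: Mapping[str, tuple[NumericBin, ...] | None] | None = None,
) -> StratifyResult:
    """Partition one gene's values by a metadata condition.

    Every sample with a non-missing condition value lands in exactly one
    category; samples with a missing condition value (or without an
    expression value for the gene) are excluded and counted.
    """
    valid = tuple(k for k in METADATA_COLUMNS if k != "dataset_id")
    if condition_key not in valid:
        raise CompendiumError(
            f"unknown condition key {condition_key!r}; valid keys: {valid}"
        )
    values = compendium.gene_values(gene)
    excluded = {"missing_condition": 0, "missing_expression": 0, "unbinnable": 0}
    groups: dict[str, list[float]] = {}
    for s in compendium.metadata.index:
        if s not in values.index or pd.isna(values[s]):
            excluded["missing_expression"] += 1
            continue
        raw = compendium.metadata.at[s, condition_key]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            excluded["missing_condition"] += 1
            continue
        label = bin_label(condition_key, raw, binnings)
        if label is None:
            excluded["unbinnable"] += 1
            continue
        groups.setdefault(label, []).append(float(values[s]))
    strata = [(lab, np.asarray(groups[lab], dtype=float)) for lab in sorted(groups)]
    return StratifyResult(condition_key, strata, sum(excluded.values()), excluded)


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

MIN_CATEGORY_N = 3  # below this the Wilcoxon test is not attempted


@dataclass
class ConditionSummary:
    condition_key: str
    category: str
    n: int
    values: np.ndarray
    median: float
    grand_median: float
    p_value: float | None
    p_adjusted: float | None = None
    significant: bool = False
    status: str = "tested"  # "tested" | "untestable"


def category_significance(
    category_values: Sequence[float],
    all_values: Sequence[float],
    alpha: float = 0.05,
    condition_key: str = "",
    category: str = "",
) -> ConditionSummary:
    """One-sample Wilcoxon signed-rank of a category against the grand median.

    The grand median is taken over *all* values of the condition (the
    category's own values included). Categories with fewer than three samples
    are flagged untestable rather than raising. The p-value here is
    unadjusted; use :func:`condition_significance` for the BH-adjusted set.
    """
    vals = np.asarray(category_values, dtype=float)
    allv = np.asarray(all_values, dtype=float)
    gm = float(np.median(allv))
    summary = ConditionSummary(
        condition_key=condition_key,
        category=category,
        n=vals.size,
        values=vals,
        median=float(np.median(vals)) if vals.size else math.nan,
        grand_median=gm,
        p_value=None,
    )
    if vals.size < MIN_CATEGORY_N:
        summary.status = "untestable"
        return summary
    diffs = vals - gm
    if np.all(diffs == 0):
        p = 1.0
    else:
        # zsplit keeps zero differences (splitting their ranks), so n is not
        # silently reduced on rank-scale data with many ties at the median.
        p = float(stats.wilcoxon(diffs, zero_method="zsplit", alternative="two-sided").pvalue)
    summary.p_value = p
    summary.significant = p < alpha  # provisional; BH applied across categories
    return summary


def condition_significance(
    strat: StratifyResult, alpha: float = 0.05
) -> list[ConditionSummary]:
    """Per-category Wilcoxon tests with BH adjustment across one condition."""
    allv = strat.all_values
    summaries = [
        category_significance(
            vals, allv, alpha, condition_key=strat.condition_key, category=cat
        )
        for cat, vals in strat.strata
    ]
    testable = [s for s in summaries if s.status == "tested"]
    if testable:
        rej, p_adj, _, _ = multipletests(
            [s.p_value for s in testable], alpha=alpha, method="fdr_bh"
        )
        for s, r, p in zip(testable, rej, p_adj):
            s.p_adjusted = float(p)
            s.significant = bool(r)
    return summaries


def analyze_conditions(
    compendium: Compendium,
    gene: str,
    condition_keys: Sequence[str] = CONDITION_KEYS,
    alpha: float = 0.05,
    binnings: Mapping[str, tuple[NumericBin, ...] | None] | None = None,
) -> pd.DataFrame:
    """Full stratified meta-analysis of one gene: one row per category."""
    rows = []
    for key in condition_keys:
        strat = stratify(compendium, gene, key, binnings)
        for s in condition_significance(strat, alpha):
            rows.append(
                {
                    "condition": s.condition_key,
                    "category": s.category,
                    "n": s.n,
                    "median": s.median,
                    "grand_median": s.grand_median,
                    "p_value": s.p_value,
                    "p_adjusted": s.p_adjusted,
                    "significant": s.significant,
                    "status": s.status,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "category",
            "n",
            "median",
            "grand_median",
            "p_value",
            "p_adjusted",
            "significant",
            "status",
        ],
    )


def long_format(compendium: Compendium, gene: str, condition_key: str,
                binnings=None) -> pd.DataFrame:
    """Boxplot-ready long table: one row per (category, value)."""
    strat = stratify(compendium, gene, condition_key, binnings)
    rows = [
        {"condition": condition_key, "category": cat, "percentile_rank": v}
        for cat, vals in strat.strata
        for v in vals
    ]
    return pd.DataFrame(rows, columns=["condition", "category", "percentile_rank"])
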