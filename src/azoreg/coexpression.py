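"""Cross-dataset consensus co-expression around a focal gene.

Within each dataset the focal gene's *profile neighbors* are the top-K genes
(K = 200 by default) whose expression profiles correlate best with the focal
gene's. Counting, for every gene, the number of independent datasets in which
it makes that list gives a consensus statistic that is robust to any single
experiment's quirks: genes repeatedly co-ranked with the focal gene across
unrelated studies are candidate functional partners. Candidates are genes
whose repetition count reaches at least half the maximum observed count.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compendium import Compendium, ExpressionDataset

DEFAULT_K = 200

UNANNOTATED = "unannotated"


class DatasetSkipped(Exception):
    """A dataset cannot contribute a neighbor list (too few samples, flat focal)."""

    def __init__(self, dataset_id: str, reason: str):
        self.dataset_id = dataset_id
        self.reason = reason
        super().__init__(f"{dataset_id}: {reason}")


@dataclass
class NeighborList:
    dataset_id: str
    focal: str
    neighbors: list[tuple[str, float]]  # (gene, r), r non-increasing
    k: int

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.neighbors]


@dataclass
class ConsensusTable:
    """gene -> number of datasets in which it neighbors the focal gene."""

    counts: pd.Series  # index gene, int values
    n_datasets: int

    def histogram(self) -> dict[int, int]:
        """count value -> number of genes at that count."""
        return {int(c): int(n) for c, n in sorted(Counter(self.counts.to_numpy()).items())}

    @classmethod
    def from_histogram(cls, histogram: Mapping[int, int], n_datasets: int | None = None
                       ) -> "ConsensusTable":
        """Rebuild a (gene-anonymous) table from a published count histogram."""
        genes, counts = [], []
        i = 0
        for c in sorted(histogram):
            for _ in range(histogram[c]):
                genes.append(f"gene_{i:05d}")
                counts.append(int(c))
                i += 1
        n = n_datasets if n_datasets is not None else (max(histogram) if histogram else 0)
        return cls(pd.Series(counts, index=genes, dtype=int), n)


def _correlations(matrix: np.ndarray, focal_row: int, method: str) -> np.ndarray:
    """Correlation of every row against the focal row; NaN where undefined."""
    x = matrix.astype(float)
    if method == "spearman":
        from scipy.stats import rankdata

        x = rankdata(x, axis=1, method="average")
        method = "pearson"
    if method == "pearson":
        x = x - x.mean(axis=1, keepdims=True)
        norms = np.sqrt((x**2).sum(axis=1))
        f = x[focal_row]
        nf = norms[focal_row]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (x @ f) / (norms * nf)
        r[norms == 0] = np.nan
        return np.clip(r, -1.0, 1.0)
    if method == "cosine":
        norms = np.sqrt((x**2).sum(axis=1))
        f = x[focal_row]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (x @ f) / (norms * norms[focal_row])
        r[norms == 0] = np.nan
        return np.clip(r, -1.0, 1.0)
    raise ValueError(f"unknown similarity method {method!r}")


def profile_neighbors(
    dataset: ExpressionDataset,
    focal: str,
    k: int = DEFAULT_K,
    method: str = "pearson",
) -> NeighborList:
    """Top-K profile neighbors of the focal gene within one dataset.

    Pearson correlation on percentile-rank profiles (equivalent to Spearman
    on the underlying raw values) is the default similarity. Genes whose
    profile has zero variance are excluded (undefined r); ties in r are
    broken lexicographically by gene id. Raises :class:`DatasetSkipped` when
    the dataset has fewer than three samples or a flat focal profile.
    """
    if focal not in dataset.ranks.index:
        raise DatasetSkipped(dataset.dataset_id, f"focal gene {focal!r} not present")
    if dataset.ranks.shape[1] < 3:
        raise DatasetSkipped(dataset.dataset_id, "fewer than 3 samples")
    genes = dataset.ranks.index.to_numpy()
    mat = dataset.ranks.to_numpy(dtype=float)
    focal_row = int(np.flatnonzero(genes == focal)[0])
    if np.ptp(mat[focal_row]) == 0:
        raise DatasetSkipped(dataset.dataset_id, "focal profile has zero variance")
    r = _correlations(mat, focal_row, method)
    order = sorted(
        (
            (float(r[i]), str(genes[i]))
            for i in range(len(genes))
            if i != focal_row and not math.isnan(r[i])
        ),
        key=lambda t: (-t[0], t[1]),
    )
    return NeighborList(
        dataset.dataset_id, focal, [(g, rv) for rv, g in order[:k]], k
    )


def compendium_neighbor_lists(
    compendium: Compendium, focal: str, k: int = DEFAULT_K, method: str = "pearson"
) -> tuple[list[NeighborList], dict[str, str]]:
    """Neighbor lists for every usable dataset; skipped datasets are logged."""
    lists: list[NeighborList] = []
    skipped: dict[str, str] = {}
    for d in compendium.datasets:
        try:
            lists.append(profile_neighbors(d, focal, k, method))
        except DatasetSkipped as exc:
            skipped[d.dataset_id] = exc.reason
    return lists, skipped


def consensus_counts(lists: Iterable[NeighborList]) -> ConsensusTable:
    """Per-gene repetition counts across datasets (each dataset counts once)."""
    lists = list(lists)
    seen: set[str] = set()
    counter: Counter[str] = Counter()
    for nl in lists:
        if nl.dataset_id in seen:
            raise ValueError(f"duplicate dataset id {nl.dataset_id!r} in neighbor lists")
        seen.add(nl.dataset_id)
        counter.update(set(nl.genes))
    counts = pd.Series(counter, dtype=int).sort_values(ascending=False)
    counts = counts.iloc[np.lexsort((counts.index, -counts.to_numpy()))]
    return ConsensusTable(counts, len(lists))


def candidate_threshold(table: ConsensusTable) -> int:
    """Half of the maximum repetition count, rounded up."""
    if table.counts.empty:
        raise ValueError("empty consensus table")
    return math.ceil(int(table.counts.max()) / 2)


def select_candidates(table: ConsensusTable, threshold: int) -> list[str]:
    """Genes with repetition count >= threshold, by (count desc, gene id)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    sel = table.counts[table.counts >= threshold]
    return sorted(sel.index, key=lambda g: (-int(sel[g]), g))


def summarize_categories(
    genes: Sequence[str], annotation: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Tally functional categories over a candidate gene list.

    A multi-category gene counts once per category; genes absent from the
    annotation are tallied under ``unannotated``. Percentages are integer
    *truncations* of 100*count/len(genes), the convention used consistently
    across this package.
    """
    if not genes:
        raise ValueError("empty gene list")
    counter: Counter[str] = Counter()
    for g in genes:
        cats = [c for c in annotation.get(g, []) if c]
        if not cats:
            counter[UNANNOTATED] += 1
        else:
            for c in set(cats):
                counter[c] += 1
    n = len(genes)
    rows = [
        {"category": c, "n_genes": k, "pct_of_candidates": (100 * k) // n}
        for c, k in sorted(counter.items(), key=lambda t: (-t[1], t[0]))
    ]
    return pd.DataFrame(rows, columns=["category", "n_genes", "pct_of_candidates"])


def read_annotation_tsv(path) -> dict[str, list[str]]:
    """Read a gene<TAB>category table (repeated rows for multi-category genes)."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["gene", "category"],
                     header=None, dtype=str)
    # tolerate a header row
    if not df.empty and df.iloc[0].tolist() == ["gene", "category"]:
        df = df.iloc[1:]
    ann: dict[str, list[str]] = {}
    for g, c in df.itertuples(index=False):
        ann.setdefault(str(g), []).append(str(c))
    return ann
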