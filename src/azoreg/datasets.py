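"""Packaged worked-example tables from the published screen.

Three small fixtures ship with the package:

* the repetition histogram of the focal gene's profile neighbors across the
  50-dataset compendium (gene identities are not published, so the rebuilt
  consensus table is gene-anonymous);
* the normalized decolorization percentages of the 20 confirmed screen
  mutants with the gene each insertion interrupted;
* the functional-annotation table of the candidate gene set (a
  reconstruction; its "Putative/ uncharacterized proteins" category is
  complete, other categories are best-effort).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .coexpression import ConsensusTable

#: Number of candidate genes in the published set (profile neighbors in >= 5
#: datasets). The reconstructed annotation fixture recovers 107 of the names.
N_PUBLISHED_CANDIDATES = 112


def _data_path(name: str):
    return resources.files("azoreg.data").joinpath(name)


def load_consensus_histogram() -> dict[int, int]:
    """Published repetition histogram: count value -> number of genes."""
    df = pd.read_csv(_data_path("consensus_histogram.tsv"), sep="\t", comment="#")
    return dict(zip(df["repetitions"].astype(int), df["n_genes"].astype(int)))


def load_published_consensus() -> ConsensusTable:
    """Gene-anonymous consensus table rebuilt from the published histogram."""
    return ConsensusTable.from_histogram(load_consensus_histogram(), n_datasets=50)


def load_screen_table() -> pd.DataFrame:
    """The 20 confirmed mutants' normalized decolorization % and gene hits."""
    return pd.read_csv(_data_path("table2_screen.tsv"), sep="\t", comment="#")


def load_annotation_table() -> pd.DataFrame:
    """Long-format gene/category annotation table (one row per membership)."""
    return pd.read_csv(
        _data_path("table1_annotations.tsv"), sep="\t", comment="#",
        names=["gene", "category"], header=None,
    )


def load_annotation_map() -> dict[str, list[str]]:
    """gene -> list of functional categories."""
    ann: dict[str, list[str]] = {}
    for g, c in load_annotation_table().itertuples(index=False):
        ann.setdefault(str(g), []).append(str(c))
    return ann


def published_candidate_genes() -> list[str]:
    """The published candidate set, padded to its true size.

    Returns the 107 recovered gene names plus anonymous placeholders up to
    the published total of 112 (five names could not be recovered from the
    source table); placeholders carry no annotation.
    """
    genes = sorted(set(load_annotation_table()["gene"]))
    pads = [f"unrecovered_{i}" for i in range(N_PUBLISHED_CANDIDATES - len(genes))]
    return genes + pads
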