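"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and metadata travel as TSV, plates and Ct tables as CSV,
sequences as FASTA (via Biopython), gene annotations as a four-column TSV
(1-based inclusive coordinates) and planted truth as JSON. All writers are
deterministic: fixed column orders, sorted keys, no timestamps.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .compendium import METADATA_COLUMNS, Compendium, ExpressionDataset
from .simulate import TruthBundle

# -- expression compendium ---------------------------------------------------


def write_compendium(compendium: Compendium, outdir: str | Path) -> None:
    """One ``datasets/<id>.tsv`` matrix per dataset plus ``metadata.tsv``."""
    outdir = Path(outdir)
    (outdir / "datasets").mkdir(parents=True, exist_ok=True)
    for d in compendium.datasets:
        d.ranks.to_csv(outdir / "datasets" / f"{d.dataset_id}.tsv",
                       sep="\t", index_label="gene")
    meta = compendium.metadata.reindex(columns=list(METADATA_COLUMNS))
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index_label="sample_id")


def read_compendium(indir: str | Path) -> Compendium:
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.tsv", sep="\t", index_col="sample_id")
    datasets = [
        ExpressionDataset(p.stem, pd.read_csv(p, sep="\t", index_col="gene"))
        for p in sorted((indir / "datasets").glob("*.tsv"))
    ]
    return Compendium(datasets, meta)


# -- plates and Ct tables ----------------------------------------------------


def write_plates(plates: pd.DataFrame, path: str | Path) -> None:
    plates.to_csv(path, index=False)


def read_plates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- sequences and annotations -----------------------------------------------


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path), "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    ann[["gene", "start", "end", "strand"]].to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- truth -------------------------------------------------------------------


def write_truth(truth: TruthBundle, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path: str | Path) -> TruthBundle:
    return TruthBundle.from_json(Path(path).read_text())


# -- generic tables ----------------------------------------------------------


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
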