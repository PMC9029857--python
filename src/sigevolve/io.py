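"""Readers and writers for the pipeline's plain-text artifacts.

Formats:

* expression TSV — first column ``gene_id``, remaining columns sample ids,
  tab-separated; a sidecar ``<file>.manifest.json`` records the scale tag.
* labels CSV — ``sample_id,label`` with label 1 (positive/GBM) or 0.
* GMT — standard tab-separated gene sets (name, description, members);
  read through gseapy's parser.
* candidate-panel TSV, solution-archive TSV, signature TSV — small
  pipeline outputs documented in the respective writers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CandidatePanel,
    ExpressionMatrix,
    SolutionArchive,
    SolutionRecord,
    ValidationError,
)


# -- expression matrix -------------------------------------------------------

def _manifest_path(path) -> Path:
    return Path(str(path) + ".manifest.json")


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    _manifest_path(path).write_text(json.dumps({"scale": matrix.scale}) + "\n")


def read_expression_tsv(path, scale: str | None = None) -> ExpressionMatrix:
    """Read an expression TSV; scale comes from the sidecar manifest unless given."""
    if scale is None:
        mpath = _manifest_path(path)
        scale = json.loads(mpath.read_text())["scale"] if mpath.exists() else "log2"
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df.index.name = None
    return ExpressionMatrix(df, scale)


# -- phenotype labels --------------------------------------------------------

def write_labels_csv(labels: pd.Series, path) -> None:
    labels.rename("label").rename_axis("sample_id").to_csv(path)


def read_labels_csv(path) -> pd.Series:
    s = pd.read_csv(path, index_col="sample_id")["label"].astype(int)
    bad = set(s.unique()) - {0, 1}
    if bad:
        raise ValidationError(f"labels must be 0/1, found {sorted(bad)}")
    return s


# -- gene sets (GMT) ---------------------------------------------------------

def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    from gseapy import read_gmt as _read_gmt

    return _read_gmt(str(path))


# -- candidate panel ---------------------------------------------------------

def write_panel_tsv(panel: CandidatePanel, path) -> None:
    df = panel.table.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_panel_tsv(path) -> CandidatePanel:
    return CandidatePanel(pd.read_csv(path, sep="\t", index_col="gene_id"))


# -- solution archive --------------------------------------------------------

def write_archive_tsv(archive: SolutionArchive, path, top_k: int | None = None) -> None:
    """Serialize an archive as ``measure<TAB>rank<TAB>fitness<TAB>bitstring``.

    With ``top_k`` set, only the deduplicated top-k ranking per measure is
    written; otherwise every raw record is written in collection order
    (rank then means collection index).
    """
    with open(path, "w") as fh:
        fh.write("measure\trank\tfitness\tbits\n")
        for measure in archive.measures:
            records = (
                archive.ranked(measure, top_k)
                if top_k is not None
                else archive.records[measure]
            )
            for rank, rec in enumerate(records, start=1):
                bits = "".join(map(str, rec.bits.astype(int)))
                fh.write(f"{measure}\t{rank}\t{rec.fitness:.12g}\t{bits}\n")


def read_archive_tsv(path) -> SolutionArchive:
    df = pd.read_csv(path, sep="\t", dtype={"bits": str})
    if df.empty:
        raise ValidationError("empty archive file")
    panel_size = len(df["bits"].iloc[0])
    archive = SolutionArchive(panel_size=panel_size)
    for row in df.itertuples(index=False):
        bits = np.frombuffer(row.bits.encode(), dtype=np.uint8) - ord("0")
        archive.add(row.measure, SolutionRecord(bits.astype(np.int8), float(row.fitness)))
    return archive


# -- signature ---------------------------------------------------------------

def write_signature_tsv(signature: pd.DataFrame, path) -> None:
    df = signature.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_signature_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
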