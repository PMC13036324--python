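"""Readers and writers for the pipeline's on-disk formats.

Tables are TSV with a header row, trees are Newick with branch lengths,
genomes are FASTA, ground-truth sidecars and reports are JSON. Readers
validate the columns each stage requires so malformed inputs fail at the
boundary rather than deep inside a computation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import MissingDataError


def read_tsv(path, required: tuple[str, ...] = (), index_col=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingDataError(f"{path}: missing required columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    if hasattr(obj, "item"):
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
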