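"""FASTA/TSV/newick/YAML I/O helpers shared by the pipeline and CLI."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .copy_calling import CloneLibrary, CopySet


def read_fasta(path) -> dict:
    """FASTA file -> {id: sequence} (ordered by file, keys unique)."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out


def write_fasta(sequences: dict, path, descriptions: dict | None = None):
    records = [
        SeqRecord(Seq(seq), id=name,
                  description=(descriptions or {}).get(name, ""))
        for name, seq in sequences.items()
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def read_clone_library(path, sample_id: str | None = None) -> CloneLibrary:
    seqs = read_fasta(path)
    sid = sample_id or Path(path).stem
    return CloneLibrary(sample_id=sid, records=list(seqs.items()))


def write_copyset_fasta(copyset: CopySet, path):
    seqs = {c.copy_id: c.consensus for c in copyset.copies}
    desc = {c.copy_id: f"members={c.count}" for c in copyset.copies}
    write_fasta(seqs, path, descriptions=desc)


def write_tsv(df: pd.DataFrame, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(data: dict, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
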