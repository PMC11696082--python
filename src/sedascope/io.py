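"""File I/O: FASTQ/FASTA via Biopython, taxonomy and truth tables as TSV."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Read
from .simulate import SimTaxonomy


def write_fastq(reads, path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        reads.append(
            Read(
                id=rec.id,
                seq=str(rec.seq),
                qual="".join(chr(q + 33) for q in quals),
            )
        )
    return reads


def write_fasta(entries: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in entries.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_taxonomy(taxonomy: SimTaxonomy, path) -> None:
    taxonomy.to_frame().to_csv(path, sep="\t", index=False)


def read_taxonomy_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
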