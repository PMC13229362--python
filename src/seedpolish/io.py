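"""FASTA/FASTQ reading and writing (plain or gzipped), via Biopython."""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def _open_text(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> dict[str, str]:
    """Ordered name -> uppercase sequence mapping (name = first token)."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            out[title.split()[0]] = seq.upper()
    if not out:
        raise ValueError(f"no records in {path}")
    return out


def iter_reads(path) -> Iterator[str]:
    """Sequences from a FASTA or FASTQ file, sniffed from the first byte."""
    with _open_text(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == "@":
            for _, seq, _ in FastqGeneralIterator(fh):
                yield seq.upper()
        elif first == ">":
            for _, seq in SimpleFastaParser(fh):
                yield seq.upper()
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ")


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path, width: int = 60) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    """(name, seq) pairs as FASTQ with uniform placeholder quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
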