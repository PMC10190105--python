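"""Genome input: FASTA parsing and canonical k-mer decomposition.

Two input conventions are supported, mirroring common practice for
assembled-genome collections:

* **single-file mode** — one (possibly gzipped) multi-record FASTA where
  every record is a genome;
* **list mode** — a text file naming one FASTA file per line, where every
  *file* is a genome and all its records (contigs) are pooled into one
  k-mer stream.  Pooling never fabricates k-mers spanning two contigs.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import Iterator

from Bio import SeqIO

from .errors import EmptyDatasetError, InputError

_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """One genome: identifier, contigs and provenance.

    ``sequence`` is the concatenation of the contigs and ``length`` the
    total base count; k-mer extraction always walks contigs separately.
    """

    id: str
    contigs: tuple[str, ...]
    source: str = ""

    @property
    def sequence(self) -> str:
        return "".join(self.contigs)

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _dedupe_ids(records: list[GenomeRecord]) -> list[GenomeRecord]:
    seen: dict[str, int] = {}
    out = []
    for rec in records:
        n = seen.get(rec.id, 0) + 1
        seen[rec.id] = n
        if n == 1:
            out.append(rec)
        else:
            out.append(GenomeRecord(f"{rec.id}__{n}", rec.contigs, rec.source))
    return out


def read_single_fasta(path: str) -> list[GenomeRecord]:
    """Read a multi-record FASTA; each record becomes one genome.

    The genome id is the first whitespace-delimited token of the header;
    sequences are uppercased.  Raises :class:`InputError` if the file is
    missing and :class:`EmptyDatasetError` if it holds no records.
    """
    if not os.path.exists(path):
        raise InputError(f"FASTA file not found: {path}")
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(GenomeRecord(rec.id, (str(rec.seq).upper(),), str(path)))
    if not records:
        raise EmptyDatasetError(f"no FASTA records in {path}")
    return _dedupe_ids(records)


def read_genome_list(path: str) -> list[GenomeRecord]:
    """Read a file-of-filenames; each listed FASTA file becomes one genome.

    Blank lines and ``#`` comments are skipped; relative paths are resolved
    against the directory of the list file.  The genome id is the file
    basename without extensions.
    """
    if not os.path.exists(path):
        raise InputError(f"genome list not found: {path}")
    base = os.path.dirname(os.path.abspath(path))
    genomes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            entry = line.strip()
            if not entry or entry.startswith("#"):
                continue
            fpath = entry if os.path.isabs(entry) else os.path.join(base, entry)
            if not os.path.exists(fpath):
                raise InputError(f"line {lineno} of {path}: file not found: {entry}")
            name = os.path.basename(fpath)
            for ext in (".gz", ".fa", ".fasta", ".fna"):
                if name.endswith(ext):
                    name = name[: -len(ext)]
            contigs = []
            with _open_text(fpath) as gfh:
                for rec in SeqIO.parse(gfh, "fasta"):
                    contigs.append(str(rec.seq).upper())
            if not contigs:
                raise InputError(f"line {lineno} of {path}: no FASTA records in {entry}")
            genomes.append(GenomeRecord(name, tuple(contigs), fpath))
    if not genomes:
        raise EmptyDatasetError(f"no genome files listed in {path}")
    return _dedupe_ids(genomes)


def canonical_kmers(sequence: str, k: int) -> Iterator[str]:
    """Yield the canonical form of every valid k-mer window, in order.

    A window is valid when it contains only A/C/G/T (case-insensitive);
    the canonical form is the lexicographically smaller of the window and
    its reverse complement.  ``k`` longer than the sequence yields nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.upper()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if any(ch not in "ACGT" for ch in window):
            continue
        rc = reverse_complement(window)
        yield window if window <= rc else rc


def genome_kmers(genome: GenomeRecord, k: int) -> Iterator[str]:
    """Canonical k-mers of a genome, walking contigs independently."""
    for contig in genome.contigs:
        yield from canonical_kmers(contig, k)


def write_fasta(genomes: list[GenomeRecord], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            seq = g.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
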