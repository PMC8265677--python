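"""Genome and annotation I/O plus the ApT-duplex coordinate geometry.

All coordinates inside the package are 0-based half-open; 1-based
conventions exist only at file boundaries (GFF3). A "Crick-strand adenine
at coordinate p" means the Watson base at p is T, so calls on both strands
share one genomic coordinate system.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from ._util import reverse_complement

VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class GeneModel:
    """A gene interval; ``tss`` is the strand-aware transcription start."""

    gene_id: str
    chrom: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: bad interval [{self.start},{self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AptDuplex:
    """One 5'-ApT-3' dinucleotide: Watson A at ``watson_pos``, Crick A at +1."""

    chrom: str
    watson_pos: int

    @property
    def crick_pos(self) -> int:
        return self.watson_pos + 1


@dataclass
class Genome:
    """Ordered chromosome name -> uppercase sequence mapping."""

    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ParseError(f"chromosome {name}: invalid bases {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    def sequence(self, name: str) -> str:
        try:
            return self.chromosomes[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def base(self, chrom: str, pos: int, strand: str = "+") -> str:
        """Reference base at (pos, strand), read on that strand."""
        b = self.sequence(chrom)[pos]
        return b if strand == "+" else reverse_complement(b)

    def checksum(self) -> str:
        h = hashlib.md5()
        for name, seq in self.chromosomes.items():
            h.update(name.encode())
            h.update(seq.encode())
        return h.hexdigest()

    def drop(self, names: Iterable[str]) -> "Genome":
        """Copy without the given chromosomes (e.g. an rDNA exclusion list)."""
        names = set(names)
        return Genome({n: s for n, s in self.chromosomes.items() if n not in names})


def read_fasta(path) -> Genome:
    """Load a multi-record FASTA; lowercase is upcased, N is allowed."""
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ParseError(f"duplicate chromosome {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ParseError(f"chromosome {rec.id}: invalid bases {sorted(bad)}")
        chroms[rec.id] = seq
    if not chroms:
        raise ParseError(f"no records in FASTA {path}")
    return Genome(chroms)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3_genes(path, genome: Genome) -> list[GeneModel]:
    """Read ``gene`` features from GFF3 (1-based inclusive) into 0-based models."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            chrom, _source, ftype, start1, end1, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            if chrom not in genome:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: gene strand must be + or -, got {strand!r}")
            start = int(start1) - 1
            end = int(end1)
            if not 0 <= start < end <= genome.lengths[chrom]:
                raise ParseError(
                    f"{path}:{lineno}: gene interval {start1}-{end1} outside {chrom} "
                    f"(length {genome.lengths[chrom]})"
                )
            gene_id = _gff_attr(attrs, "ID") or f"gene{lineno}"
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, chrom, start, end, strand))
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsixma\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def _gff_attr(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + "="):
            return item[len(key) + 1 :]
    return None


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def apt_watson_positions(seq: str) -> np.ndarray:
    """0-based positions p with seq[p:p+2] == 'AT' (occurrences never overlap)."""
    a = _seq_array(seq)
    if len(a) < 2:
        return np.empty(0, dtype=np.int64)
    return np.where((a[:-1] == ord("A")) & (a[1:] == ord("T")))[0].astype(np.int64)


def index_apt_duplexes(genome: Genome) -> list[AptDuplex]:
    """One duplex per Watson 'AT'; its Crick A (at p+1) also reads ApT 5'->3'."""
    out: list[AptDuplex] = []
    for name, seq in genome.chromosomes.items():
        out.extend(AptDuplex(name, int(p)) for p in apt_watson_positions(seq))
    return out


def is_apt_context(genome: Genome, chrom: str, pos: int, strand: str) -> bool:
    """True iff the adenine at (pos, strand) has a strand-local 3' T.

    Watson: the neighbour is seq[pos+1]. Crick: an A on Crick sits over a
    Watson T, and its 3' neighbour on Crick is the base at pos-1, which is T
    on Crick iff the Watson base there is A. Chromosome edges cannot be ApT.
    """
    seq = genome.sequence(chrom)
    if strand == "+":
        if seq[pos] != "A":
            raise ValueError(f"{chrom}:{pos}:+ is {seq[pos]}, not A")
        return pos + 1 < len(seq) and seq[pos + 1] == "T"
    if strand == "-":
        if seq[pos] != "T":
            raise ValueError(f"{chrom}:{pos}:- is {reverse_complement(seq[pos])}, not A")
        return pos - 1 >= 0 and seq[pos - 1] == "A"
    raise ValueError(f"strand must be + or -, got {strand!r}")


def adenine_count(genome: Genome, both_strands: bool = True) -> int:
    """Unambiguous adenines in the genome (N never counts).

    ``both_strands`` counts strand-resolved adenines (Watson A + Crick A,
    i.e. A+T of the Watson sequence), matching strand-resolved call sets.
    """
    total = 0
    for seq in genome.chromosomes.values():
        a = _seq_array(seq)
        total += int((a == ord("A")).sum())
        if both_strands:
            total += int((a == ord("T")).sum())
    return total
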