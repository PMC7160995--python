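"""Core containers for annotated (possibly circular) mitogenomes.

Coordinates are 0-based, half-open throughout the library; GFF3 output is
converted to 1-based inclusive on the way out.  A scaffold may be flagged
circular, in which case intervals are interpreted modulo its length and a
feature may wrap the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "Scaffold",
    "AnnotatedGenome",
    "revcomp",
    "circ_slice",
    "circ_interval_distance",
    "interval_union_length",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (delegates to Biopython)."""
    return str(Seq(seq).reverse_complement())


def circ_slice(seq: str, start: int, length: int) -> str:
    """Slice ``length`` bases starting at ``start`` on a circular sequence."""
    n = len(seq)
    if length > n:
        raise ValueError(f"slice of {length} bp exceeds sequence length {n}")
    start %= n
    end = start + length
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]


def _linear_gap(a0: int, a1: int, b0: int, b1: int) -> int:
    """Gap between two half-open intervals on a line (0 if they touch/overlap)."""
    if a1 <= b0:
        return b0 - a1
    if b1 <= a0:
        return a0 - b1
    return 0


def circ_interval_distance(
    a: tuple[int, int], b: tuple[int, int], length: int, circular: bool = True
) -> int:
    """Minimal edge-to-edge distance between two intervals, circular-aware.

    Intervals are half-open and may wrap (start > end means wrapping).
    Returns 0 when the intervals overlap or touch.
    """

    def unroll(iv: tuple[int, int]) -> list[tuple[int, int]]:
        s, e = iv
        s %= length
        e = e % length if e % length else (length if e else 0)
        if s < e:
            return [(s, e)]
        if s == e:
            return [(s, e)]
        return [(s, length), (0, e)]  # wrapping interval

    best = None
    for s0, e0 in unroll(a):
        for s1, e1 in unroll(b):
            g = _linear_gap(s0, e0, s1, e1)
            if circular:
                # also consider going the other way around the circle
                g = min(g, length - (max(e0, e1) - min(s0, s1)))
                g = max(g, 0)
            if best is None or g < best:
                best = g
    return best if best is not None else 0


def interval_union_length(intervals: Iterable[tuple[int, int]], length: int) -> int:
    """Total number of distinct positions covered by (possibly wrapping) intervals."""
    import numpy as np

    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        s %= length
        span = e - s if e >= s else (e % length) + length - s
        if span >= length:
            return length
        if s + span <= length:
            mask[s : s + span] = True
        else:
            mask[s:] = True
            mask[: s + span - length] = True
    return int(mask.sum())


@dataclass(frozen=True)
class GeneFeature:
    """A gene on a scaffold.  ``type`` is one of protein / rRNA / tRNA."""

    name: str
    type: str
    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Scaffold:
    name: str
    seq: str
    circular: bool = True

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AnnotatedGenome:
    """One or more scaffolds of a mitogenome plus gene annotations."""

    scaffolds: dict[str, Scaffold] = field(default_factory=dict)
    genes: list[GeneFeature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    def sequence(self, scaffold: str | None = None) -> str:
        if scaffold is None:
            if len(self.scaffolds) != 1:
                raise ValueError("scaffold name required for multi-scaffold genome")
            return next(iter(self.scaffolds.values())).seq
        return self.scaffolds[scaffold].seq

    def genes_on(self, scaffold: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.scaffold == scaffold]

    def copy(self) -> "AnnotatedGenome":
        return AnnotatedGenome(
            scaffolds={n: replace(s) for n, s in self.scaffolds.items()},
            genes=list(self.genes),
        )

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(
                Seq(s.seq),
                id=s.name,
                description=f"circular={'true' if s.circular else 'false'}",
            )
            for s in self.scaffolds.values()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "AnnotatedGenome":
        g = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            circular = "circular=true" in rec.description
            g.scaffolds[rec.id] = Scaffold(rec.id, str(rec.seq).upper(), circular)
        return g

    def write_gff3(self, path: str | Path) -> None:
        """Write gene features as a minimal GFF3 (1-based inclusive coordinates)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for s in self.scaffolds.values():
                fh.write(f"##sequence-region {s.name} 1 {len(s)}\n")
            for i, g in enumerate(self.genes):
                attrs = f"ID=gene{i};Name={g.name};gene_type={g.type}"
                fh.write(
                    f"{g.scaffold}\tmitovar\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )

    def read_gff3_genes(self, path: str | Path) -> None:
        """Load gene features written by :meth:`write_gff3` (GFF3 subset)."""
        self.genes = read_gff3(path)


def read_gff3(path: str | Path) -> list[GeneFeature]:
    """Parse the GFF3 subset this package writes (gene rows with Name/gene_type)."""
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            genes.append(
                GeneFeature(
                    name=attrs.get("Name", attrs.get("ID", "?")),
                    type=attrs.get("gene_type", "protein"),
                    scaffold=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                )
            )
    return genes
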