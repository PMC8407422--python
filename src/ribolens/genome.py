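"""Core genomic containers: gene records, annotated genomes, 5'-end tracks.

Coordinates are 0-based half-open throughout the library; conversion to the
1-based closed GFF3 convention happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene on a (possibly circular) bacterial genome.

    ``start``/``end`` are 0-based half-open genome coordinates; ``strand`` is
    '+' or '-'.  ``operon`` groups co-transcribed genes (operon id plus the
    0-based position of the gene within the operon).  ``complex_id`` and
    ``copy_number`` describe membership in a multimeric protein complex.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    operon: str | None = None
    operon_index: int = 0
    complex_id: str | None = None
    copy_number: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def cds_start(self) -> int:
        """Genome coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1

    def overlaps(self, other: "GeneRecord") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class AnnotatedGenome:
    """A genome sequence plus strand-aware gene annotation.

    The chromosome is circular in the organism but genes never wrap the
    origin, so all interval arithmetic is linear.
    """

    sequence: str
    genes: list[GeneRecord]
    name: str = "chr"

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(
                    f"gene {g.gene_id} extends past the end of the sequence"
                )
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids in annotation")

    def __len__(self) -> int:
        return len(self.sequence)

    def gene(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def subsequence(self, start: int, end: int, strand: str = "+") -> str:
        """Strand-aware sequence slice; minus strand returns the reverse
        complement so the result always reads 5'→3' on the requested strand."""
        seg = self.sequence[max(start, 0) : min(end, len(self.sequence))]
        return reverse_complement(seg) if strand == "-" else seg

    def operons(self) -> dict[str, list[GeneRecord]]:
        """Operon id -> member genes ordered by position within the operon."""
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            if g.operon is not None:
                out.setdefault(g.operon, []).append(g)
        for members in out.values():
            members.sort(key=lambda g: g.operon_index)
        return out

    def complexes(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            if g.complex_id is not None:
                out.setdefault(g.complex_id, []).append(g)
        return out


@dataclass
class FivePrimeTrack:
    """Per-strand, per-position counts of read 5' ends for one library.

    ``plus``/``minus`` are dense arrays of length ``genome_length``; float
    dtype so that noise-free expected tracks can be represented exactly.
    """

    plus: np.ndarray
    minus: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=float)
        self.minus = np.asarray(self.minus, dtype=float)
        if self.plus.shape != self.minus.shape or self.plus.ndim != 1:
            raise ValueError("plus/minus arrays must be 1-D and equal length")
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise ValueError("negative counts in track")

    @classmethod
    def zeros(cls, genome_length: int, name: str = "") -> "FivePrimeTrack":
        return cls(np.zeros(genome_length), np.zeros(genome_length), name=name)

    def __len__(self) -> int:
        return len(self.plus)

    def strand(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError("strand must be '+' or '-'")

    @property
    def total(self) -> float:
        return float(self.plus.sum() + self.minus.sum())

    def scaled(self, factor: float, name: str | None = None) -> "FivePrimeTrack":
        return FivePrimeTrack(
            self.plus * factor, self.minus * factor,
            name=self.name if name is None else name,
        )

    def copy(self) -> "FivePrimeTrack":
        return FivePrimeTrack(self.plus.copy(), self.minus.copy(), name=self.name)

    def allclose(self, other: "FivePrimeTrack", **kw) -> bool:
        return np.allclose(self.plus, other.plus, **kw) and np.allclose(
            self.minus, other.minus, **kw
        )
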