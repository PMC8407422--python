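"""Readers and writers for the pipeline's on-disk formats.

Conventions: FASTA for genome sequence, GFF3 for annotation (1-based closed
intervals, strand in column 7, converted to 0-based half-open in memory),
bedGraph (0-based half-open) for per-strand 5'-end tracks — one file pair per
library with ``.plus.bedgraph``/``.minus.bedgraph`` suffixes — and TSV with a
header row for every tabular output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import AnnotatedGenome, FivePrimeTrack, GeneRecord
from .quantify import DataError


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration files."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Return (name, sequence) of the first record."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise DataError(f"no sequences in {path}")
    return recs[0].id, str(recs[0].seq).upper()


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_COLS = 9


def write_annotation(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write gene records as GFF3 CDS features (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {len(genome)}\n")
        for g in sorted(genome.genes, key=lambda g: g.start):
            attrs = [f"ID={g.gene_id}"]
            if g.operon is not None:
                attrs.append(f"operon={g.operon}")
                attrs.append(f"operon_index={g.operon_index}")
            if g.complex_id is not None:
                attrs.append(f"complex_id={g.complex_id}")
                attrs.append(f"copy_number={g.copy_number}")
            fh.write(
                "\t".join(
                    [
                        genome.name, "ribolens", "CDS",
                        str(g.start + 1), str(g.end), ".", g.strand, "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_annotation(path: str | Path) -> list[GeneRecord]:
    """Read CDS features from GFF3 into gene records (0-based half-open).

    Malformed lines raise :class:`DataError` naming the line number.
    """
    import pyranges as pr

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLS:
                raise DataError(
                    f"{path}:{lineno}: expected {_GFF_COLS} tab-separated fields"
                )
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise DataError(f"{path}:{lineno}: end < start")
            if parts[6] not in ("+", "-"):
                raise DataError(f"{path}:{lineno}: strand must be '+' or '-'")

    df = pr.read_gff3(str(path)).df
    df = df[df["Feature"] == "CDS"]

    def attr(row, name, default=None):
        val = getattr(row, name, None)
        return default if val is None or pd.isna(val) else val

    records = []
    for row in df.itertuples():
        records.append(
            GeneRecord(
                gene_id=str(row.ID),
                start=int(row.Start),
                end=int(row.End),
                strand=str(row.Strand),
                operon=attr(row, "operon"),
                operon_index=int(float(attr(row, "operon_index", 0))),
                complex_id=attr(row, "complex_id"),
                copy_number=int(float(attr(row, "copy_number", 1))),
            )
        )
    records.sort(key=lambda g: (g.start, g.gene_id))
    return records


def load_genome(fasta_path: str | Path, gff_path: str | Path) -> AnnotatedGenome:
    name, seq = read_fasta(fasta_path)
    return AnnotatedGenome(seq, read_annotation(gff_path), name=name)


# ---------------------------------------------------------------------------
# bedGraph 5'-end tracks
# ---------------------------------------------------------------------------

def _write_bedgraph(arr: np.ndarray, path: Path, chrom: str) -> None:
    with open(path, "w") as fh:
        # run-length encode consecutive equal nonzero values
        nz = np.flatnonzero(arr)
        if len(nz) == 0:
            return
        run_start = nz[0]
        prev = nz[0]
        val = arr[nz[0]]
        for i in nz[1:]:
            if i == prev + 1 and arr[i] == val:
                prev = i
                continue
            fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{_fmt(val)}\n")
            run_start, prev, val = i, i, arr[i]
        fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{_fmt(val)}\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_track(track: FivePrimeTrack, prefix: str | Path, chrom: str = "chr") -> tuple[Path, Path]:
    """Write a track as ``<prefix>.plus.bedgraph`` / ``<prefix>.minus.bedgraph``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    p = prefix.with_name(prefix.name + ".plus.bedgraph")
    m = prefix.with_name(prefix.name + ".minus.bedgraph")
    _write_bedgraph(track.plus, p, chrom)
    _write_bedgraph(track.minus, m, chrom)
    return p, m


def _read_bedgraph(path: Path, genome_length: int) -> np.ndarray:
    arr = np.zeros(genome_length)
    if not path.exists() or path.stat().st_size == 0:
        return arr
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    prev_end = -1
    last_start = -1
    for row in df.itertuples():
        if row.start < last_start or row.start < 0 or row.end > genome_length:
            raise DataError(f"{path}: intervals must be sorted and in bounds")
        if row.start < prev_end:
            raise DataError(f"{path}: overlapping intervals at {row.start}")
        arr[row.start : row.end] = row.value
        prev_end = row.end
        last_start = row.start
    return arr


def read_track(prefix: str | Path, genome_length: int, name: str = "") -> FivePrimeTrack:
    """Read a ``.plus/.minus.bedgraph`` pair back into a dense track."""
    prefix = Path(prefix)
    p = prefix.with_name(prefix.name + ".plus.bedgraph")
    m = prefix.with_name(prefix.name + ".minus.bedgraph")
    return FivePrimeTrack(
        _read_bedgraph(p, genome_length),
        _read_bedgraph(m, genome_length),
        name=name or prefix.name,
    )


# ---------------------------------------------------------------------------
# TSV + config
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


@dataclass
class PipelineConfig:
    """Configuration of an end-to-end run.

    Either ``simulate`` holds keyword arguments for the synthetic generator,
    or the genome/annotation/track paths point at existing inputs.
    """

    outdir: Path
    seed: int = 0
    simulate: dict | None = None
    genome_fasta: Path | None = None
    annotation_gff: Path | None = None
    tracks_dir: Path | None = None
    parameters: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" not in raw:
            raise ConfigError("config must set 'outdir'")
        cfg = cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate"),
            genome_fasta=Path(raw["genome_fasta"]) if raw.get("genome_fasta") else None,
            annotation_gff=Path(raw["annotation_gff"]) if raw.get("annotation_gff") else None,
            tracks_dir=Path(raw["tracks_dir"]) if raw.get("tracks_dir") else None,
            parameters=dict(raw.get("parameters", {})),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            for attr in ("genome_fasta", "annotation_gff", "tracks_dir"):
                p = getattr(self, attr)
                if p is None:
                    raise ConfigError(
                        f"config needs either a 'simulate' section or '{attr}'"
                    )
                if not Path(p).exists():
                    raise ConfigError(f"{attr} path does not exist: {p}")
        known = {
            "asite_offset", "min_ratio", "min_density", "merge_window",
            "upstream", "downstream", "te_floor", "promoter_length",
            "min_utr_length", "metagene_window",
        }
        unknown = set(self.parameters) - known
        if unknown:
            raise ConfigError(f"unknown parameters: {sorted(unknown)}")
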