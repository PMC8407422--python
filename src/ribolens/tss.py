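"""dRNA-Seq transcription start site calling, merging, categorization,
5'-UTR assignment and promoter extraction.

A TSS is a genome position whose normalized 5'-end density in the
pyrophosphatase-treated (RPP+) library exceeds the untreated (RPP-) library
more than ``min_ratio``-fold (pseudo-density 0.5 added to both), is at least
``min_density`` counts-per-million, and is a local maximum of RPP+ density
within +/-4 nt on its strand.  Candidates from several libraries are merged
by single-linkage clustering of positions within +/-4 nt.  Merged TSSs are
categorized against the annotation with priority P > S > I > A > N:

* P (primary)   — highest-density TSS within <300 nt upstream to 100 nt
                  downstream of a gene start on the same strand,
* S (secondary) — other TSSs in such a window,
* I (internal)  — inside a gene body on the same strand,
* A (antisense) — inside a gene body on the opposite strand,
* N (intergenic, "novel") — none of the above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, FivePrimeTrack, GeneRecord
from .quantify import DataError

logger = logging.getLogger(__name__)

CATEGORIES = ("P", "S", "I", "A", "N")


@dataclass
class TSSRecord:
    position: int
    strand: str
    enrichment_ratio: float
    peak_density: float
    category: str = ""
    associated_gene: str | None = None
    supporting_libraries: tuple[str, ...] = ()


@dataclass
class UTRRecord:
    gene_id: str
    tss: int
    length: int
    sequence: str        # RNA alphabet, 5'->3'
    leaderless: bool


def normalize_tracks(
    rpp_plus: FivePrimeTrack,
    rpp_minus: FivePrimeTrack,
    scale: float = 1e6,
) -> tuple[FivePrimeTrack, FivePrimeTrack]:
    """Scale both libraries to ``scale`` total 5' ends (counts per million)."""
    out = []
    for trk in (rpp_plus, rpp_minus):
        if trk.total <= 0:
            raise DataError(f"cannot normalize empty track {trk.name!r}")
        out.append(trk.scaled(scale / trk.total))
    return out[0], out[1]


def call_tss(
    rpp_plus: FivePrimeTrack,
    rpp_minus: FivePrimeTrack,
    min_ratio: float = 2.0,
    min_density: float = 10.0,
    epsilon: float = 0.5,
    peak_window: int = 4,
    library: str = "",
) -> list[TSSRecord]:
    """Candidate TSSs from one normalized RPP+/RPP- pair.

    Emits positions where (RPP+ + eps)/(RPP- + eps) > min_ratio, RPP+ density
    >= min_density, and the RPP+ density is maximal within +/-peak_window nt.
    """
    if min_ratio <= 1:
        raise DataError("min_ratio must exceed 1")
    records: list[TSSRecord] = []
    n = len(rpp_plus)
    for strand in ("+", "-"):
        p = rpp_plus.strand(strand)
        m = rpp_minus.strand(strand)
        ratio = (p + epsilon) / (m + epsilon)
        cand = np.flatnonzero((ratio > min_ratio) & (p >= min_density))
        for pos in cand:
            lo, hi = max(0, pos - peak_window), min(n, pos + peak_window + 1)
            if p[pos] == p[lo:hi].max():
                records.append(
                    TSSRecord(
                        position=int(pos),
                        strand=strand,
                        enrichment_ratio=float(ratio[pos]),
                        peak_density=float(p[pos]),
                        supporting_libraries=(library,) if library else (),
                    )
                )
    records.sort(key=lambda r: (r.strand, r.position))
    return records


def merge_tss(
    candidates: list[TSSRecord] | list[list[TSSRecord]],
    window: int = 4,
) -> list[TSSRecord]:
    """Merge candidate TSSs within +/-window nt on the same strand.

    Single-linkage clustering along each strand; each cluster collapses to
    one record at the position of highest summed density, with densities
    summed and supporting libraries unioned.  Empty input yields empty
    output; output records on the same strand are pairwise > window nt apart,
    making the operation idempotent.
    """
    flat: list[TSSRecord] = []
    for item in candidates:
        flat.extend(item) if isinstance(item, list) else flat.append(item)
    merged: list[TSSRecord] = []
    for strand in ("+", "-"):
        recs = sorted(
            (r for r in flat if r.strand == strand), key=lambda r: r.position
        )
        cluster: list[TSSRecord] = []
        for r in recs:
            if cluster and r.position - cluster[-1].position > window:
                merged.append(_collapse(cluster))
                cluster = []
            cluster.append(r)
        if cluster:
            merged.append(_collapse(cluster))
    merged.sort(key=lambda r: (r.strand, r.position))
    return merged


def _collapse(cluster: list[TSSRecord]) -> TSSRecord:
    dens: dict[int, float] = {}
    for r in cluster:
        dens[r.position] = dens.get(r.position, 0.0) + r.peak_density
    best = max(sorted(dens), key=lambda p: dens[p])  # ties -> leftmost
    libs = sorted({lib for r in cluster for lib in r.supporting_libraries})
    return TSSRecord(
        position=best,
        strand=cluster[0].strand,
        enrichment_ratio=max(r.enrichment_ratio for r in cluster),
        peak_density=sum(r.peak_density for r in cluster),
        supporting_libraries=tuple(libs),
    )


def _primary_window(gene: GeneRecord, upstream: int, downstream: int) -> tuple[int, int]:
    """Inclusive position range of the primary-TSS window around the start."""
    s = gene.cds_start
    if gene.strand == "+":
        return s - upstream + 1, s + downstream
    return s - downstream, s + upstream - 1


def categorize_tss(
    records: list[TSSRecord],
    genome: AnnotatedGenome,
    upstream: int = 300,
    downstream: int = 100,
) -> list[TSSRecord]:
    """Assign each TSS one category (priority P > S > I > A > N) and a gene.

    Per gene, the highest-density same-strand TSS within <upstream nt before
    and <=downstream nt after the start codon is its primary TSS; equal
    densities break toward the most upstream position.  A TSS primary for
    several genes associates with the gene whose start is nearest.
    """
    roles: dict[int, tuple[str, str, int]] = {}  # record idx -> (cat, gene, dist)
    for gene in genome.genes:
        lo, hi = _primary_window(gene, upstream, downstream)
        in_win = [
            (i, r) for i, r in enumerate(records)
            if r.strand == gene.strand and lo <= r.position <= hi
        ]
        if not in_win:
            continue
        upstream_key = (
            (lambda r: r.position) if gene.strand == "+" else (lambda r: -r.position)
        )
        primary_i, primary = max(
            in_win, key=lambda ir: (ir[1].peak_density, -upstream_key(ir[1]))
        )
        for i, r in in_win:
            cat = "P" if i == primary_i else "S"
            dist = abs(r.position - gene.cds_start)
            prev = roles.get(i)
            if (
                prev is None
                or _better_role(cat, dist, prev[0], prev[2])
            ):
                roles[i] = (cat, gene.gene_id, dist)

    out: list[TSSRecord] = []
    for i, r in enumerate(records):
        if i in roles:
            cat, gid, _ = roles[i]
            out.append(replace(r, category=cat, associated_gene=gid))
            continue
        cat, gid = "N", None
        for gene in genome.genes:
            if gene.start <= r.position < gene.end:
                if gene.strand == r.strand:
                    cat, gid = "I", gene.gene_id
                    break
                cat, gid = "A", gene.gene_id  # keep looking for same-strand hit
        out.append(replace(r, category=cat, associated_gene=gid))
    return out


def _better_role(cat: str, dist: int, prev_cat: str, prev_dist: int) -> bool:
    order = {"P": 0, "S": 1}
    if order[cat] != order[prev_cat]:
        return order[cat] < order[prev_cat]
    return dist < prev_dist


def assign_utr(
    records: list[TSSRecord],
    genome: AnnotatedGenome,
    leaderless_below: int = 5,
) -> list[UTRRecord]:
    """5' UTRs for primary TSSs: strand-aware distance TSS -> start codon.

    TSSs downstream of the start codon (negative distance) are skipped with a
    warning.  The UTR sequence is read off the coding strand and transcribed
    to the RNA alphabet; UTRs shorter than ``leaderless_below`` nt are
    flagged leaderless.
    """
    out: list[UTRRecord] = []
    for r in records:
        if r.category != "P" or r.associated_gene is None:
            continue
        gene = genome.gene(r.associated_gene)
        length = (
            gene.cds_start - r.position if gene.strand == "+"
            else r.position - gene.cds_start
        )
        if length < 0:
            logger.warning(
                "TSS at %d is downstream of the start of %s; skipped",
                r.position, gene.gene_id,
            )
            continue
        if gene.strand == "+":
            seq = genome.subsequence(r.position, gene.cds_start, "+")
        else:
            seq = genome.subsequence(gene.cds_start + 1, r.position + 1, "-")
        out.append(
            UTRRecord(
                gene_id=gene.gene_id,
                tss=r.position,
                length=int(length),
                sequence=seq.upper().replace("T", "U"),
                leaderless=length < leaderless_below,
            )
        )
    return out


MINUS10_CONSENSUS = "TATAAT"
MINUS35_CONSENSUS = "TTGACA"


def consensus_scan(seq: str, motif: str, max_mismatch: int = 1) -> list[tuple[int, int]]:
    """Sliding-window scan: (offset, mismatches) for windows within tolerance."""
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        mm = sum(a != b for a, b in zip(seq[i : i + len(motif)], motif))
        if mm <= max_mismatch:
            hits.append((i, mm))
    return hits


def extract_promoters(
    records: list[TSSRecord],
    genome: AnnotatedGenome,
    length: int = 50,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """50-nt (by default) upstream coding-strand sequences per TSS, with a
    consensus scan for the -10 (TATAAT) and -35 (TTGACA) box motifs.

    Offsets in the hit columns count from the window's 5' end; the window
    ends immediately before the TSS.  Sequences truncated by a contig edge
    are flagged.
    """
    rows = []
    for r in records:
        if r.strand == "+":
            lo, hi = r.position - length, r.position
            seq = genome.subsequence(max(lo, 0), hi, "+")
            truncated = lo < 0
        else:
            lo, hi = r.position + 1, r.position + 1 + length
            seq = genome.subsequence(lo, min(hi, len(genome)), "-")
            truncated = hi > len(genome)
        rows.append(
            {
                "position": r.position,
                "strand": r.strand,
                "category": r.category or "N",
                "sequence": seq,
                "truncated": truncated,
                "minus10_hits": consensus_scan(seq, MINUS10_CONSENSUS, max_mismatch),
                "minus35_hits": consensus_scan(seq, MINUS35_CONSENSUS, max_mismatch),
            }
        )
    return pd.DataFrame(rows)


def tss_to_bed(records: list[TSSRecord], chrom: str = "chr") -> pd.DataFrame:
    """BED6 representation: name=category, score=truncated 100x enrichment."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [r.position for r in records],
            "end": [r.position + 1 for r in records],
            "name": [r.category or "N" for r in records],
            "score": [int(min(r.enrichment_ratio * 100, 1000)) for r in records],
            "strand": [r.strand for r in records],
        }
    )
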