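"""Gene-wise read counting, RPKM, size factors and simple differential calls.

RNA-Seq reads are counted by their 5'-end position within the gene body.
Ribo-Seq (RPF) reads are assigned to their A-site (5' end shifted a fixed
offset toward the 3' end of the coding strand) and counted only when the
A-site falls within the elongation window of the ORF — codons 6 through
L/3 - 5, i.e. excluding the first and last five codons to avoid initiation
and termination effects.

RPKM follows the classic definition
``RPKM = 1e9 * reads_on_gene / (total_mapped_reads * gene_length)``;
``total_mapped_reads`` is the per-sample column sum of the gene-wise count
table.  Size factors are DESeq-style median-of-ratios.  Differential calls
use a two-sided binomial rate-ratio test on summed normalized counts — a
deliberately simple substitute for a negative-binomial Wald test — with
Benjamini-Hochberg adjustment and the significance rule
``p_adj < 0.01 and |log2FC| > 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import AnnotatedGenome, FivePrimeTrack, GeneRecord

logger = logging.getLogger(__name__)

MIN_RPF_CODONS = 11  # below this the trimmed elongation window is empty
TRIM_CODONS = 5


class DataError(ValueError):
    """Raised when input data violate a contract (bad counts, empty tracks...)."""


@dataclass
class CountTable:
    """Gene x sample raw counts with condition labels for one assay."""

    counts: pd.DataFrame              # genes x samples, non-negative
    conditions: dict[str, str]        # sample id -> condition label
    assay: str = "RNA"                # {"RNA", "RPF"}

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise DataError("count table contains negative entries")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise DataError("duplicate row or column labels in count table")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise DataError(f"samples without condition labels: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def condition_samples(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.counts.columns:
            out.setdefault(self.conditions[s], []).append(s)
        return out


def trimmed_window(gene: GeneRecord) -> tuple[int, int]:
    """Genome interval of codons 6..L/3-5 (empty for genes < 11 codons).

    Trimming five codons from each end is symmetric in genome coordinates,
    so the window is the same slice on either strand.
    """
    if gene.n_codons < MIN_RPF_CODONS:
        return gene.start, gene.start
    return gene.start + 3 * TRIM_CODONS, gene.end - 3 * TRIM_CODONS


def count_reads_per_gene(
    track: FivePrimeTrack,
    genome: AnnotatedGenome,
    assay: str = "RNA",
    asite_offset: int = 17,
) -> pd.Series:
    """Count a library's 5'-end reads per gene.

    RNA assay: a read is counted for a gene when its 5' end lies in the gene
    body on the gene's strand.  RPF assay: the 5' end is shifted
    ``asite_offset`` nt toward 3' on the coding strand and counted when the
    resulting A-site lies in the trimmed elongation window.
    """
    if asite_offset < 0:
        raise DataError("asite_offset must be >= 0")
    if assay not in ("RNA", "RPF"):
        raise DataError(f"unknown assay {assay!r}")
    n = len(track)
    out = {}
    for g in genome.genes:
        if g.end > n:
            raise DataError(f"gene {g.gene_id} extends beyond track bounds")
        arr = track.strand(g.strand)
        if assay == "RNA":
            out[g.gene_id] = float(arr[g.start : g.end].sum())
            continue
        if g.n_codons < MIN_RPF_CODONS:
            logger.warning(
                "gene %s has %d codons (<%d): RPF count set to 0",
                g.gene_id, g.n_codons, MIN_RPF_CODONS,
            )
            out[g.gene_id] = 0.0
            continue
        lo, hi = trimmed_window(g)
        # a 5' end at p has its A-site at p+offset (+) or p-offset (-)
        if g.strand == "+":
            lo5, hi5 = lo - asite_offset, hi - asite_offset
        else:
            lo5, hi5 = lo + asite_offset, hi + asite_offset
        out[g.gene_id] = float(arr[max(lo5, 0) : max(min(hi5, n), 0)].sum())
    return pd.Series(out, name=track.name or assay)


def build_count_table(
    tracks: dict[str, FivePrimeTrack],
    genome: AnnotatedGenome,
    conditions: dict[str, str],
    assay: str = "RNA",
    asite_offset: int = 17,
) -> CountTable:
    """Count several libraries into one gene x sample table."""
    cols = {
        sample: count_reads_per_gene(trk, genome, assay=assay, asite_offset=asite_offset)
        for sample, trk in tracks.items()
    }
    return CountTable(pd.DataFrame(cols), conditions=dict(conditions), assay=assay)


def compute_rpkm(
    counts: CountTable | pd.DataFrame,
    gene_lengths: pd.Series,
    total_mapped: pd.Series | None = None,
) -> pd.DataFrame:
    """RPKM = 1e9 * count / (total mapped reads * gene length).

    ``total_mapped`` defaults to the per-sample column sums of the table.
    """
    df = counts.counts if isinstance(counts, CountTable) else counts
    lengths = gene_lengths.reindex(df.index)
    if lengths.isna().any():
        raise DataError("gene_lengths missing for some genes in the count table")
    if (lengths <= 0).any():
        raise DataError("gene lengths must be positive")
    totals = df.sum(axis=0) if total_mapped is None else total_mapped.reindex(df.columns)
    zero = totals[totals <= 0]
    if len(zero):
        raise DataError(f"zero total mapped reads in sample(s): {list(zero.index)}")
    return 1e9 * df.div(totals, axis=1).div(lengths, axis=0)


def size_factors(counts: CountTable | pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples, computed on
    genes with nonzero counts in every sample; the factor for a sample is the
    median of its count/reference ratios over those genes.
    """
    df = counts.counts if isinstance(counts, CountTable) else counts
    arr = df.to_numpy(dtype=float)
    expressed = (arr > 0).all(axis=1)
    if not expressed.any():
        raise DataError("no gene has nonzero counts in all samples")
    sub = arr[expressed]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / ref[:, None], axis=0)
    return pd.Series(factors, index=df.columns, name="size_factor")


def differential_expression(
    counts: CountTable,
    condition_pair: tuple[str, str] | None = None,
    pseudocount: float = 1.0,
    alpha: float = 0.01,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 fold change, p and BH-adjusted p between two conditions.

    Counts are normalized by median-of-ratios size factors; the fold change
    is the ratio of condition means with a pseudocount; the p-value is a
    two-sided binomial rate-ratio test on the summed normalized counts.
    A gene is flagged significant when ``p_adj < alpha`` and
    ``|log2FC| > lfc_threshold``.
    """
    by_cond = counts.condition_samples()
    if condition_pair is None:
        if len(by_cond) != 2:
            raise DataError(
                "condition_pair must be given unless exactly two conditions present"
            )
        condition_pair = tuple(by_cond)  # type: ignore[assignment]
    c1, c2 = condition_pair
    for c in (c1, c2):
        if c not in by_cond or not by_cond[c]:
            raise DataError(f"condition {c!r} has no samples")
    if len(by_cond[c1]) + len(by_cond[c2]) < 2:
        raise DataError("need at least two samples in total")

    sf = size_factors(counts)
    norm = counts.counts.div(sf, axis=1)
    m1 = norm[by_cond[c1]].mean(axis=1)
    m2 = norm[by_cond[c2]].mean(axis=1)
    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    base_mean = norm[by_cond[c1] + by_cond[c2]].mean(axis=1)

    k1 = norm[by_cond[c1]].sum(axis=1).round().astype(np.int64)
    k2 = norm[by_cond[c2]].sum(axis=1).round().astype(np.int64)
    p0 = len(by_cond[c2]) / (len(by_cond[c1]) + len(by_cond[c2]))
    pvals = np.ones(len(norm))
    for i, (a, b) in enumerate(zip(k1.to_numpy(), k2.to_numpy())):
        tot = a + b
        if tot > 0:
            pvals[i] = stats.binomtest(int(b), int(tot), p0, alternative="two-sided").pvalue
    padj = benjamini_hochberg(pvals)
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "p": pvals,
            "p_adj": padj,
            "significant": (padj < alpha) & (np.abs(log2fc) > lfc_threshold),
        },
        index=counts.counts.index,
    )
    out.index.name = "gene"
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]
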