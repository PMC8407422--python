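"""Ribosome-position analysis: A-site assignment, metagene profiles,
5'-UTR occupancy, RNA-structure scoring and Shine-Dalgarno scoring.

Ribosome footprint 5' ends are converted to A-site positions by shifting a
fixed offset (17 nt by default) toward the 3' end of the coding strand.
Metagene profiles average length-normalized A-site densities across genes
aligned at the start codon and report the frame composition of elongating
ribosomes (3-nt periodicity).  5'-UTR vs CDS ribosome occupancy compares
per-nt RPF/RNA density ratios between the two regions.  The structure engine
is a Nussinov base-pair-maximization folder (minimum hairpin loop 3 nt,
AU/GC/GU pairs) whose score, -(number of pairs), serves as a deterministic
proxy for a thermodynamic minimum free energy; an external folder returning
kcal/mol can be plugged in instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .genome import AnnotatedGenome, FivePrimeTrack
from .quantify import DataError, trimmed_window
from .tss import UTRRecord

logger = logging.getLogger(__name__)


def asite_track(track: FivePrimeTrack, offset: int = 17) -> FivePrimeTrack:
    """Shift 5'-end counts to A-site positions.

    Plus-strand 5' ends move ``offset`` nt to larger coordinates, minus-strand
    ends to smaller coordinates (3' direction on each strand).  Counts shifted
    off the contig are dropped and logged.
    """
    if offset < 0:
        raise DataError("offset must be >= 0")
    n = len(track)
    plus = np.zeros(n)
    minus = np.zeros(n)
    if offset == 0:
        plus[:], minus[:] = track.plus, track.minus
    else:
        plus[offset:] = track.plus[: n - offset]
        minus[: n - offset] = track.minus[offset:]
        dropped = track.plus[n - offset :].sum() + track.minus[:offset].sum()
        if dropped:
            logger.warning("%s: %g counts shifted off the contig", track.name, dropped)
    return FivePrimeTrack(plus, minus, name=f"{track.name}.asite")


@dataclass
class MetageneProfile:
    """Mean A-site density around the start codon plus frame composition."""

    offsets: np.ndarray          # nt relative to the first base of the start codon
    density: np.ndarray          # mean of per-gene-normalized densities
    frame_fractions: tuple[float, float, float]
    n_genes: int


def metagene(
    asite: FivePrimeTrack,
    genome: AnnotatedGenome,
    window: tuple[int, int] = (-30, 60),
) -> MetageneProfile:
    """Average per-gene-normalized A-site density aligned at start codons.

    Each gene's window is normalized by its mean ORF density before
    averaging, so highly expressed genes do not dominate.  Frame fractions
    are computed from A-site counts within the 5-codon-trimmed ORFs.
    """
    lo, hi = window
    if not genome.genes:
        raise DataError("empty annotation")
    width = hi - lo + 1
    acc = np.zeros(width)
    nused = 0
    frames = np.zeros(3)
    for g in genome.genes:
        arr = asite.strand(g.strand)
        if g.length <= width:
            continue
        s = g.cds_start
        if g.strand == "+":
            idx = np.arange(s + lo, s + hi + 1)
        else:
            idx = np.arange(s - lo, s - hi - 1, -1)
        if idx.min() < 0 or idx.max() >= len(arr):
            continue
        prof = arr[idx]
        orf_mean = arr[g.start : g.end].mean()
        if orf_mean > 0:
            acc += prof / orf_mean
            nused += 1
        wlo, whi = trimmed_window(g)
        body = arr[wlo:whi]
        if len(body):
            by_frame = body.reshape(-1, 3).sum(axis=0)
            if g.strand == "-":
                # frame 0 is the first base of each codon reading right-to-left
                by_frame = by_frame[::-1]
            frames += by_frame
    if nused == 0:
        raise DataError("no gene long enough for the metagene window")
    total = frames.sum()
    ff = tuple(frames / total) if total > 0 else (np.nan,) * 3
    return MetageneProfile(
        offsets=np.arange(lo, hi + 1),
        density=acc / nused,
        frame_fractions=ff,  # type: ignore[arg-type]
        n_genes=nused,
    )


def utr_occupancy(
    rpf_asite: FivePrimeTrack,
    rna: FivePrimeTrack,
    utrs: list[UTRRecord],
    genome: AnnotatedGenome,
    min_utr_length: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene 5'-UTR and CDS RPF/RNA density ratios and their comparison.

    Densities are counts per nt: the UTR region runs from the TSS to (and
    excluding) the start codon; the CDS RPF density uses the 5-codon-trimmed
    window while the CDS RNA density uses the full ORF.  The summary reports
    per-region median ratios and a two-tailed Wilcoxon signed-rank test of
    the paired per-gene UTR vs CDS ratios.
    """
    rows = []
    for u in utrs:
        if u.length < min_utr_length:
            continue
        g = genome.gene(u.gene_id)
        arr_rpf = rpf_asite.strand(g.strand)
        arr_rna = rna.strand(g.strand)
        if g.strand == "+":
            ulo, uhi = u.tss, g.start
        else:
            ulo, uhi = g.end, u.tss + 1
        utr_rpf = arr_rpf[ulo:uhi].sum() / u.length
        utr_rna = arr_rna[ulo:uhi].sum() / u.length
        wlo, whi = trimmed_window(g)
        cds_rpf = arr_rpf[wlo:whi].sum() / max(whi - wlo, 1)
        cds_rna = arr_rna[g.start : g.end].sum() / g.length
        if utr_rna <= 0 or cds_rna <= 0:
            continue
        rows.append(
            {
                "gene": u.gene_id,
                "utr_length": u.length,
                "utr_rpf_density": utr_rpf,
                "utr_rna_density": utr_rna,
                "cds_rpf_density": cds_rpf,
                "cds_rna_density": cds_rna,
                "utr_ratio": utr_rpf / utr_rna,
                "cds_ratio": cds_rpf / cds_rna,
            }
        )
    if not rows:
        raise DataError("no qualifying 5' UTRs for occupancy analysis")
    df = pd.DataFrame(rows)
    diffs = df["utr_ratio"] - df["cds_ratio"]
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(df["utr_ratio"], df["cds_ratio"]).pvalue)
    rel = df["utr_ratio"] / df["cds_ratio"].where(df["cds_ratio"] > 0)
    summary = {
        "n": len(df),
        "median_utr_ratio": float(df["utr_ratio"].median()),
        "median_cds_ratio": float(df["cds_ratio"].median()),
        "median_relative_occupancy": float(rel.median()),
        "wilcoxon_p": p,
    }
    return df, summary


# ---------------------------------------------------------------------------
# RNA structure
# ---------------------------------------------------------------------------

PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3


@dataclass
class FoldResult:
    sequence: str
    energy: float                 # kcal/mol with an external engine, -(pairs) internally
    pairs: list[tuple[int, int]]  # nested, non-crossing, 0-based

    @property
    def dot_bracket(self) -> str:
        s = ["."] * len(self.sequence)
        for i, j in self.pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)


def _check_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise DataError(f"invalid RNA characters: {sorted(bad)}")
    if not seq:
        raise DataError("empty sequence")
    return seq


def fold_mfe(
    sequence: str,
    engine: str = "internal",
    external_fold: Callable[[str], tuple[float, list[tuple[int, int]]]] | None = None,
) -> FoldResult:
    """Fold an RNA sequence.

    The internal engine maximizes base pairs (Nussinov dynamic program,
    minimum hairpin loop of 3 unpaired nt, AU/GC/GU pairs) and reports
    ``-(number of pairs)`` as a structure-score proxy.  ``engine='external'``
    delegates to ``external_fold`` which must return (energy in kcal/mol,
    pair list).
    """
    seq = _check_rna(sequence)
    if engine == "external":
        if external_fold is None:
            raise DataError("external engine requested but no folder supplied")
        energy, pairs = external_fold(seq)
        _check_nested(pairs, len(seq))
        return FoldResult(seq, float(energy), sorted(pairs))
    if engine != "internal":
        raise DataError(f"unknown engine {engine!r}")
    n = len(seq)
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)  # dp[i][j]: max pairs in seq[i:j]
    for span in range(MIN_LOOP + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # interval [i, j)
            best = dp[i][j - 1]
            last = j - 1
            for k in range(i, last - MIN_LOOP):
                if (seq[k], seq[last]) in PAIRS:
                    cand = dp[i][k] + dp[k + 1][last] + 1
                    if cand > best:
                        best = cand
            dp[i][j] = best
    pairs: list[tuple[int, int]] = []
    _traceback(seq, dp, 0, n, pairs)
    return FoldResult(seq, -float(len(pairs)), sorted(pairs))


def _traceback(seq: str, dp: np.ndarray, i: int, j: int,
               pairs: list[tuple[int, int]]) -> None:
    while j - i > MIN_LOOP + 1:
        if dp[i][j] == dp[i][j - 1]:
            j -= 1
            continue
        last = j - 1
        for k in range(i, last - MIN_LOOP):
            if (seq[k], seq[last]) in PAIRS and dp[i][j] == dp[i][k] + dp[k + 1][last] + 1:
                pairs.append((k, last))
                _traceback(seq, dp, i, k, pairs)
                i, j = k + 1, last
                break
        else:  # pragma: no cover - defensive
            raise RuntimeError("traceback failed")


def _check_nested(pairs: list[tuple[int, int]], n: int) -> None:
    for (i, j) in pairs:
        if not (0 <= i < j < n):
            raise DataError(f"invalid pair {(i, j)}")
        if j - i <= MIN_LOOP:
            raise DataError(f"hairpin loop below {MIN_LOOP} nt in pair {(i, j)}")
    for (i, j) in pairs:
        for (k, l) in pairs:
            if i < k < j < l:
                raise DataError("crossing pairs (pseudoknot) not allowed")


def rnafold_engine(seq: str) -> tuple[float, list[tuple[int, int]]]:
    """External folder backed by the ViennaRNA ``RNAfold`` executable."""
    import re
    import subprocess

    out = subprocess.run(
        ["RNAfold", "--noPS"], input=seq + "\n", capture_output=True, text=True,
        check=True,
    ).stdout.splitlines()
    struct_line = out[-1]
    m = re.match(r"([.()]+)\s+\(\s*(-?\d+\.?\d*)\)", struct_line)
    if not m:
        raise DataError(f"cannot parse RNAfold output: {struct_line!r}")
    db, energy = m.group(1), float(m.group(2))
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    return energy, sorted(pairs)


def te_by_mfe(
    energies: pd.Series,
    te_changes: pd.Series,
    threshold: float | None = None,
) -> dict:
    """Compare TE changes of structured vs unstructured 5' UTRs.

    Genes whose folding energy is below ``threshold`` (default: the cohort
    median, appropriate for the internal pair-count proxy; -30 kcal/mol is a
    natural choice with a thermodynamic folder) form the structured group.
    Distributions are compared with a two-tailed Wilcoxon rank-sum test.
    """
    common = energies.index.intersection(te_changes.index)
    e = energies.loc[common].astype(float)
    t = te_changes.loc[common].astype(float)
    ok = e.notna() & t.notna()
    e, t = e[ok], t[ok]
    if threshold is None:
        threshold = float(e.median())
    structured = t[e < threshold]
    unstructured = t[e >= threshold]
    if len(structured) < 3 or len(unstructured) < 3:
        raise DataError(
            f"each group needs >= 3 genes (got {len(structured)}/{len(unstructured)})"
        )
    res = stats.mannwhitneyu(structured, unstructured, alternative="two-sided")
    return {
        "threshold": float(threshold),
        "n_structured": int(len(structured)),
        "n_unstructured": int(len(unstructured)),
        "median_structured": float(structured.median()),
        "median_unstructured": float(unstructured.median()),
        "median_difference": float(structured.median() - unstructured.median()),
        "p": float(res.pvalue),
    }


# ---------------------------------------------------------------------------
# Shine-Dalgarno scoring
# ---------------------------------------------------------------------------

ANTI_SD = "CCUCCU"  # written 3'->5' when paired against the mRNA


def sd_score(
    sequence: str,
    window: tuple[int, int] = (-20, -5),
    anti_sd: str = ANTI_SD,
) -> tuple[int, bool]:
    """Maximum contiguous complementarity run against the anti-SD sequence.

    ``sequence`` is the region upstream of (and ending at) the start codon,
    5'->3'.  The window is given relative to the first base of the start
    codon (so (-20, -5) scores 15 nt ending 5 nt before the start).  The
    anti-SD is slid along the window at every offset; at each offset the
    longest run of Watson-Crick or GU-wobble paired columns is recorded and
    the maximum over offsets returned.  A perfect AGGAGG gives 6.  The
    second return value flags windows shortened by a too-short sequence.
    """
    seq = sequence.upper().replace("T", "U")
    lo, hi = window
    if lo >= hi:
        raise DataError("window must satisfy lo < hi")
    start = len(seq) + lo
    end = len(seq) + hi
    flagged = start < 0
    w = seq[max(start, 0) : max(end, 0)]
    mate = anti_sd.upper().replace("T", "U")  # 3'->5', aligns antiparallel as-is
    best = 0
    if len(w) == 0:
        return 0, True
    for off in range(-len(mate) + 1, len(w)):
        run = 0
        for k in range(len(mate)):
            i = off + k
            if 0 <= i < len(w) and (w[i], mate[k]) in PAIRS:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best, flagged


def sd_scores(
    utr_sequences: dict[str, str] | pd.Series,
    window: tuple[int, int] = (-20, -5),
    anti_sd: str = ANTI_SD,
) -> pd.DataFrame:
    """SD scores for a set of genes (sequences end at the start codon)."""
    items = (
        utr_sequences.items()
        if isinstance(utr_sequences, (dict, pd.Series))
        else utr_sequences
    )
    rows = []
    for gene, seq in items:
        score, flagged = sd_score(seq, window=window, anti_sd=anti_sd)
        rows.append({"gene": gene, "sd_score": score, "short_window": flagged})
    return pd.DataFrame(rows).set_index("gene")


def position_frequency_matrix(
    sequences: list[str],
    window: tuple[int, int] = (-20, -5),
) -> tuple[pd.DataFrame, pd.Series]:
    """PFM and per-column information content for start-aligned sequences.

    Sequences end at the start codon; columns are positions ``window[0]`` to
    ``window[1]-1`` relative to it.  Information content per column is
    2 - H(column) bits; sequences too short for a column are ignored there.
    """
    lo, hi = window
    width = hi - lo
    counts = np.zeros((4, width))
    alphabet = "ACGU"
    for seq in sequences:
        seq = seq.upper().replace("T", "U")
        for col in range(width):
            pos = len(seq) + lo + col
            if 0 <= pos < len(seq) and seq[pos] in alphabet:
                counts[alphabet.index(seq[pos]), col] += 1
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(totals > 0, counts / np.maximum(totals, 1), 0.25)
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    info = 2.0 + plogp.sum(axis=0)
    cols = list(range(lo, hi))
    pfm = pd.DataFrame(freq, index=list(alphabet), columns=cols)
    return pfm, pd.Series(info, index=cols, name="information_bits")
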