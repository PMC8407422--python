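"""Synthetic genomes and condition-paired sequencing libraries with known truth.

The generator emulates the data structure of a bacterial transcriptome /
translatome study: a single circular chromosome annotated with operons of
protein-coding genes, and per-strand 5'-end count tracks for

* RNA-Seq        — 5' ends uniform over each transcript,
* Ribo-Seq       — footprint 5' ends placed so that the A-site (5' end + a
                   fixed offset, 17 nt by default) falls in frame 0 with a
                   controllable probability, giving 3-nt periodicity,
* dRNA-Seq       — a pyrophosphatase-treated (RPP+) / untreated (RPP-)
                   library pair in which true transcription start sites are
                   enriched in RPP+ by a known fold over RPP-.

Planted per-gene mRNA abundances, translation efficiencies (TE), TE
fold-changes with class labels, TSS positions and 5'-UTR lengths are returned
as a :class:`SyntheticTruth` for recovery tests.  Count noise is per-position
negative binomial (mean mu, variance mu + dispersion*mu^2); dispersion 0
degenerates to Poisson, and ``exact=True`` returns the expected tracks with no
sampling at all.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, FivePrimeTrack, GeneRecord, reverse_complement


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


DEFAULT_CONDITIONS = ("heterotrophic", "autotrophic")

# stream ids for deterministic per-library child seeds
_STREAMS = {"genome": 0, "rna": 1, "ribo": 2, "drna": 3}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults mirror the structure of a two-condition (heterotrophic vs
    autotrophic growth) bacterial profiling experiment: biological duplicates,
    deep 5'-end libraries, a 17-nt 5'-end-to-A-site offset, and a 5'-UTR
    length law with a median of 49 nt.
    """

    genome_length: int = 200_000
    n_genes: int = 200
    n_conditions: int = 2
    replicates_per_condition: int = 2
    library_depth: float = 1_000_000.0
    dispersion: float = 0.1
    frame0_fraction: float = 0.8
    asite_offset: int = 17
    tss_enrichment: float = 8.0
    utr_median_nt: float = 49.0
    seed: int = 0

    # gene geometry
    min_gene_codons: int = 60
    max_gene_codons: int = 400
    max_operon_genes: int = 10
    edge_margin: int = 200

    # planted biology
    log2_abundance_sd: float = 2.0
    log2_te_sd: float = 0.5
    te_high_fraction: float = 0.16
    te_low_fraction: float = 0.08
    te_high_mean: float = 2.8
    te_low_mean: float = -2.8
    te_component_sd: float = 0.3
    te_neutral_sd: float = 0.8
    buffering_coefficient: float = 0.0
    plant_complexes: bool = True
    internal_tss_prob: float = 0.35
    utr_ribo_occupancy: tuple[float, ...] = (0.5, 1.4)
    tss_read_fraction: float = 0.3
    plant_promoter_motifs: bool = True
    plant_sd_for_high_te: bool = True

    def validate(self) -> None:
        if self.genome_length <= 0 or self.n_genes < 0:
            raise ConfigurationError("genome_length must be positive, n_genes >= 0")
        if self.n_conditions < 1:
            raise ConfigurationError("need at least one condition")
        if self.replicates_per_condition < 1:
            raise ConfigurationError("need at least one replicate per condition")
        if self.library_depth <= 0:
            raise ConfigurationError("library_depth must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")
        if not (1.0 / 3.0 <= self.frame0_fraction <= 1.0):
            raise ConfigurationError("frame0_fraction must be in [1/3, 1]")
        if self.asite_offset < 0:
            raise ConfigurationError("asite_offset must be >= 0")
        if self.tss_enrichment <= 1.0:
            raise ConfigurationError("tss_enrichment must exceed 1 (no signal)")
        if self.utr_median_nt < 0:
            raise ConfigurationError("utr_median_nt must be >= 0")
        if self.min_gene_codons < 11:
            raise ConfigurationError(
                "genes must be at least 11 codons for trimmed-window counting"
            )
        if len(self.utr_ribo_occupancy) < self.n_conditions:
            raise ConfigurationError(
                "utr_ribo_occupancy needs one value per condition"
            )

    @property
    def condition_names(self) -> list[str]:
        names = list(DEFAULT_CONDITIONS[: self.n_conditions])
        while len(names) < self.n_conditions:
            names.append(f"cond{len(names) + 1}")
        return names


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic study.

    ``genes`` has one row per gene: coordinates, operon/complex membership,
    per-condition mRNA abundance (``abund_<condition>``, arbitrary units),
    per-condition TE (``te_<condition>``), the planted log2 TE change
    (condition 2 over condition 1), its class label, the true TSS position
    (-1 when the gene has none) and the true 5'-UTR length.
    """

    genes: pd.DataFrame
    complexes: pd.DataFrame
    conditions: list[str]
    planted_mu: float
    planted_sigma: float

    def tss_positions(self) -> pd.DataFrame:
        """True TSSs as (position, strand, gene_id); category is primary."""
        g = self.genes[self.genes["tss"] >= 0]
        return pd.DataFrame(
            {
                "position": g["tss"].astype(int),
                "strand": g["strand"],
                "gene_id": g["gene_id"],
            }
        ).reset_index(drop=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.complexes.to_csv(outdir / "truth_complexes.tsv", sep="\t", index=False)
        meta = pd.DataFrame(
            {
                "key": ["conditions", "planted_mu", "planted_sigma"],
                "value": [
                    ",".join(self.conditions),
                    repr(self.planted_mu),
                    repr(self.planted_sigma),
                ],
            }
        )
        meta.to_csv(outdir / "truth_meta.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir: str | Path) -> "SyntheticTruth":
        outdir = Path(outdir)
        genes = pd.read_csv(
            outdir / "truth_genes.tsv", sep="\t",
            dtype={"operon": str, "complex_id": str},
        )
        if "complex_id" in genes:
            genes["complex_id"] = genes["complex_id"].astype(object).where(
                genes["complex_id"].notna(), None
            )
        complexes = pd.read_csv(
            outdir / "truth_complexes.tsv", sep="\t",
            dtype={"complex_id": str, "gene_id": str},
        )
        meta = pd.read_csv(outdir / "truth_meta.tsv", sep="\t")
        kv = dict(zip(meta["key"], meta["value"]))
        return cls(
            genes=genes,
            complexes=complexes,
            conditions=str(kv["conditions"]).split(","),
            planted_mu=float(kv["planted_mu"]),
            planted_sigma=float(kv["planted_sigma"]),
        )


def _child_rng(config: SimulationConfig, stream: str, *key: int) -> np.random.Generator:
    """Deterministic per-library generator derived from the master seed."""
    entropy = [int(config.seed) & 0x7FFFFFFF, _STREAMS[stream], *key]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# genome + truth generation
# ---------------------------------------------------------------------------

def _draw_operon_sizes(rng: np.random.Generator, n_genes: int, max_size: int) -> list[int]:
    sizes: list[int] = []
    total = 0
    while total < n_genes:
        s = min(int(rng.geometric(0.45)), max_size, n_genes - total)
        sizes.append(s)
        total += s
    return sizes


def _empty_truth(config: SimulationConfig) -> SyntheticTruth:
    cols = [
        "gene_id", "operon", "operon_index", "strand", "start", "end", "length",
        "complex_id", "copy_number", "tss", "utr_length",
        "log2_te_change", "te_class",
    ]
    for c in config.condition_names:
        cols += [f"abund_{c}", f"te_{c}"]
    return SyntheticTruth(
        genes=pd.DataFrame(columns=cols),
        complexes=pd.DataFrame(columns=["complex_id", "gene_id", "copy_number", "order"]),
        conditions=config.condition_names,
        planted_mu=0.0,
        planted_sigma=1.0,
    )


def generate_genome(config: SimulationConfig) -> tuple[AnnotatedGenome, SyntheticTruth]:
    """Lay out non-overlapping operons on both strands and plant the truth.

    Genes never wrap the circular origin.  Every operon's first gene gets a
    primary TSS; downstream operon members get their own TSS with probability
    ``internal_tss_prob``.  5'-UTR lengths are floor(exponential) with the
    configured median, capped at 280 nt so every planted TSS stays within the
    primary-TSS window of its gene.  Raises :class:`ConfigurationError` when
    the requested genes cannot fit in the genome.
    """
    config.validate()
    rng = _child_rng(config, "genome")
    conds = config.condition_names

    if config.n_genes == 0:
        seq = "".join(rng.choice(list("ACGT"), size=config.genome_length))
        return AnnotatedGenome(seq, [], name="synthetic"), _empty_truth(config)

    sizes = _draw_operon_sizes(rng, config.n_genes, config.max_operon_genes)

    genes: list[dict] = []
    cursor = config.edge_margin
    gi = 0
    for oi, size in enumerate(sizes):
        strand = "+" if rng.random() < 0.5 else "-"
        cursor += int(rng.integers(150, 321))  # leading intergenic gap
        members = []
        for k in range(size):
            if k > 0:
                cursor += int(rng.integers(15, 41))
            ncod = int(rng.integers(config.min_gene_codons, config.max_gene_codons + 1))
            start, end = cursor, cursor + 3 * ncod
            cursor = end
            members.append((start, end))
        for k, (start, end) in enumerate(members):
            # on the minus strand transcription runs right-to-left, so the
            # rightmost gene is first in the operon
            order = size - 1 - k if strand == "-" else k
            genes.append(
                dict(
                    gene_id=f"g{gi:04d}",
                    operon=f"op{oi:03d}",
                    operon_index=order,
                    strand=strand,
                    start=start,
                    end=end,
                )
            )
            gi += 1
        if cursor > config.genome_length - config.edge_margin:
            raise ConfigurationError(
                f"cannot fit {config.n_genes} genes in {config.genome_length} nt; "
                "increase genome_length or reduce n_genes"
            )

    df = pd.DataFrame(genes)
    df["length"] = df["end"] - df["start"]
    # operon_index must reflect transcription order
    df = df.sort_values(["operon", "operon_index"]).reset_index(drop=True)

    # --- complexes: multi-gene operons become protein complexes; the first
    # two-gene operon is planted non-equimolar (1:9), others near-equimolar.
    df["complex_id"] = pd.array([None] * len(df), dtype="object")
    df["copy_number"] = 1
    operon_sizes = df.groupby("operon")["gene_id"].count()
    nonequi_done = False
    for operon, size in operon_sizes.items():
        if size < 2 or not config.plant_complexes:
            continue
        idx = df.index[df["operon"] == operon]
        if size == 2 and not nonequi_done:
            df.loc[idx, "complex_id"] = f"cpx_{operon}"
            df.loc[idx, "copy_number"] = [1, 9]
            nonequi_done = True
        elif rng.random() < 0.5:
            df.loc[idx, "complex_id"] = f"cpx_{operon}"
            df.loc[idx, "copy_number"] = rng.choice([1, 1, 1, 2, 3], size=size)

    # --- planted abundances: shared within an operon (co-transcription)
    n_operons = len(operon_sizes)
    op_log2_abund = rng.normal(3.0, config.log2_abundance_sd, size=n_operons)
    op_log2_mrna_change = rng.normal(0.0, 1.0, size=n_operons)
    op_idx = {op: i for i, op in enumerate(operon_sizes.index)}
    base_abund = 2.0 ** np.array([op_log2_abund[op_idx[o]] for o in df["operon"]])
    mrna_change = np.array([op_log2_mrna_change[op_idx[o]] for o in df["operon"]])

    # --- planted TE: per-gene baseline plus a high/neutral/low change mixture
    n = len(df)
    base_log2_te = rng.normal(0.0, config.log2_te_sd, size=n)
    u = rng.random(n)
    comp = np.where(
        u < config.te_high_fraction, 1,
        np.where(u < config.te_high_fraction + config.te_low_fraction, -1, 0),
    )
    te_change = np.where(
        comp == 1,
        rng.normal(config.te_high_mean, config.te_component_sd, size=n),
        np.where(
            comp == -1,
            rng.normal(config.te_low_mean, config.te_component_sd, size=n),
            rng.normal(0.0, config.te_neutral_sd, size=n),
        ),
    )
    te_change = te_change + config.buffering_coefficient * mrna_change

    planted_mu = float(np.mean(te_change)) if n else 0.0
    planted_sigma = float(np.std(te_change, ddof=1)) if n > 1 else 1.0
    te_class = np.where(
        te_change > planted_mu + planted_sigma, "high",
        np.where(te_change < planted_mu - planted_sigma, "low", "neutral"),
    )

    for ci, cond in enumerate(conds):
        if ci == 0:
            abund = base_abund
            log2_te = base_log2_te
        elif ci == 1:
            abund = base_abund * 2.0 ** mrna_change
            log2_te = base_log2_te + te_change
        else:
            abund = base_abund * 2.0 ** rng.normal(0.0, 1.0, size=n)
            log2_te = base_log2_te
        # RPF level proportional to complex copy number (stoichiometric
        # translation): fold the copy number into TE, not mRNA.
        df[f"abund_{cond}"] = abund
        df[f"te_{cond}"] = 2.0 ** log2_te * df["copy_number"].to_numpy()

    df["log2_te_change"] = te_change if config.n_conditions >= 2 else 0.0
    df["te_class"] = te_class if config.n_conditions >= 2 else "neutral"

    # --- TSSs and 5' UTRs
    scale = config.utr_median_nt / np.log(2.0) if config.utr_median_nt > 0 else 0.0
    has_tss = (df["operon_index"] == 0) | (rng.random(n) < config.internal_tss_prob)
    utr_len = np.where(
        has_tss,
        np.minimum(np.floor(rng.exponential(scale, size=n) if scale else np.zeros(n)), 280),
        -1,
    ).astype(int)
    tss = np.full(n, -1, dtype=int)
    plus = df["strand"].to_numpy() == "+"
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    tss[has_tss & plus] = starts[has_tss & plus] - utr_len[has_tss & plus]
    tss[has_tss & ~plus] = ends[has_tss & ~plus] - 1 + utr_len[has_tss & ~plus]
    bad = has_tss & ((tss < 50) | (tss > config.genome_length - 51))
    tss[bad] = -1
    utr_len[bad] = -1
    df["tss"] = tss
    df["utr_length"] = np.where(tss >= 0, utr_len, -1)

    # --- sequence with start/stop codons and planted motifs
    seq = rng.choice(list("ACGT"), size=config.genome_length)
    if config.plant_sd_for_high_te:
        for row in df.itertuples():
            if row.te_class != "high":
                continue
            _plant(seq, "AGGAGG", row.start - 12, row.end + 6, row.strand)
    if config.plant_promoter_motifs:
        for row in df.itertuples():
            if row.tss < 0:
                continue
            if row.strand == "+":
                _plant(seq, "TATAAT", row.tss - 12, None, "+")
                _plant(seq, "TTGACA", row.tss - 37, None, "+")
            else:
                _plant(seq, "TATAAT", None, row.tss + 7, "-")
                _plant(seq, "TTGACA", None, row.tss + 32, "-")
    # codons written last so planted motifs can never clobber gene bounds
    for row in df.itertuples():
        if row.strand == "+":
            seq[row.start : row.start + 3] = list("ATG")
            seq[row.end - 3 : row.end] = list("TAA")
        else:
            seq[row.end - 3 : row.end] = list(reverse_complement("ATG"))
            seq[row.start : row.start + 3] = list(reverse_complement("TAA"))

    records = [
        GeneRecord(
            gene_id=row.gene_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            operon=row.operon,
            operon_index=int(row.operon_index),
            complex_id=None if pd.isna(row.complex_id) else row.complex_id,
            copy_number=int(row.copy_number),
        )
        for row in df.itertuples()
    ]
    genome = AnnotatedGenome("".join(seq), records, name="synthetic")

    cx = df[df["complex_id"].notna()][
        ["complex_id", "gene_id", "copy_number", "operon_index"]
    ].rename(columns={"operon_index": "order"}).reset_index(drop=True)

    truth = SyntheticTruth(
        genes=df,
        complexes=cx,
        conditions=conds,
        planted_mu=planted_mu,
        planted_sigma=planted_sigma,
    )
    return genome, truth


def _plant(seq: np.ndarray, motif: str, plus_pos: int | None,
           minus_pos: int | None, strand: str) -> None:
    """Write a motif (read 5'->3' on the transcript strand) into the genome.

    ``plus_pos``/``minus_pos`` is the left genome coordinate of the slice;
    on the minus strand the reverse complement is written.
    """
    left = plus_pos if strand == "+" else minus_pos
    if left is None or left < 0 or left + len(motif) > len(seq):
        return
    text = motif if strand == "+" else reverse_complement(motif)
    seq[left : left + len(motif)] = list(text)


# ---------------------------------------------------------------------------
# library simulators
# ---------------------------------------------------------------------------

def _sample_counts(mu: np.ndarray, dispersion: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Negative binomial counts with mean mu, variance mu + dispersion*mu^2."""
    out = np.zeros_like(mu)
    nz = mu > 0
    if not nz.any():
        return out
    if dispersion == 0:
        out[nz] = rng.poisson(mu[nz])
    else:
        r = 1.0 / dispersion
        p = r / (r + mu[nz])
        out[nz] = rng.negative_binomial(r, p)
    return out


def _finalize(mu_plus: np.ndarray, mu_minus: np.ndarray, depth: float,
              dispersion: float, rng: np.random.Generator, exact: bool,
              name: str) -> FivePrimeTrack:
    total = mu_plus.sum() + mu_minus.sum()
    if total <= 0:
        raise ConfigurationError(f"library {name}: nothing to simulate")
    f = depth / total
    mu_plus, mu_minus = mu_plus * f, mu_minus * f
    if exact:
        return FivePrimeTrack(mu_plus, mu_minus, name=name)
    return FivePrimeTrack(
        _sample_counts(mu_plus, dispersion, rng),
        _sample_counts(mu_minus, dispersion, rng),
        name=name,
    )


def _transcript_bounds(row) -> tuple[int, int]:
    """Transcript interval including the 5' UTR when the gene has a TSS."""
    if row.strand == "+":
        left = row.tss if row.tss >= 0 else row.start
        return int(left), int(row.end)
    right = row.tss + 1 if row.tss >= 0 else row.end
    return int(row.start), int(right)


def simulate_rnaseq(truth: SyntheticTruth, config: SimulationConfig,
                    exact: bool = False) -> dict[tuple[int, int], FivePrimeTrack]:
    """RNA-Seq 5'-end tracks, one per (condition, replicate).

    Expected 5'-end density is uniform over each transcript and proportional
    to the planted mRNA abundance, so the expected count over a gene body is
    proportional to abundance x length.
    """
    config.validate()
    if config.library_depth <= 0:
        raise ConfigurationError("library_depth must be positive")
    L = config.genome_length
    out: dict[tuple[int, int], FivePrimeTrack] = {}
    for ci, cond in enumerate(config.condition_names):
        mu_plus = np.zeros(L)
        mu_minus = np.zeros(L)
        for row in truth.genes.itertuples():
            a = getattr(row, f"abund_{cond}")
            if a <= 0:
                continue
            lo, hi = _transcript_bounds(row)
            (mu_plus if row.strand == "+" else mu_minus)[lo:hi] += a
        for rep in range(config.replicates_per_condition):
            rng = _child_rng(config, "rna", ci, rep)
            out[(ci, rep)] = _finalize(
                mu_plus.copy(), mu_minus.copy(), config.library_depth,
                config.dispersion, rng, exact, name=f"rna_{cond}_rep{rep + 1}",
            )
    return out


def _ribo_expectation(truth: SyntheticTruth, config: SimulationConfig,
                      cond: str, ci: int) -> tuple[np.ndarray, np.ndarray]:
    L = config.genome_length
    mu_plus = np.zeros(L)
    mu_minus = np.zeros(L)
    f0 = config.frame0_fraction
    frame_w = np.array([f0, (1 - f0) / 2, (1 - f0) / 2])
    off = config.asite_offset
    occ = config.utr_ribo_occupancy[ci]
    for row in truth.genes.itertuples():
        a = getattr(row, f"abund_{cond}")
        te = getattr(row, f"te_{cond}")
        w = a * te * row.length
        if w <= 0:
            continue
        ncod = row.length // 3
        codons = np.arange(5, ncod - 5)  # trimmed elongation window
        per_codon = w / len(codons)
        if row.strand == "+":
            asite = row.start + 3 * codons
            for fr in range(3):
                pos5 = asite + fr - off
                np.add.at(mu_plus, pos5, per_codon * frame_w[fr])
        else:
            asite = row.end - 1 - 3 * codons
            for fr in range(3):
                pos5 = asite - fr + off
                np.add.at(mu_minus, pos5, per_codon * frame_w[fr])
        # 5'-UTR footprints at a condition-dependent fraction of CDS density
        if row.tss >= 0 and row.utr_length > 0:
            d = (w / row.length) * occ
            if row.strand == "+":
                asites = np.arange(row.tss, row.start)
                pos5 = asites - off
                ok = pos5 >= 0
                np.add.at(mu_plus, pos5[ok], d)
            else:
                asites = np.arange(row.end, row.tss + 1)
                pos5 = asites + off
                ok = pos5 < L
                np.add.at(mu_minus, pos5[ok], d)
    return mu_plus, mu_minus


def simulate_riboseq(truth: SyntheticTruth, config: SimulationConfig,
                     exact: bool = False) -> dict[tuple[int, int], FivePrimeTrack]:
    """Ribo-Seq 5'-end tracks, one per (condition, replicate).

    Expected footprint count over a gene is proportional to
    abundance x TE x length; A-sites are uniform over the 5-codon-trimmed
    elongation window, in frame 0 with probability ``frame0_fraction`` (the
    remainder split equally over frames 1 and 2), and the recorded 5' end is
    the A-site shifted ``asite_offset`` nt toward the transcript 5' end.
    """
    config.validate()
    out: dict[tuple[int, int], FivePrimeTrack] = {}
    for ci, cond in enumerate(config.condition_names):
        mu_plus, mu_minus = _ribo_expectation(truth, config, cond, ci)
        for rep in range(config.replicates_per_condition):
            rng = _child_rng(config, "ribo", ci, rep)
            out[(ci, rep)] = _finalize(
                mu_plus.copy(), mu_minus.copy(), config.library_depth,
                config.dispersion, rng, exact, name=f"ribo_{cond}_rep{rep + 1}",
            )
    return out


def simulate_drnaseq(truth: SyntheticTruth, config: SimulationConfig,
                     exact: bool = False
                     ) -> dict[int, tuple[FivePrimeTrack, FivePrimeTrack]]:
    """dRNA-Seq RPP+/RPP- track pairs, one pair per condition.

    A ``tss_read_fraction`` share of the RPP+ library concentrates on the true
    TSS positions (weights proportional to transcript abundance); the rest is
    uniform background over both strands.  At a true TSS the expected RPP-
    density is exactly RPP+ / ``tss_enrichment``; elsewhere the two libraries
    have equal expected background.  ``library_depth`` refers to the RPP+
    library; the RPP- library is correspondingly shallower.
    """
    config.validate()
    L = config.genome_length
    out: dict[int, tuple[FivePrimeTrack, FivePrimeTrack]] = {}
    for ci, cond in enumerate(config.condition_names):
        bg = np.full(L, 1.0)
        peak_plus = np.zeros(L)
        peak_minus = np.zeros(L)
        tss_rows = truth.genes[truth.genes["tss"] >= 0]
        weights = tss_rows[f"abund_{cond}"].to_numpy(dtype=float)
        if len(tss_rows) and weights.sum() > 0:
            # allocate peak mass so peaks carry tss_read_fraction of RPP+
            bg_mass = 2 * L
            peak_mass = config.tss_read_fraction / (1 - config.tss_read_fraction) * bg_mass
            vals = peak_mass * weights / weights.sum()
            for (pos, strand), v in zip(
                zip(tss_rows["tss"].astype(int), tss_rows["strand"]), vals
            ):
                (peak_plus if strand == "+" else peak_minus)[pos] += v
        plus_p = bg + peak_plus
        minus_p = bg + peak_minus
        plus_m = bg.copy()
        minus_m = bg.copy()
        at_p = peak_plus > 0
        at_m = peak_minus > 0
        plus_m[at_p] = plus_p[at_p] / config.tss_enrichment
        minus_m[at_m] = minus_p[at_m] / config.tss_enrichment

        total_p = plus_p.sum() + minus_p.sum()
        f = config.library_depth / total_p
        rng = _child_rng(config, "drna", ci)
        if exact:
            pair = (
                FivePrimeTrack(plus_p * f, minus_p * f, name=f"drna_{cond}_rpp+"),
                FivePrimeTrack(plus_m * f, minus_m * f, name=f"drna_{cond}_rpp-"),
            )
        else:
            pair = (
                FivePrimeTrack(
                    _sample_counts(plus_p * f, config.dispersion, rng),
                    _sample_counts(minus_p * f, config.dispersion, rng),
                    name=f"drna_{cond}_rpp+",
                ),
                FivePrimeTrack(
                    _sample_counts(plus_m * f, config.dispersion, rng),
                    _sample_counts(minus_m * f, config.dispersion, rng),
                    name=f"drna_{cond}_rpp-",
                ),
            )
        out[ci] = pair
    return out
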