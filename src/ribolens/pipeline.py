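"""End-to-end orchestration: simulate (optional) -> quantify -> TE -> TSS ->
UTR -> stoichiometry, with a reproducibility manifest.

Every stage writes plain-text TSV/FASTA/GFF3/bedGraph outputs into the
configured output directory; the manifest records the package version, the
effective parameters, the seed, per-stage row counts and a SHA-256 digest of
every file, so that identical config + seed implies identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome import AnnotatedGenome, FivePrimeTrack
from .io import ConfigError, PipelineConfig, load_genome, read_track, write_annotation, write_fasta, write_track, write_tsv
from .quantify import CountTable, DataError, build_count_table, compute_rpkm, differential_expression, size_factors
from .stoichiometry import complexes_from_table, first_second_gene_correlation, stoichiometry_correlation, subunit_cv
from .synthetic import SimulationConfig, SyntheticTruth, generate_genome, simulate_drnaseq, simulate_riboseq, simulate_rnaseq
from .te import buffering_correlation, classify_te_changes, compute_te, condition_means
from .tss import assign_utr, call_tss, categorize_tss, extract_promoters, merge_tss, normalize_tracks, tss_to_bed
from .utr import asite_track, fold_mfe, metagene, sd_scores, te_by_mfe, utr_occupancy

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = {
        "asite_offset": 17,
        "min_ratio": 2.0,
        "min_density": 10.0,
        "merge_window": 4,
        "upstream": 300,
        "downstream": 100,
        "te_floor": 1.0,
        "promoter_length": 50,
        "min_utr_length": 10,
    }
    params.update(config.parameters)
    logger.info("effective parameters: %s", params)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": params,
        "stages": {},
        "files": {},
    }

    # --- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
            genome, truth = generate_genome(sim)
            rna = simulate_rnaseq(truth, sim)
            ribo = simulate_riboseq(truth, sim)
            drna = simulate_drnaseq(truth, sim)
            conds = sim.condition_names
            write_fasta(genome, out / "genome.fasta")
            write_annotation(genome, out / "annotation.gff3")
            truth.write(out / "truth")
            tracks_dir = out / "tracks"
            rna_tracks, ribo_tracks = {}, {}
            for (ci, rep), trk in rna.items():
                name = f"rna_{conds[ci]}_rep{rep + 1}"
                write_track(trk, tracks_dir / name, chrom=genome.name)
                rna_tracks[name] = trk
            for (ci, rep), trk in ribo.items():
                name = f"ribo_{conds[ci]}_rep{rep + 1}"
                write_track(trk, tracks_dir / name, chrom=genome.name)
                ribo_tracks[name] = trk
            drna_pairs = {}
            for ci, (tp, tm) in drna.items():
                write_track(tp, tracks_dir / f"drna_{conds[ci]}_rpp_plus", chrom=genome.name)
                write_track(tm, tracks_dir / f"drna_{conds[ci]}_rpp_minus", chrom=genome.name)
                drna_pairs[conds[ci]] = (tp, tm)
        else:
            genome = load_genome(config.genome_fasta, config.annotation_gff)
            truth = None
            conds, rna_tracks, ribo_tracks, drna_pairs = _discover_tracks(
                Path(config.tracks_dir), len(genome)
            )
        conditions = {}
        for name in list(rna_tracks) + list(ribo_tracks):
            conditions[name] = name.split("_")[1]
        manifest["stages"][stage] = {
            "n_genes": len(genome.genes),
            "genome_length": len(genome),
            "conditions": conds,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: quantification --------------------------------------------
    stage = "quantification"
    try:
        lengths = pd.Series({g.gene_id: g.length for g in genome.genes})
        rna_ct = build_count_table(rna_tracks, genome, conditions, assay="RNA")
        rpf_ct = build_count_table(
            ribo_tracks, genome, conditions, assay="RPF",
            asite_offset=params["asite_offset"],
        )
        rpkm_rna = compute_rpkm(rna_ct, lengths)
        rpkm_rpf = compute_rpkm(rpf_ct, lengths)
        write_tsv(rna_ct.counts, out / "counts_rna.tsv")
        write_tsv(rpf_ct.counts, out / "counts_rpf.tsv")
        write_tsv(rpkm_rna, out / "rpkm_rna.tsv")
        write_tsv(rpkm_rpf, out / "rpkm_rpf.tsv")
        de_rna = de_rpf = None
        if len(set(conditions.values())) == 2 and len(rna_ct.samples) >= 2:
            de_rna = differential_expression(rna_ct, tuple(conds[:2]))
            de_rpf = differential_expression(rpf_ct, tuple(conds[:2]))
            write_tsv(de_rna, out / "diffexp_rna.tsv")
            write_tsv(de_rpf, out / "diffexp_rpf.tsv")
        manifest["stages"][stage] = {
            "n_genes": len(lengths),
            "n_samples_rna": len(rna_ct.samples),
            "n_samples_rpf": len(rpf_ct.samples),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: translation efficiency -------------------------------------
    stage = "te"
    te_labeled = None
    try:
        if len(conds) >= 2:
            te_table = compute_te(
                condition_means(rpkm_rpf, conditions),
                condition_means(rpkm_rna, conditions),
                floor=params["te_floor"],
            )
            fit, te_labeled = classify_te_changes(te_table)
            write_tsv(te_labeled, out / "te_table.tsv")
            buf = {}
            if de_rna is not None:
                mask = te_labeled["log2_te_change"].notna()
                try:
                    r, p = buffering_correlation(
                        de_rna.loc[mask.index[mask], "log2FC"],
                        te_labeled.loc[mask, "log2_te_change"],
                    )
                    buf = {"buffering_r": r, "buffering_p": p}
                except DataError:
                    buf = {}
            manifest["stages"][stage] = {
                "mu": fit.mu,
                "sigma": fit.sigma,
                "counts": fit.counts,
                **buf,
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: TSS --------------------------------------------------------
    stage = "tss"
    utrs = []
    merged = []
    try:
        per_library = []
        for cond, (tp, tm) in drna_pairs.items():
            np_plus, np_minus = normalize_tracks(tp, tm)
            per_library.append(
                call_tss(
                    np_plus, np_minus,
                    min_ratio=params["min_ratio"],
                    min_density=params["min_density"],
                    library=cond,
                )
            )
        merged = merge_tss(per_library, window=params["merge_window"])
        merged = categorize_tss(
            merged, genome,
            upstream=params["upstream"], downstream=params["downstream"],
        )
        write_tsv(tss_to_bed(merged, chrom=genome.name), out / "tss.bed", index=False)
        utrs = assign_utr(merged, genome)
        utr_df = pd.DataFrame(
            [
                {
                    "gene": u.gene_id, "tss": u.tss, "length": u.length,
                    "leaderless": u.leaderless, "sequence": u.sequence,
                }
                for u in utrs
            ]
        )
        write_tsv(utr_df, out / "utrs.tsv", index=False)
        promoters = extract_promoters(merged, genome, length=params["promoter_length"])
        write_tsv(promoters, out / "promoters.tsv", index=False)
        cats = pd.Series([r.category for r in merged])
        manifest["stages"][stage] = {
            "n_tss": len(merged),
            "categories": cats.value_counts().to_dict(),
            "n_utrs": len(utrs),
            "median_utr_length": float(utr_df["length"].median()) if len(utr_df) else None,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: UTR analysis ------------------------------------------------
    stage = "utr"
    try:
        info: dict = {}
        first_cond = conds[0]
        ribo_by_cond: dict[str, list[FivePrimeTrack]] = {}
        rna_by_cond: dict[str, list[FivePrimeTrack]] = {}
        for name, trk in ribo_tracks.items():
            ribo_by_cond.setdefault(conditions[name], []).append(trk)
        for name, trk in rna_tracks.items():
            rna_by_cond.setdefault(conditions[name], []).append(trk)
        for cond in conds:
            pooled_ribo = _pool(ribo_by_cond[cond])
            pooled_rna = _pool(rna_by_cond[cond])
            shifted = asite_track(pooled_ribo, offset=params["asite_offset"])
            prof = metagene(shifted, genome)
            info[f"frame0_{cond}"] = prof.frame_fractions[0]
            if utrs:
                try:
                    occ_df, occ = utr_occupancy(
                        shifted, pooled_rna, utrs, genome,
                        min_utr_length=params["min_utr_length"],
                    )
                    write_tsv(occ_df, out / f"utr_occupancy_{cond}.tsv", index=False)
                    info[f"occupancy_{cond}"] = occ
                except DataError as exc:
                    logger.warning("occupancy for %s skipped: %s", cond, exc)
        if utrs and te_labeled is not None:
            folds = {
                u.gene_id: fold_mfe(u.sequence).energy
                for u in utrs
                if params["min_utr_length"] <= u.length <= 200
            }
            fold_s = pd.Series(folds, name="energy")
            write_tsv(fold_s.to_frame(), out / "utr_folds.tsv")
            try:
                info["te_by_structure"] = te_by_mfe(
                    fold_s, te_labeled["log2_te_change"]
                )
            except DataError as exc:
                logger.warning("structure comparison skipped: %s", exc)
            sd_in = {
                u.gene_id: u.sequence for u in utrs if u.length >= params["min_utr_length"]
            }
            if sd_in:
                sd_df = sd_scores(sd_in)
                write_tsv(sd_df, out / "sd_scores.tsv")
                info["mean_sd_score"] = float(sd_df["sd_score"].mean())
        manifest["stages"][stage] = info
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: stoichiometry ----------------------------------------------
    stage = "stoichiometry"
    try:
        info = {}
        rpkm_rpf_mean = condition_means(rpkm_rpf, conditions)[first_cond]
        cx_table = pd.DataFrame(
            [
                {
                    "complex_id": g.complex_id,
                    "gene_id": g.gene_id,
                    "copy_number": g.copy_number,
                    "order": g.operon_index,
                }
                for g in genome.genes
                if g.complex_id is not None
            ]
        )
        if len(cx_table):
            defs = complexes_from_table(cx_table)
            cx_df, pooled = stoichiometry_correlation(defs, rpkm_rpf_mean)
            cvs = {
                d.complex_id: subunit_cv(rpkm_rpf_mean.loc[d.genes])
                for d in defs
            }
            cx_df["cv_percent"] = cx_df["complex_id"].map(cvs)
            write_tsv(cx_df, out / "stoichiometry.tsv", index=False)
            info["n_complexes"] = len(defs)
            info.update(pooled)
        try:
            r, p, scatter = first_second_gene_correlation(genome, rpkm_rpf_mean)
            write_tsv(scatter, out / "operon_first_second.tsv", index=False)
            info["first_second_r"] = r
            info["first_second_p"] = p
        except DataError as exc:
            logger.warning("operon correlation skipped: %s", exc)
        manifest["stages"][stage] = info
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- manifest -----------------------------------------------------------
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _pool(tracks: list[FivePrimeTrack]) -> FivePrimeTrack:
    plus = sum(t.plus for t in tracks)
    minus = sum(t.minus for t in tracks)
    return FivePrimeTrack(plus, minus, name=tracks[0].name + ".pooled")


def _discover_tracks(tracks_dir: Path, genome_length: int):
    """Load rna_/ribo_/drna_ track pairs following the naming convention."""
    prefixes = sorted(
        {p.name[: -len(".plus.bedgraph")] for p in tracks_dir.glob("*.plus.bedgraph")}
    )
    rna_tracks: dict[str, FivePrimeTrack] = {}
    ribo_tracks: dict[str, FivePrimeTrack] = {}
    drna_raw: dict[str, dict[str, FivePrimeTrack]] = {}
    conds: list[str] = []
    for prefix in prefixes:
        trk = read_track(tracks_dir / prefix, genome_length, name=prefix)
        parts = prefix.split("_")
        kind, cond = parts[0], parts[1]
        if cond not in conds:
            conds.append(cond)
        if kind == "rna":
            rna_tracks[prefix] = trk
        elif kind == "ribo":
            ribo_tracks[prefix] = trk
        elif kind == "drna":
            drna_raw.setdefault(cond, {})["_".join(parts[2:])] = trk
    drna_pairs = {
        cond: (d["rpp_plus"], d["rpp_minus"])
        for cond, d in drna_raw.items()
        if "rpp_plus" in d and "rpp_minus" in d
    }
    if not rna_tracks or not ribo_tracks:
        raise ConfigError(f"no usable tracks found under {tracks_dir}")
    return conds, rna_tracks, ribo_tracks, drna_pairs
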