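"""Operon- and complex-level translation-balance diagnostics.

Subunits of a multimeric protein complex are expected to be synthesized in
proportion to their copy numbers in the assembled complex.  This module
quantifies that expectation: the coefficient of variation of subunit
translation levels (CV = sample SD / mean x 100), per-complex correlation
between copy number and translation level (RPKM of ribosome footprints),
and the correlation between the translation levels of the first and second
genes of each operon (log10 scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import AnnotatedGenome
from .quantify import DataError


@dataclass
class ComplexDefinition:
    """A multimeric complex: ordered subunit genes and their copy numbers."""

    complex_id: str
    genes: list[str]
    copy_numbers: list[int]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise DataError(f"complex {self.complex_id}: need >= 2 subunits")
        if len(self.copy_numbers) != len(self.genes):
            raise DataError(f"complex {self.complex_id}: copy number per subunit")
        if any(c < 1 for c in self.copy_numbers):
            raise DataError(f"complex {self.complex_id}: copy numbers must be >= 1")


def complexes_from_table(table: pd.DataFrame) -> list[ComplexDefinition]:
    """Build definitions from a (complex, gene, copy_number[, order]) table."""
    defs = []
    cols = {c.lower(): c for c in table.columns}
    cid = cols.get("complex_id", cols.get("complex"))
    sort_by = [cid] + ([cols["order"]] if "order" in cols else [])
    for name, grp in table.sort_values(sort_by).groupby(cid, sort=True):
        defs.append(
            ComplexDefinition(
                complex_id=str(name),
                genes=list(grp[cols["gene_id"] if "gene_id" in cols else cols["gene"]]),
                copy_numbers=[int(c) for c in grp[cols["copy_number"]]],
            )
        )
    return defs


def subunit_cv(values: np.ndarray | pd.Series | list[float]) -> float:
    """Coefficient of variation, percent: sample SD / mean x 100."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise DataError("CV needs at least two values")
    mean = x.mean()
    if mean == 0:
        raise DataError("CV undefined for zero mean")
    return float(np.std(x, ddof=1) / mean * 100.0)


def stoichiometry_correlation(
    complexes: list[ComplexDefinition],
    rpkm: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Copy-number vs translation-level agreement per complex and pooled.

    Per complex: Pearson r between subunit copy numbers and RPKM values, a
    least-squares proportionality slope through the origin, and the ratio of
    per-copy-number mean levels (max over min copy number) as a direct
    estimate of the planted stoichiometric fold.  Complexes with constant
    copy numbers are flagged (r undefined).
    """
    rows = []
    all_cn: list[float] = []
    all_lv: list[float] = []
    for cx in complexes:
        missing = [g for g in cx.genes if g not in rpkm.index]
        if missing:
            raise DataError(f"complex {cx.complex_id}: genes missing from table: {missing}")
        levels = rpkm.loc[cx.genes].to_numpy(dtype=float)
        cn = np.asarray(cx.copy_numbers, dtype=float)
        slope = float((cn * levels).sum() / (cn * cn).sum())
        constant = np.all(cn == cn[0])
        if constant:
            r = p = np.nan
            ratio = np.nan
        else:
            r, p = stats.pearsonr(cn, levels)
            hi, lo = cn.max(), cn.min()
            ratio = float(levels[cn == hi].mean() / levels[cn == lo].mean())
        rows.append(
            {
                "complex_id": cx.complex_id,
                "n_subunits": len(cx.genes),
                "r": float(r) if not constant else np.nan,
                "p": float(p) if not constant else np.nan,
                "slope": slope,
                "level_ratio_max_min_copy": ratio,
                "constant_copy_numbers": bool(constant),
            }
        )
        all_cn.extend(cn)
        all_lv.extend(levels)
    df = pd.DataFrame(rows)
    cn = np.asarray(all_cn)
    lv = np.asarray(all_lv)
    pooled: dict = {"n_points": len(cn)}
    if len(cn) >= 3 and np.std(cn) > 0:
        r, p = stats.pearsonr(cn, lv)
        pooled.update(
            pooled_r=float(r), pooled_p=float(p),
            pooled_slope=float((cn * lv).sum() / (cn * cn).sum()),
        )
    return df, pooled


def first_second_gene_correlation(
    genome: AnnotatedGenome,
    rpkm: pd.Series,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson r of log10 translation levels of first vs second operon genes.

    Uses operons with at least two genes whose levels are positive; fewer
    than three such operons is an error.
    """
    rows = []
    for operon, members in genome.operons().items():
        if len(members) < 2:
            continue
        g1, g2 = members[0].gene_id, members[1].gene_id
        if g1 not in rpkm.index or g2 not in rpkm.index:
            continue
        v1, v2 = float(rpkm[g1]), float(rpkm[g2])
        if v1 > 0 and v2 > 0:
            rows.append({"operon": operon, "first": v1, "second": v2})
    if len(rows) < 3:
        raise DataError(f"need >= 3 qualifying operons, got {len(rows)}")
    df = pd.DataFrame(rows)
    r, p = stats.pearsonr(np.log10(df["first"]), np.log10(df["second"]))
    return float(r), float(p), df


def group_comparison(
    values_a: np.ndarray | pd.Series,
    values_b: np.ndarray | pd.Series,
) -> dict:
    """Two-tailed Wilcoxon rank-sum comparison of two level groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise DataError("each group needs >= 3 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "p": float(res.pvalue),
    }
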