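"""Translation efficiency: computation, change classification, buffering,
and gene-set enrichment.

TE for a gene is the ratio of its ribosome-footprint level to its mRNA level
(RPKM_RPF / RPKM_RNA, arbitrary units).  Changes between two conditions are
classified on the log2 scale with a one-standard-deviation rule: the mean mu
and SD sigma of the log2 TE-change distribution are estimated, and genes
beyond mu +/- sigma are called high-TE / low-TE — with a unit-variance
Gaussian this flags roughly 15.9% of genes on each side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import DataError

CLASSES = ("high", "neutral", "low", "undefined")


def condition_means(rpkm: pd.DataFrame, conditions: dict[str, str]) -> pd.DataFrame:
    """Average replicate RPKM columns into one column per condition."""
    groups: dict[str, list[str]] = {}
    for sample in rpkm.columns:
        groups.setdefault(conditions[sample], []).append(sample)
    return pd.DataFrame({c: rpkm[cols].mean(axis=1) for c, cols in groups.items()})


def compute_te(
    rpkm_rpf: pd.DataFrame,
    rpkm_rna: pd.DataFrame,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Per-condition TE = RPKM_RPF / RPKM_RNA where RPKM_RNA >= floor.

    Inputs are gene x condition tables with identical labels.  Where the mRNA
    level is below the expression floor the TE is undefined (NaN) and the
    gene is excluded downstream.  With two conditions the log2 TE change
    (second condition over first) is added.
    """
    if not rpkm_rpf.index.equals(rpkm_rna.index) or list(rpkm_rpf.columns) != list(
        rpkm_rna.columns
    ):
        raise DataError("RPF and RNA tables must share gene ids and conditions")
    te = rpkm_rpf / rpkm_rna.where(rpkm_rna >= floor)
    te = te.where(te > 0)  # TE is positive wherever defined
    te.columns = [f"te_{c}" for c in rpkm_rpf.columns]
    out = te.copy()
    conds = list(rpkm_rpf.columns)
    if len(conds) >= 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["log2_te_change"] = np.log2(
                out[f"te_{conds[1]}"] / out[f"te_{conds[0]}"]
            )
    out.index.name = "gene"
    return out


@dataclass
class TEDistributionFit:
    """Moments and thresholds of a log2 TE-change distribution."""

    mu: float
    sigma: float
    n_defined: int
    n_total: int
    counts: dict[str, int]

    @property
    def low_threshold(self) -> float:
        return self.mu - self.sigma

    @property
    def high_threshold(self) -> float:
        return self.mu + self.sigma

    def fractions(self, of_defined: bool = True) -> dict[str, float]:
        denom = self.n_defined if of_defined else self.n_total
        return {k: v / denom for k, v in self.counts.items() if denom}


def classify_te_changes(
    te_table: pd.DataFrame,
    trimmed: float = 0.0,
) -> tuple[TEDistributionFit, pd.DataFrame]:
    """Label genes high/neutral/low by the mu +/- sigma rule.

    ``mu``/``sigma`` are the sample mean and SD of the defined log2 TE
    changes (the moment-matching equivalent of fitting a Gaussian curve).
    ``trimmed`` > 0 uses symmetrically trimmed estimates (fraction removed
    from each tail) for robustness to heavy tails.
    """
    if "log2_te_change" not in te_table:
        raise DataError("te_table lacks a log2_te_change column")
    delta = te_table["log2_te_change"]
    defined = delta.dropna()
    if len(defined) < 10:
        raise DataError(f"need >= 10 defined TE changes, got {len(defined)}")
    if trimmed > 0:
        x = np.sort(defined.to_numpy())
        k = int(len(x) * trimmed)
        x = x[k : len(x) - k]
        mu, sigma = float(np.mean(x)), float(np.std(x, ddof=1))
    else:
        mu, sigma = float(defined.mean()), float(defined.std(ddof=1))
    if sigma == 0 or not np.isfinite(sigma):
        raise DataError("degenerate TE-change distribution (sigma = 0)")

    labels = pd.Series("undefined", index=te_table.index, name="te_class")
    labels[defined.index] = "neutral"
    labels[defined.index[defined > mu + sigma]] = "high"
    labels[defined.index[defined < mu - sigma]] = "low"
    out = te_table.copy()
    out["te_class"] = labels
    counts = {c: int((labels == c).sum()) for c in CLASSES}
    fit = TEDistributionFit(
        mu=mu, sigma=sigma, n_defined=len(defined), n_total=len(te_table),
        counts=counts,
    )
    return fit, out


def buffering_correlation(
    mrna_log2fc: pd.Series | np.ndarray,
    te_log2fc: pd.Series | np.ndarray,
) -> tuple[float, float]:
    """Pearson correlation between mRNA change and TE change.

    A negative r indicates translational buffering: transcriptional changes
    are partially compensated at the translational level.
    """
    x = np.asarray(mrna_log2fc, dtype=float)
    y = np.asarray(te_log2fc, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise DataError("need >= 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def geneset_enrichment(
    hit_genes: set[str] | list[str],
    geneset_map: dict[str, set[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set among hits.

    p is the upper tail P(X >= overlap) for drawing ``len(hits)`` genes from
    a universe of N containing K set members; the corrected p is Bonferroni
    (p x number of sets, capped at 1).
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty gene universe")
    hits = set(hit_genes) & universe
    m = len(geneset_map)
    rows = []
    for name, members in geneset_map.items():
        extra = set(members) - universe
        if extra:
            raise DataError(f"gene set {name!r} contains genes outside the universe")
        k = len(set(members) & hits)
        kk = len(set(members))
        p = float(stats.hypergeom.sf(k - 1, len(universe), kk, len(hits)))
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": kk,
                "n_hits": len(hits),
                "universe": len(universe),
                "p": p,
                "p_bonferroni": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
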