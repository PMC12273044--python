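"""Expression integration: upper-quartile normalization, fold changes,
tiered Pearson correlation, and methylation-expression association.

Normalization equalizes each sample's 75th percentile of NONZERO gene counts
to the geometric mean of the per-sample quartiles (zeros stay zero), the
standard between-sample upper-quartile scheme.  Fold changes are
log2((tumor_mean + pc) / (normal_mean + pc)) with a pseudocount, thresholded
at |log2FC| >= 1.5 (an externally supplied per-gene p < 0.05 is honoured when
present; no count-model p-values are computed here).  Correlations are
product-moment r with the two-sided t-transform p (n-2 df) and are tiered:
strong when |r| > 0.7, moderate when 0.3 < |r| <= 0.7, none otherwise.
Benjamini-Hochberg FDR is reported alongside raw p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationRecord",
    "FoldChangeRecord",
    "upper_quartile_normalize",
    "log2_fold_change",
    "fold_change_table",
    "correlation_tier",
    "pearson",
    "meth_expr_association",
    "nat_concordance",
    "add_fdr",
]

TIER_MODERATE = 0.3
TIER_STRONG = 0.7
LOG2FC_THRESHOLD = 1.5


@dataclass(frozen=True)
class CorrelationRecord:
    pair: tuple[str, str]
    r: float
    p: float
    tier: str  # none | moderate | strong
    n: int


@dataclass(frozen=True)
class FoldChangeRecord:
    gene: str
    log2fc: float
    passes: bool
    p: float = float("nan")  # externally supplied, optional


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Between-sample upper-quartile normalization (genes x samples).

    Each sample is scaled so its 75th percentile of nonzero counts equals the
    geometric mean of the per-sample 75th percentiles; zeros stay zero.
    Idempotent and invariant to per-sample scaling.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    quartiles = np.empty(values.shape[1])
    for j, col in enumerate(values.T):
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {counts.columns[j]!r} has all-zero counts")
        quartiles[j] = np.percentile(nz, 75)
    reference = float(np.exp(np.mean(np.log(quartiles))))
    return counts * (reference / quartiles)


def log2_fold_change(
    tumor_mean: float, normal_mean: float, pseudocount: float = 1.0
) -> float:
    """log2((tumor + pc) / (normal + pc)); pc guards division by zero."""
    if tumor_mean < 0 or normal_mean < 0:
        raise ValueError("normalized means must be >= 0")
    return float(np.log2((tumor_mean + pseudocount) / (normal_mean + pseudocount)))


def fold_change_table(
    normalized: pd.DataFrame,
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str],
    pseudocount: float = 1.0,
    pvalues: Mapping[str, float] | None = None,
    threshold: float = LOG2FC_THRESHOLD,
) -> list[FoldChangeRecord]:
    """Per-gene fold-change records between two sample sets.

    ``pvalues`` is an optional externally produced per-gene p column; when
    present, passing requires |log2FC| >= threshold AND p < 0.05, otherwise
    the threshold alone applies (threshold-only, clearly labelled in output).
    """
    records = []
    t_mean = normalized[list(tumor_samples)].mean(axis=1)
    n_mean = normalized[list(normal_samples)].mean(axis=1)
    for gene in normalized.index:
        fc = log2_fold_change(float(t_mean[gene]), float(n_mean[gene]), pseudocount)
        passes = abs(fc) >= threshold
        p = float("nan")
        if pvalues is not None:
            p = float(pvalues.get(gene, np.nan))
            passes = passes and (np.isfinite(p) and p < 0.05)
        records.append(FoldChangeRecord(gene=str(gene), log2fc=fc, passes=passes, p=p))
    return records


def correlation_tier(r: float) -> str:
    """strong if |r| > 0.7, moderate if 0.3 < |r| <= 0.7, else none."""
    a = abs(r)
    if a > TIER_STRONG:
        return "strong"
    if a > TIER_MODERATE:
        return "moderate"
    return "none"


def pearson(
    x: Sequence[float], y: Sequence[float], pair: tuple[str, str] = ("x", "y")
) -> CorrelationRecord:
    """Pearson r with two-sided t-transform p (n-2 df) and tier label.

    Raises on constant input (r undefined) and on n < 3.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValueError("pearson requires two equal-length vectors, n >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError(f"constant vector for pair {pair}: r undefined")
    r, p = stats.pearsonr(xv, yv)
    return CorrelationRecord(
        pair=pair, r=float(r), p=float(p), tier=correlation_tier(float(r)), n=int(xv.size)
    )


def meth_expr_association(
    region_meth: pd.DataFrame,
    expression: pd.DataFrame,
    region_type: str = "promoter",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene correlation between region methylation and expression.

    ``region_meth``: tidy frame (gene_id, region_type, ordinal, sample_id,
    mean_pct).  ``expression``: normalized genes x samples matrix, correlated
    on log2(x+1) by default.  For each gene with >= 3 shared samples and
    non-constant vectors: r, p, tier, and a direction call (inverse if r < 0,
    concordant if r > 0).  Skipped genes are flagged in the result.
    """
    sub = region_meth[region_meth["region_type"] == region_type]
    rows = []
    for gene_id, gm in sub.groupby("gene_id", sort=True):
        if gene_id not in expression.index:
            continue
        meth = gm.groupby("sample_id")["mean_pct"].mean()
        shared = [s for s in meth.index if s in expression.columns]
        if len(shared) < 3:
            logger.info("gene %s: %d shared sample(s) < 3; skipped", gene_id, len(shared))
            rows.append((gene_id, np.nan, np.nan, "skipped", len(shared), "none"))
            continue
        expr = expression.loc[gene_id, shared].to_numpy(dtype=float)
        if log_transform:
            expr = np.log2(expr + 1.0)
        mvals = meth.loc[shared].to_numpy(dtype=float)
        if np.ptp(mvals) == 0 or np.ptp(expr) == 0:
            logger.info("gene %s: constant vector; skipped", gene_id)
            rows.append((gene_id, np.nan, np.nan, "skipped", len(shared), "none"))
            continue
        rec = pearson(mvals, expr, pair=(f"{gene_id}.{region_type}", gene_id))
        direction = "inverse" if rec.r < 0 else ("concordant" if rec.r > 0 else "none")
        rows.append((gene_id, rec.r, rec.p, rec.tier, rec.n, direction))
    df = pd.DataFrame(rows, columns=["gene_id", "r", "p", "tier", "n", "direction"])
    return add_fdr(df)


def nat_concordance(
    nat_pairs: Sequence,
    expression: pd.DataFrame,
    log_transform: bool = True,
) -> list[CorrelationRecord]:
    """Co-expression of natural-antisense lncRNA-gene pairs.

    Pearson r between the lncRNA and its partner gene across samples of the
    normalized expression matrix (log2(x+1) by default); pairs with a member
    absent from the matrix are skipped.
    """
    records = []
    for pair in nat_pairs:
        a, b = pair.lncrna_id, pair.gene_id
        if a not in expression.index or b not in expression.index:
            logger.info("NAT pair (%s, %s): member absent from matrix; skipped", a, b)
            continue
        xa = expression.loc[a].to_numpy(dtype=float)
        xb = expression.loc[b].to_numpy(dtype=float)
        if log_transform:
            xa, xb = np.log2(xa + 1.0), np.log2(xb + 1.0)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            logger.info("NAT pair (%s, %s): constant expression; skipped", a, b)
            continue
        records.append(pearson(xa, xb, pair=(a, b)))
    return records


def add_fdr(df: pd.DataFrame, p_col: str = "p") -> pd.DataFrame:
    """Append a Benjamini-Hochberg FDR column for the finite p-values."""
    out = df.copy()
    out["fdr"] = np.nan
    finite = out[p_col].notna() & np.isfinite(out[p_col])
    if finite.any():
        out.loc[finite, "fdr"] = multipletests(out.loc[finite, p_col], method="fdr_bh")[1]
    return out
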