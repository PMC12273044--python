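"""Constitutively unmethylated region (CUR) scanning.

A CUR is a maximal run of CpGs that stays essentially unmethylated in every
sample regardless of disease state — the methylome signature of permanently
open chromatin at HOX loci.  A CpG is *eligible* when, across all samples
pooled (which subsumes within-group and case-vs-control variation), its
methylation band (max - min, or SD if configured) stays below tau_cur_band
AND every sample individually sits below the tau_unmeth absolute cut-off.
Maximal runs of eligible CpGs (inter-CpG gap <= max_gap_bp, length >=
min_cur_cpgs) are then contrasted against their flanks: the nearest
min_cur_cpgs ineligible CpGs on each available side must be, on average,
tau_contrast percentage points more methylated than the run; when no flank
exists on either side the contrast is waived.

The screened territory of a gene runs from its promoter through its 3' end,
since published CURs fall both upstream of and inside gene bodies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, promoter_interval

logger = logging.getLogger(__name__)

__all__ = [
    "CURConfig",
    "CURCall",
    "cpg_band",
    "eligible_sites",
    "scan_runs",
    "scan_gene",
    "scan_cohort",
    "cur_report",
    "gene_territory",
    "interval_jaccard",
]


@dataclass(frozen=True)
class CURConfig:
    """CUR scan thresholds (percent scale unless noted).

    tau_cur_band and tau_unmeth carry the published <10% variation /
    unmethylated cut-offs; min_cur_cpgs, max_gap_bp and tau_contrast are
    implementation choices sized so published CUR spans (roughly 200-1,650
    bp) are representable.  band_stat selects range (max-min, the strictest
    reading of "variation within and between samples") or sd.
    """

    tau_cur_band: float = 10.0
    tau_unmeth: float = 10.0
    min_cur_cpgs: int = 3
    tau_contrast: float = 20.0
    max_gap_bp: int = 300
    band_stat: str = "range"  # range | sd

    def __post_init__(self) -> None:
        if min(self.tau_cur_band, self.tau_unmeth, self.tau_contrast) <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_cur_cpgs < 1 or self.max_gap_bp < 1:
            raise ValueError("min_cur_cpgs and max_gap_bp must be positive")
        if self.band_stat not in {"range", "sd"}:
            raise ValueError(f"unknown band_stat {self.band_stat!r}")


@dataclass(frozen=True)
class CURCall:
    """One constitutively unmethylated region call."""

    gene_id: str
    interval: GenomicInterval  # first -> last CpG of the run (0-based half-open)
    n_cpgs: int
    max_band: float
    mean_pct: float
    flank_contrast: float  # NaN when waived (no flank on either side)


def cpg_band(values: np.ndarray | Sequence[float], stat: str = "range") -> float:
    """Across-sample methylation variation at one CpG (percent).

    ``values`` are the retained per-sample percentages; at least 2 required.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("cpg_band needs >= 2 retained sample values")
    if stat == "range":
        return float(v.max() - v.min())
    if stat == "sd":
        return float(v.std(ddof=1))
    raise ValueError(f"unknown band statistic {stat!r}")


def eligible_sites(pct: pd.DataFrame, config: CURConfig = CURConfig()) -> pd.Series:
    """Boolean CUR-membership eligibility per CpG.

    ``pct`` is a site x sample percent matrix (NaN = not covered).  A site is
    eligible iff >= 2 samples retain it, its band over ALL samples pooled is
    < tau_cur_band, and every retained sample value is < tau_unmeth.
    """
    values = pct.to_numpy(dtype=float)
    n_obs = np.isfinite(values).sum(axis=1)
    with np.errstate(invalid="ignore"):
        if config.band_stat == "range":
            band = np.nanmax(values, axis=1, initial=-np.inf) - np.nanmin(
                values, axis=1, initial=np.inf
            )
        else:
            band = pd.DataFrame(values).std(axis=1, ddof=1).to_numpy()
        high = np.nanmax(values, axis=1, initial=-np.inf)
    ok = (n_obs >= 2) & (band < config.tau_cur_band) & (high < config.tau_unmeth)
    return pd.Series(ok, index=pct.index, name="eligible")


def _flank_mean(pct: np.ndarray, idx: Sequence[int]) -> float:
    if not len(idx):
        return np.nan
    vals = pct[list(idx), :]
    return float(np.nanmean(vals))


def scan_runs(
    positions: np.ndarray,
    eligible: np.ndarray,
    pct: np.ndarray,
    config: CURConfig,
    gene_id: str,
    chrom: str,
) -> list[CURCall]:
    """Enumerate maximal eligible runs within one gene territory.

    ``positions`` are sorted 1-based CpG positions; ``pct`` is the matching
    site x sample percent matrix.  A run breaks at any ineligible CpG and at
    inter-CpG gaps > max_gap_bp.  Runs shorter than min_cur_cpgs are dropped,
    as are runs whose flank contrast (mean of the nearest min_cur_cpgs
    ineligible CpGs per available side, pooled over sides and samples, minus
    the run mean) falls below tau_contrast; contrast is waived when no flank
    exists on either side.
    """
    positions = np.asarray(positions)
    if positions.size == 0:
        return []
    if not np.all(np.diff(positions) > 0):
        raise ValueError("CpG positions must be strictly increasing")
    # maximal runs of consecutive eligible sites, split further at large gaps
    runs: list[tuple[int, int]] = []  # inclusive index ranges
    i = 0
    n = positions.size
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and eligible[j + 1]
            and positions[j + 1] - positions[j] <= config.max_gap_bp
        ):
            j += 1
        runs.append((i, j))
        i = j + 1
    ineligible_idx = np.flatnonzero(~np.asarray(eligible, dtype=bool))
    calls = []
    for i, j in runs:
        n_cpgs = j - i + 1
        if n_cpgs < config.min_cur_cpgs:
            continue
        run_vals = pct[i : j + 1, :]
        mean_pct = float(np.nanmean(run_vals))
        bands = [cpg_band(pct[k, :], config.band_stat) for k in range(i, j + 1)]
        left = ineligible_idx[ineligible_idx < i][-config.min_cur_cpgs :]
        right = ineligible_idx[ineligible_idx > j][: config.min_cur_cpgs]
        flank_idx = list(left) + list(right)
        contrast = _flank_mean(pct, flank_idx) - mean_pct if flank_idx else np.nan
        if flank_idx and contrast < config.tau_contrast:
            logger.debug(
                "%s: run %d-%d dropped, flank contrast %.1f < %.1f",
                gene_id, positions[i], positions[j], contrast, config.tau_contrast,
            )
            continue
        calls.append(
            CURCall(
                gene_id=gene_id,
                interval=GenomicInterval(chrom, int(positions[i]) - 1, int(positions[j])),
                n_cpgs=n_cpgs,
                max_band=float(max(bands)),
                mean_pct=mean_pct,
                flank_contrast=float(contrast) if flank_idx else float("nan"),
            )
        )
    return calls


def gene_territory(gene: GeneModel) -> GenomicInterval:
    """Screened territory: promoter through the gene's 3' end."""
    prom = promoter_interval(gene)
    return GenomicInterval(
        gene.chrom, min(prom.start, gene.start), max(prom.end, gene.end), gene.strand
    )


def scan_gene(
    gene: GeneModel, pct: pd.DataFrame, config: CURConfig = CURConfig()
) -> list[CURCall]:
    """Scan one gene territory.  ``pct`` is the cohort-wide (chrom, pos) x
    sample percent matrix; sites outside the territory are ignored."""
    terr = gene_territory(gene)
    if gene.chrom not in pct.index.get_level_values(0):
        return []
    sub = pct.loc[gene.chrom]
    pos = sub.index.to_numpy()
    mask = (pos - 1 >= terr.start) & (pos - 1 < terr.end)
    if not mask.any():
        return []
    sub = sub.loc[pos[mask]]
    elig = eligible_sites(sub, config).to_numpy()
    return scan_runs(
        sub.index.to_numpy(), elig, sub.to_numpy(dtype=float), config, gene.gene_id, gene.chrom
    )


def scan_cohort(
    genes: Sequence[GeneModel], pct: pd.DataFrame, config: CURConfig = CURConfig()
) -> list[CURCall]:
    """Scan every gene territory; calls sorted by coordinate."""
    calls = []
    for gene in genes:
        calls.extend(scan_gene(gene, pct, config))
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.gene_id))
    return calls


def cur_report(
    calls: Sequence[CURCall],
    bed_path: str | Path,
    tsv_path: str | Path | None = None,
) -> None:
    """Write calls as BED6 (names gene.CUR_k) and an optional full TSV."""
    counter: dict[str, int] = {}
    named = []
    for call in calls:
        k = counter.get(call.gene_id, 0) + 1
        counter[call.gene_id] = k
        named.append((f"{call.gene_id}.CUR_{k}", call))
    with open(bed_path, "w") as fh:
        for name, call in named:
            iv = call.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write(
                "name\tgene_id\tchrom\tstart\tend\tn_cpgs\tmax_band\tmean_pct\tflank_contrast\n"
            )
            for name, call in named:
                iv = call.interval
                fh.write(
                    f"{name}\t{call.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{call.n_cpgs}\t{call.max_band:.4f}\t{call.mean_pct:.4f}\t"
                    f"{call.flank_contrast:.4f}\n"
                )


def interval_jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    """Jaccard index of two intervals (0 when on different chromosomes)."""
    inter = a.overlap_bp(b)
    union = a.length + b.length - inter
    return inter / union if union else 0.0


def tighten(config: CURConfig, **kw) -> CURConfig:
    """Return a config with replaced fields (convenience for sensitivity runs)."""
    return replace(config, **kw)
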