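"""Per-sample CpG methylation: coverage parsing, region summaries, matched
tumor-normal differences and hyper/hypo classification.

Input is a bismark-style cytosine coverage table per sample (tab-separated:
chrom, start (1-based), end, methylation %, count methylated, count
unmethylated).  Counts are authoritative: the percent column is recomputed
from counts and the reported value only triggers a logged inconsistency
warning when it deviates by more than 0.5.

Region-level methylation is the UNWEIGHTED mean of per-CpG percentages (not
read-weighted), so sequencing depth does not masquerade as biology.  A
matched tumor-normal region difference > +25% is called hypermethylated and
< -25% hypomethylated, with strict inequalities at the boundaries; regions
with no covered CpGs propagate as missing, never as 0%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, RegionKey, derive_regions

logger = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "MethylationCall",
    "RegionSummary",
    "DiffMethRecord",
    "read_coverage",
    "write_coverage",
    "read_metadata",
    "pct_matrix",
    "region_mean",
    "region_summaries",
    "region_meth_long",
    "matched_delta",
    "classify_diff",
    "matched_pairs",
    "diffmeth_table",
    "group_cpg_profile",
]

COVERAGE_COLUMNS = ["chrom", "pos", "n_meth", "n_unmeth", "pct"]
METADATA_COLUMNS = ["sample_id", "patient_id", "tissue", "group", "histology"]

GROUPS = ("PMOL", "TN0", "TN0plus")
HISTOLOGIES = ("leukoplakia", "WDSCC", "MDSCC", "other", "NA")


@dataclass(frozen=True)
class Thresholds:
    """Classification cut-offs (percent scale) and data-retention floors.

    tau_hyper/tau_unmeth/tau_cur_band carry the published 25% / 10% / 10%
    cut-offs; min_coverage and min_cpgs_per_region are retention floors of
    this implementation (configurable).
    """

    tau_hyper: float = 25.0
    tau_unmeth: float = 10.0
    tau_cur_band: float = 10.0
    min_coverage: int = 5
    min_cpgs_per_region: int = 1

    def __post_init__(self) -> None:
        for name in ("tau_hyper", "tau_unmeth", "tau_cur_band", "min_coverage",
                     "min_cpgs_per_region"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class MethylationCall(NamedTuple):
    """One retained CpG call in one sample (counts authoritative)."""

    chrom: str
    pos: int  # 1-based
    sample_id: str
    n_meth: int
    n_unmeth: int

    @property
    def pct(self) -> float:
        return 100.0 * self.n_meth / (self.n_meth + self.n_unmeth)


@dataclass(frozen=True)
class RegionSummary:
    region: RegionKey
    sample_id: str
    mean_pct: float
    n_cpgs: int
    min_coverage_used: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_pct <= 100.0):
            raise ValueError("mean_pct outside [0, 100]")
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")


@dataclass(frozen=True)
class DiffMethRecord:
    region: RegionKey
    delta_pct: float
    call: str  # hyper | hypo | none
    n_pairs: int


def read_coverage(
    path: str | Path, sample_id: str, min_coverage: int = 5
) -> pd.DataFrame:
    """Read one bismark-style cytosine coverage file.

    Returns a DataFrame with columns chrom, pos (1-based), n_meth, n_unmeth,
    pct; one row per retained CpG call (total reads >= min_coverage).  When
    start != end the interval collapses to start.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "pct_reported", "n_meth", "n_unmeth"],
            dtype={"chrom": str},
        )
        for col in ("start", "n_meth", "n_unmeth"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed coverage file: {exc}") from exc
    if (df[["n_meth", "n_unmeth"]] < 0).to_numpy().any():
        bad = int(np.argmax((df[["n_meth", "n_unmeth"]] < 0).any(axis=1).to_numpy())) + 1
        raise ValueError(f"{path}: line {bad}: negative counts")
    total = df["n_meth"] + df["n_unmeth"]
    df = df[total >= max(1, min_coverage)].copy()
    total = df["n_meth"] + df["n_unmeth"]
    df["pct"] = 100.0 * df["n_meth"] / total
    mismatch = (df["pct_reported"] - df["pct"]).abs() > 0.5
    if mismatch.any():
        logger.warning(
            "%s: %d call(s) with reported %% deviating >0.5 from counts; counts kept",
            path, int(mismatch.sum()),
        )
    df = df.rename(columns={"start": "pos"})
    df["sample_id"] = sample_id
    return df[["chrom", "pos", "n_meth", "n_unmeth", "pct", "sample_id"]].reset_index(drop=True)


def write_coverage(df: pd.DataFrame, path: str | Path) -> None:
    """Write calls in the coverage dialect read_coverage consumes."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"],
            "pct": df["pct"].round(6),
            "n_meth": df["n_meth"],
            "n_unmeth": df["n_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata table."""
    # keep_default_na: histology uses the literal string "NA" for normals
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    bad_tissue = set(meta["tissue"]) - {"normal", "tumor"}
    if bad_tissue:
        raise ValueError(f"{path}: unknown tissue values {sorted(bad_tissue)}")
    bad_group = set(meta["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"{path}: unknown group values {sorted(bad_group)}")
    return meta


def pct_matrix(coverage: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble per-sample calls into a (chrom, pos) x sample percent matrix.

    Sites a sample does not cover are NaN.
    """
    cols = {
        sid: df.set_index(["chrom", "pos"])["pct"]
        for sid, df in coverage.items()
    }
    mat = pd.DataFrame(cols)
    return mat.sort_index()


# ---------------------------------------------------------------------------
# region summaries and matched differences
# ---------------------------------------------------------------------------

def region_mean(
    calls: pd.DataFrame,
    interval: GenomicInterval,
    key: RegionKey,
    min_cpgs: int = 1,
    min_coverage: int = 5,
) -> RegionSummary | None:
    """Unweighted mean CpG methylation of one sample over one region.

    Returns None (missing, flagged in the log) when fewer than ``min_cpgs``
    retained CpGs fall inside the interval.
    """
    inside = calls[
        (calls["chrom"] == interval.chrom)
        & (calls["pos"] - 1 >= interval.start)
        & (calls["pos"] - 1 < interval.end)
    ]
    if len(inside) < max(1, min_cpgs):
        logger.debug("region %s: %d CpG(s) < %d required; missing", key, len(inside), min_cpgs)
        return None
    sample_id = str(inside["sample_id"].iloc[0]) if "sample_id" in inside else ""
    return RegionSummary(
        region=key,
        sample_id=sample_id,
        mean_pct=float(inside["pct"].mean()),
        n_cpgs=int(len(inside)),
        min_coverage_used=min_coverage,
    )


def region_summaries(
    calls: pd.DataFrame,
    genes: Sequence[GeneModel],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-region mean methylation for one sample over all genes' regions.

    Returns a tidy frame (gene_id, region_type, ordinal, mean_pct, n_cpgs);
    regions without covered CpGs are absent (missing, not 0).
    """
    # sort calls once per chromosome; each region is then a searchsorted slice
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in calls.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        by_chrom[str(chrom)] = (
            sub["pos"].to_numpy()[order],
            sub["pct"].to_numpy(dtype=float)[order],
        )
    min_cpgs = max(1, thresholds.min_cpgs_per_region)
    rows = []
    for gene in genes:
        for key, iv in derive_regions(gene):
            if iv.chrom not in by_chrom:
                continue
            pos, pct = by_chrom[iv.chrom]
            lo = np.searchsorted(pos - 1, iv.start, side="left")
            hi = np.searchsorted(pos - 1, iv.end, side="left")
            if hi - lo < min_cpgs:
                continue
            rows.append(
                (key.gene_id, key.region_type, key.ordinal,
                 float(pct[lo:hi].mean()), int(hi - lo))
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "region_type", "ordinal", "mean_pct", "n_cpgs"]
    )


def region_meth_long(
    coverage: Mapping[str, pd.DataFrame],
    genes: Sequence[GeneModel],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Cohort-wide tidy region methylation (region_summaries + sample_id)."""
    frames = []
    for sid, calls in coverage.items():
        rs = region_summaries(calls, genes, thresholds)
        rs["sample_id"] = sid
        frames.append(rs)
    return pd.concat(frames, ignore_index=True)


def matched_delta(tumor_summary: RegionSummary, normal_summary: RegionSummary) -> float:
    """Tumor minus normal region methylation (%) for one matched pair."""
    if tumor_summary.region != normal_summary.region:
        raise ValueError(
            f"region mismatch: {tumor_summary.region} vs {normal_summary.region}"
        )
    return tumor_summary.mean_pct - normal_summary.mean_pct


def classify_diff(delta_pct: float, thresholds: Thresholds = Thresholds()) -> str:
    """hyper if delta > +tau, hypo if < -tau, else none (strict at the boundary)."""
    if not math.isfinite(delta_pct):
        raise ValueError("delta_pct must be finite")
    if delta_pct > thresholds.tau_hyper:
        return "hyper"
    if delta_pct < -thresholds.tau_hyper:
        return "hypo"
    return "none"


def matched_pairs(metadata: pd.DataFrame) -> list[tuple[str, str, str, str]]:
    """(patient_id, group, tumor_sample, normal_sample) for complete pairs."""
    pairs = []
    for pid, sub in metadata.groupby("patient_id", sort=True):
        tumors = sub[sub["tissue"] == "tumor"]["sample_id"].tolist()
        normals = sub[sub["tissue"] == "normal"]["sample_id"].tolist()
        if len(tumors) == 1 and len(normals) == 1:
            pairs.append((pid, sub["group"].iloc[0], tumors[0], normals[0]))
        else:
            logger.info("patient %s: incomplete pair (%d tumor, %d normal); excluded",
                        pid, len(tumors), len(normals))
    return pairs


def diffmeth_table(
    coverage: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    genes: Sequence[GeneModel],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Region x group matched-difference table (heatmap-ready).

    For each region and disease group: delta_pct = mean over matched pairs of
    (tumor - normal) region methylation, pair-first; plus the hyper/hypo/none
    call and the number of contributing pairs.  Pairs where either side lacks
    the region are excluded.
    """
    summaries = {
        sid: df.set_index(["gene_id", "region_type", "ordinal"])["mean_pct"]
        for sid, df in (
            (sid, region_summaries(coverage[sid], genes, thresholds))
            for sid in coverage
        )
    }
    rows = []
    all_regions = sorted(set().union(*[set(s.index) for s in summaries.values()]))
    pairs = matched_pairs(metadata)
    for region in all_regions:
        for group in GROUPS:
            deltas = []
            for _pid, g, t_sid, n_sid in pairs:
                if g != group:
                    continue
                t = summaries.get(t_sid)
                n = summaries.get(n_sid)
                if t is None or n is None or region not in t.index or region not in n.index:
                    continue
                deltas.append(t.loc[region] - n.loc[region])
            if deltas:
                delta = float(np.mean(deltas))
                rows.append(
                    (*region, group, delta, classify_diff(delta, thresholds), len(deltas))
                )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "region_type", "ordinal", "group", "delta_pct", "call", "n_pairs"],
    )


def group_cpg_profile(
    coverage: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    group: str,
    loci: Iterable[tuple[str, int]],
) -> pd.DataFrame:
    """Per-CpG matched-delta profile for one disease group.

    For each locus (chrom, 1-based pos): mean over the group's matched pairs
    of (tumor - normal) percent and the standard error (sample SD / sqrt(n));
    SE is NaN with fewer than 2 pairs.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    mat = pct_matrix(coverage)
    rows = []
    pairs = [(t, n) for _pid, g, t, n in matched_pairs(metadata) if g == group]
    for chrom, pos in loci:
        deltas = []
        if (chrom, pos) in mat.index:
            site = mat.loc[(chrom, pos)]
            for t_sid, n_sid in pairs:
                t, n = site.get(t_sid, np.nan), site.get(n_sid, np.nan)
                if np.isfinite(t) and np.isfinite(n):
                    deltas.append(t - n)
        mean = float(np.mean(deltas)) if deltas else np.nan
        se = float(np.std(deltas, ddof=1) / np.sqrt(len(deltas))) if len(deltas) >= 2 else np.nan
        rows.append((chrom, pos, mean, se, len(deltas)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "mean_delta", "se", "n_pairs"])
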