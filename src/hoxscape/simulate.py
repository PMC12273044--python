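"""Synthetic matched tumor-normal cohorts with HOX-cluster structure.

The generator emits everything the analysis modules consume — annotation,
per-sample cytosine coverage, sample metadata, expression counts — together
with truth tables describing every planted structure, so each pipeline stage
is testable without any external data.

What is emulated
----------------
* a 39-gene four-cluster HOX-like annotation with six embedded antisense
  lncRNAs (coordinates styled on hg19 so reports read naturally; the data
  are synthetic);
* matched tumor-normal pairs in three disease groups (PMOL / TN0 / TN0plus,
  default 8/6/8 pairs) with histology labels (3 leukoplakia, 8 WDSCC,
  5 MDSCC under the defaults);
* beta-binomial CpG methylation: background sites draw Beta(15, 5)
  methylation per sample; planted constitutively unmethylated regions (CURs)
  carry a shared near-zero site level (Beta(0.5, 30) truncated at 2% — the
  constitutive regime, so a planted CUR satisfies the CUR definition by
  construction) with binomial read noise on top; CpGs are pinned at planted
  interval boundaries so a perfect call spans the recorded interval exactly;
* a progressively hypermethylated 8-CpG intronic panel (PMOL +5, TN0 +15,
  TN0plus +40 percentage points in tumors, applied on the logit scale so the
  group ordering survives near the probability boundaries);
* mildly hypermethylated tumor regions (exonic/intronic) for the
  differential heatmap to find;
* negative-binomial expression with promoter-methylation-coupled genes
  (log2 mean decreasing in methylation) and shared-latent-factor
  co-expression for designated natural-antisense pairs.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, GenomicInterval, write_gtf
from .curscan import gene_territory
from .methcov import read_metadata, write_coverage

__all__ = [
    "SimConfig",
    "CohortBundle",
    "default_gene_models",
    "generate",
    "worked_fixture",
    "PANEL_LOCI",
    "PLANTED_CURS",
]

# ---------------------------------------------------------------------------
# fixture annotation: 39 HOX-like coding genes in 4 clusters + 6 lncRNAs
# ---------------------------------------------------------------------------

# (symbol, chrom, strand, exons, biotype); coordinates styled on hg19.
_GRID_LEN = 3000


def _grid_exons(chrom: str, start: int, strand: str) -> tuple[GenomicInterval, ...]:
    return (
        GenomicInterval(chrom, start, start + 1200, strand),
        GenomicInterval(chrom, start + 1800, start + _GRID_LEN, strand),
    )


def _gene(symbol, chrom, strand, exons, biotype="coding"):
    return GeneModel(
        gene_id=symbol, symbol=symbol, chrom=chrom, strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype=biotype,
    )


def default_gene_models() -> list[GeneModel]:
    """The packaged synthetic HOX-like annotation (39 coding + 6 lncRNA)."""
    genes: list[GeneModel] = []
    # --- HOXA cluster, chr7, minus strand ---
    genes.append(_gene("HOXA1", "chr7", "-", [(27132613, 27133689), (27134950, 27136000)]))
    for sym, start in [("HOXA2", 27140000), ("HOXA3", 27149000), ("HOXA4", 27158000),
                       ("HOXA5", 27167000), ("HOXA6", 27176000), ("HOXA7", 27185000),
                       ("HOXA9", 27194000), ("HOXA10", 27203000), ("HOXA13", 27212000)]:
        genes.append(_gene(sym, "chr7", "-",
                           [(start, start + 1200), (start + 1800, start + _GRID_LEN)]))
    genes.append(_gene("HOXA11", "chr7", "-", [(27220000, 27221500), (27222500, 27226000)]))
    # --- HOXB cluster, chr17, minus strand ---
    for sym, start in [("HOXB13", 46603000), ("HOXB1", 46620000), ("HOXB2", 46627000),
                       ("HOXB3", 46634000), ("HOXB4", 46641000), ("HOXB7", 46648000),
                       ("HOXB8", 46655000)]:
        genes.append(_gene(sym, "chr17", "-",
                           [(start, start + 1200), (start + 1800, start + _GRID_LEN)]))
    genes.append(_gene("HOXB5", "chr17", "-", [(46665000, 46667000), (46669000, 46671500)]))
    genes.append(_gene("HOXB6", "chr17", "-", [(46676000, 46677500), (46678500, 46680500)]))
    genes.append(_gene("HOXB9", "chr17", "-", [(46698519, 46699801), (46702700, 46703835)]))
    # --- HOXC cluster, chr12, plus strand ---
    for sym, start in [("HOXC4", 54330000), ("HOXC6", 54336000), ("HOXC8", 54342000),
                       ("HOXC9", 54348000), ("HOXC12", 54354000), ("HOXC13", 54360000)]:
        genes.append(_gene(sym, "chr12", "+",
                           [(start, start + 1200), (start + 1800, start + _GRID_LEN)]))
    genes.append(_gene("HOXC11", "chr12", "+", [(54366000, 54367000), (54369800, 54370500)]))
    genes.append(_gene("HOXC10", "chr12", "+", [(54378000, 54379500), (54380200, 54382000)]))
    genes.append(_gene("HOXC5", "chr12", "+", [(54426000, 54427500), (54428200, 54430000)]))
    # --- HOXD cluster, chr2, plus strand ---
    for sym, start in [("HOXD1", 176930000), ("HOXD3", 176937000), ("HOXD4", 176944000),
                       ("HOXD8", 176951000), ("HOXD9", 176958000), ("HOXD10", 176965000),
                       ("HOXD11", 176972000), ("HOXD12", 176979000), ("HOXD13", 176986000)]:
        genes.append(_gene(sym, "chr2", "+",
                           [(start, start + 1200), (start + 1800, start + _GRID_LEN)]))
    # --- embedded antisense lncRNAs (opposite strand to their partners) ---
    genes.append(_gene("HOTAIRM1", "chr7", "+",
                       [(27135600, 27135900), (27136100, 27136400)], "lncRNA"))
    genes.append(_gene("HOXA10-AS", "chr7", "+", [(27204000, 27204400)], "lncRNA"))
    genes.append(_gene("HOXB-AS3", "chr17", "+",
                       [(46671000, 46671300), (46679000, 46679300)], "lncRNA"))
    genes.append(_gene("HOXC13-AS", "chr12", "-", [(54360500, 54360900)], "lncRNA"))
    genes.append(_gene("HAGLR", "chr2", "-",
                       [(176930500, 176930900), (176937400, 176937800)], "lncRNA"))
    genes.append(_gene("HOXD-AS1", "chr2", "-", [(176938900, 176939300)], "lncRNA"))
    return genes


# 8-CpG intronic panel inside HOXB9 (1-based positions, chr17), spanning the
# interval 46702528-46702583.
PANEL_CHROM = "chr17"
PANEL_LOCI: tuple[int, ...] = (
    46702528, 46702535, 46702542, 46702549, 46702556, 46702563, 46702570, 46702583,
)

# planted CUR spans (0-based half-open), one per gene, inside its territory
PLANTED_CURS: dict[str, tuple[str, int, int]] = {
    "HOXA1": ("chr7", 27135301, 27136558),
    "HOXA11": ("chr7", 27223858, 27224500),
    "HOXB5": ("chr17", 46671202, 46671443),
    "HOXB6": ("chr17", 46679967, 46680261),
    "HOXB9": ("chr17", 46703139, 46703596),
    "HOXC5": ("chr12", 54426389, 54426695),
    "HOXC10": ("chr12", 54378697, 54378899),
    "HOXC11": ("chr12", 54367151, 54368797),
}

# mild tumor hypermethylation planted in gene bodies (region interval looked
# up from the gene model; delta in percentage points at a 30% base)
PLANTED_DMRS: dict[str, tuple[str, float]] = {
    "HOXA4": ("exon", 35.0),
    "HOXD3": ("exon", 35.0),
    "HOXA6": ("intron", 30.0),
    "HOXB9": ("intron", 30.0),
}

# genes with inverse promoter-methylation -> expression coupling
COUPLED_GENES: tuple[str, ...] = ("HOXA3", "HOXA4", "HOXA10", "HOXB4", "HOXD12", "HOXD13")

# natural-antisense pairs given a shared expression factor
NAT_COEXPRESSED: tuple[tuple[str, str], ...] = (
    ("HOTAIRM1", "HOXA1"),
    ("HOXA10-AS", "HOXA10"),
    ("HOXC13-AS", "HOXC13"),
    ("HOXD-AS1", "HOXD3"),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated study: 8/6/8 matched pairs, an 8-CpG panel
    with progressive tumor hypermethylation (+5/+15/+40 points), planted CURs
    at the eight published-style spans, 150x mean on-target depth (typical of
    targeted methyl-capture) and ~10 bp CpG spacing (CpG-island-dense HOX
    territory).
    """

    seed: int = 20250717
    n_pairs: Mapping[str, int] = field(
        default_factory=lambda: {"PMOL": 8, "TN0": 6, "TN0plus": 8}
    )
    cpg_spacing: float = 10.0
    depth: float = 150.0
    beta_background: tuple[float, float] = (15.0, 5.0)
    beta_unmeth: tuple[float, float] = (0.5, 30.0)
    unmeth_cap: float = 0.02  # truncation keeping CUR sites constitutive
    planted_curs: Mapping[str, tuple[str, int, int]] = field(
        default_factory=lambda: dict(PLANTED_CURS)
    )
    panel_loci: tuple[int, ...] = PANEL_LOCI
    panel_effect: Mapping[str, float] = field(
        default_factory=lambda: {"PMOL": 5.0, "TN0": 15.0, "TN0plus": 40.0}
    )
    panel_base: float = 0.10
    planted_dmrs: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(PLANTED_DMRS)
    )
    coupled_genes: tuple[str, ...] = COUPLED_GENES
    coupling_b: float = 3.0  # log2 expression units per methylation fraction
    nat_pairs: tuple[tuple[str, str], ...] = NAT_COEXPRESSED
    nat_rho: float = 1.5  # SD (log2) of the shared NAT factor; dominates noise
    expr_log2_mu: tuple[float, float] = (4.0, 9.0)
    expr_dispersion: float = 0.05
    min_coverage: int = 5

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_pairs.values()):
            raise ValueError("each group needs >= 2 matched pairs")
        if min(self.cpg_spacing, self.depth, self.expr_dispersion, self.nat_rho) <= 0:
            raise ValueError("rates and dispersions must be positive")


@dataclass
class CohortBundle:
    """A complete in-memory synthetic cohort plus its truth tables."""

    config: SimConfig
    gene_models: list[GeneModel]
    metadata: pd.DataFrame
    sites: pd.DataFrame  # chrom, pos (1-based), site_class
    depth: np.ndarray  # sites x samples read totals
    n_meth: np.ndarray  # sites x samples methylated counts
    counts: pd.DataFrame  # genes x samples expression counts
    truth: dict[str, pd.DataFrame]

    @property
    def sample_ids(self) -> list[str]:
        return self.metadata["sample_id"].tolist()

    def pct_matrix(self, min_coverage: int | None = None) -> pd.DataFrame:
        """(chrom, pos) x sample percent matrix; NaN below the coverage floor."""
        floor = self.config.min_coverage if min_coverage is None else min_coverage
        d = self.depth.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(d >= max(1, floor), 100.0 * self.n_meth / d, np.nan)
        idx = pd.MultiIndex.from_frame(self.sites[["chrom", "pos"]])
        return pd.DataFrame(pct, index=idx, columns=self.sample_ids).sort_index()

    def coverage_frames(self) -> dict[str, pd.DataFrame]:
        """Per-sample call frames in the layout read_coverage produces."""
        out = {}
        floor = max(1, self.config.min_coverage)
        for j, sid in enumerate(self.sample_ids):
            d = self.depth[:, j]
            keep = d >= floor
            df = pd.DataFrame(
                {
                    "chrom": self.sites["chrom"][keep].to_numpy(),
                    "pos": self.sites["pos"][keep].to_numpy(),
                    "n_meth": self.n_meth[keep, j],
                    "n_unmeth": d[keep] - self.n_meth[keep, j],
                }
            )
            df["pct"] = 100.0 * df["n_meth"] / (df["n_meth"] + df["n_unmeth"])
            df["sample_id"] = sid
            out[sid] = df
        return out

    def write(self, outdir: str | Path) -> None:
        """Write the bundle as the plain-text file set the pipeline consumes."""
        outdir = Path(outdir)
        (outdir / "coverage").mkdir(parents=True, exist_ok=True)
        write_gtf(self.gene_models, outdir / "annotation.gtf")
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
        for sid, df in self.coverage_frames().items():
            write_coverage(df, outdir / "coverage" / f"{sid}.cov.tsv")
        for name, table in self.truth.items():
            table.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)

    def checksum_payload(self) -> bytes:
        """Canonical byte serialization (for determinism checks)."""
        buf = io.BytesIO()
        buf.write(self.metadata.to_csv(index=False).encode())
        buf.write(self.sites.to_csv(index=False).encode())
        buf.write(np.ascontiguousarray(self.depth).tobytes())
        buf.write(np.ascontiguousarray(self.n_meth).tobytes())
        buf.write(self.counts.to_csv().encode())
        return buf.getvalue()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _build_metadata(config: SimConfig) -> pd.DataFrame:
    rows = []
    patient_no = 0
    for group in ("PMOL", "TN0", "TN0plus"):
        n = config.n_pairs.get(group, 0)
        for k in range(n):
            patient_no += 1
            pid = f"P{patient_no:02d}"
            if group == "PMOL":
                hist = "leukoplakia" if k < 3 else "other"
            elif group == "TN0":
                hist = "WDSCC"
            else:
                hist = "WDSCC" if k < 2 else ("MDSCC" if k < 7 else "other")
            rows.append((f"{pid}_T", pid, "tumor", group, hist))
            rows.append((f"{pid}_N", pid, "normal", group, "NA"))
    return pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "tissue", "group", "histology"]
    )


def _merged_territories(genes: Sequence[GeneModel]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        t = gene_territory(g)
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    merged = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def _cpg_positions(
    rng: np.random.Generator,
    territories: dict[str, list[tuple[int, int]]],
    config: SimConfig,
) -> dict[str, np.ndarray]:
    """1-based CpG positions per chromosome: a geometric-gap point process
    plus pinned positions (planted-CUR boundaries, panel loci)."""
    pinned: dict[str, list[int]] = {}
    for _gene, (chrom, s, e) in config.planted_curs.items():
        pinned.setdefault(chrom, []).extend([s + 1, e])
    pinned.setdefault(PANEL_CHROM, []).extend(config.panel_loci)
    positions = {}
    p_gap = 1.0 / config.cpg_spacing
    for chrom in sorted(territories):
        pos: list[np.ndarray] = []
        for s, e in territories[chrom]:
            length = e - s
            n_draw = int(length * p_gap * 1.6) + 20
            gaps = rng.geometric(p_gap, size=n_draw)
            pts = s + np.cumsum(gaps)
            pos.append(pts[pts <= e] )  # 1-based positions in (s, e]
        allpos = np.concatenate(pos + [np.array(pinned.get(chrom, []), dtype=np.int64)])
        positions[chrom] = np.unique(allpos.astype(np.int64))
    return positions


def _truncated_beta(rng: np.random.Generator, a: float, b: float, cap: float,
                    size: int) -> np.ndarray:
    """Inverse-CDF sampling of Beta(a, b) conditioned on X <= cap."""
    u = rng.uniform(0.0, stats.beta.cdf(cap, a, b), size=size)
    return stats.beta.ppf(u, a, b)


def _logit(p: np.ndarray | float) -> np.ndarray:
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _region_intervals(gene: GeneModel, region_type: str) -> list[GenomicInterval]:
    if region_type == "exon":
        return list(gene.exons)
    if region_type == "intron":
        return list(gene.introns_transcript_order())
    raise ValueError(f"unsupported planted region type {region_type!r}")


def generate(config: SimConfig) -> CohortBundle:
    """Generate a full synthetic cohort bundle (deterministic given seed)."""
    rng = np.random.default_rng(config.seed)
    genes = default_gene_models()
    by_id = {g.gene_id: g for g in genes}

    # validate planted structures against territories
    for gene_id, (chrom, s, e) in config.planted_curs.items():
        if gene_id not in by_id:
            raise ValueError(f"planted CUR references unknown gene {gene_id!r}")
        t = gene_territory(by_id[gene_id])
        if not (t.chrom == chrom and t.start <= s and e <= t.end):
            raise ValueError(f"planted CUR {gene_id} [{s}, {e}) outside gene territory")

    metadata = _build_metadata(config)
    sample_ids = metadata["sample_id"].tolist()
    n_samples = len(sample_ids)
    is_tumor = (metadata["tissue"] == "tumor").to_numpy()
    group_of = metadata["group"].to_numpy()

    territories = _merged_territories(genes)
    positions = _cpg_positions(rng, territories, config)
    site_rows = []
    for chrom in sorted(positions):
        for pos in positions[chrom]:
            site_rows.append((chrom, int(pos)))
    sites = pd.DataFrame(site_rows, columns=["chrom", "pos"])
    n_sites = len(sites)
    chrom_arr = sites["chrom"].to_numpy()
    pos0 = sites["pos"].to_numpy() - 1  # 0-based

    # --- site classes, with precedence CUR > panel > coupled promoter > DMR ---
    site_class = np.full(n_sites, "background", dtype=object)

    def _mask(chrom: str, s: int, e: int) -> np.ndarray:
        return (chrom_arr == chrom) & (pos0 >= s) & (pos0 < e)

    dmr_masks = {}
    for gene_id, (rtype, delta) in config.planted_dmrs.items():
        m = np.zeros(n_sites, dtype=bool)
        for iv in _region_intervals(by_id[gene_id], rtype):
            m |= _mask(iv.chrom, iv.start, iv.end)
        dmr_masks[gene_id] = m
        site_class[m] = "dmr"
    coupled_masks = {}
    for gene_id in config.coupled_genes:
        from .annotation import promoter_interval

        iv = promoter_interval(by_id[gene_id])
        m = _mask(iv.chrom, iv.start, iv.end)
        coupled_masks[gene_id] = m
        site_class[m] = "coupled_promoter"
    panel_mask = (chrom_arr == PANEL_CHROM) & np.isin(sites["pos"].to_numpy(),
                                                      np.asarray(config.panel_loci))
    site_class[panel_mask] = "panel"
    cur_mask = np.zeros(n_sites, dtype=bool)
    for gene_id, (chrom, s, e) in config.planted_curs.items():
        cur_mask |= _mask(chrom, s, e)
    site_class[cur_mask] = "cur"
    sites["site_class"] = site_class

    # --- per-site, per-sample methylation probabilities ---
    a_bg, b_bg = config.beta_background
    p = rng.beta(a_bg, b_bg, size=(n_sites, n_samples))

    cur_idx = np.flatnonzero(cur_mask)
    a_u, b_u = config.beta_unmeth
    cur_levels = _truncated_beta(rng, a_u, b_u, config.unmeth_cap, cur_idx.size)
    p[cur_idx, :] = cur_levels[:, None]

    # panel: shared low base, logit-scale tumor shift by group, mild noise
    panel_idx = np.flatnonzero(panel_mask)
    base = rng.beta(10, 90, size=panel_idx.size)
    shift = np.zeros(n_samples)
    for g, delta in config.panel_effect.items():
        target = min(0.95, config.panel_base + delta / 100.0)
        shift[(group_of == g) & is_tumor] = float(
            _logit(target) - _logit(config.panel_base)
        )
    noise = rng.normal(0.0, 0.15, size=(panel_idx.size, n_samples))
    p[panel_idx, :] = _expit(_logit(base)[:, None] + shift[None, :] + noise)

    # planted DMRs: moderate base, tumor logit shift sized to the target delta
    for gene_id, (rtype, delta) in config.planted_dmrs.items():
        idx = np.flatnonzero(dmr_masks[gene_id] & ~panel_mask & ~cur_mask)
        if idx.size == 0:
            continue
        base = rng.beta(6, 14, size=idx.size)
        dshift = float(_logit(min(0.95, 0.30 + delta / 100.0)) - _logit(0.30))
        noise = rng.normal(0.0, 0.3, size=(idx.size, n_samples))
        p[idx, :] = _expit(
            _logit(base)[:, None] + dshift * is_tumor[None, :] + noise
        )

    # coupled promoters: one methylation state per gene x sample, shared
    # across the promoter's CpGs (patient-specific epigenetic state)
    coupling_state = {}
    for gene_id in config.coupled_genes:
        idx = np.flatnonzero(coupled_masks[gene_id] & ~panel_mask & ~cur_mask)
        m_state = rng.beta(2, 2, size=n_samples)
        coupling_state[gene_id] = m_state
        if idx.size:
            p[idx, :] = np.clip(m_state[None, :], 0.01, 0.99)

    # --- reads ---
    depth = rng.poisson(config.depth, size=(n_sites, n_samples))
    n_meth = rng.binomial(depth, p)

    # --- expression ---
    all_ids = [g.gene_id for g in genes]
    log2_mu = rng.uniform(*config.expr_log2_mu, size=len(all_ids))
    log2_mat = np.tile(log2_mu[:, None], (1, n_samples)).astype(float)
    gene_row = {gid: i for i, gid in enumerate(all_ids)}
    for gene_id in config.coupled_genes:
        log2_mat[gene_row[gene_id], :] += config.coupling_b * (
            0.5 - coupling_state[gene_id]
        )
    for lnc, partner in config.nat_pairs:
        f = rng.normal(0.0, config.nat_rho, size=n_samples)
        log2_mat[gene_row[lnc], :] += f
        log2_mat[gene_row[partner], :] += f
    log2_mat += rng.normal(0.0, 0.25, size=log2_mat.shape)
    size_factor = rng.uniform(0.7, 1.4, size=n_samples)
    mu = (2.0 ** log2_mat) * size_factor[None, :]
    r = 1.0 / config.expr_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=all_ids, columns=sample_ids)

    # --- truth tables ---
    truth = {
        "curs": pd.DataFrame(
            [(g, c, s, e) for g, (c, s, e) in sorted(config.planted_curs.items())],
            columns=["gene_id", "chrom", "start", "end"],
        ),
        "panel": pd.DataFrame(
            {
                "chrom": PANEL_CHROM,
                "pos": list(config.panel_loci),
            }
        ).assign(
            **{f"delta_{g}": d for g, d in config.panel_effect.items()}
        ),
        "couplings": pd.DataFrame(
            {"gene_id": list(config.coupled_genes),
             "coupling_b": config.coupling_b}
        ),
        "nat_pairs": pd.DataFrame(
            config.nat_pairs, columns=["lncrna_id", "gene_id"]
        ).assign(nat_rho=config.nat_rho),
        "dmrs": pd.DataFrame(
            [(g, t, d) for g, (t, d) in sorted(config.planted_dmrs.items())],
            columns=["gene_id", "region_type", "delta_pct"],
        ),
    }

    return CohortBundle(
        config=config,
        gene_models=genes,
        metadata=metadata,
        sites=sites,
        depth=depth,
        n_meth=n_meth,
        counts=counts_df,
        truth=truth,
    )


def worked_fixture(seed: int | None = None) -> CohortBundle:
    """The packaged small cohort: 8/6/8 matched pairs, the 8-CpG panel at
    chr17:46702528-46702583, CURs planted at the eight fixture spans."""
    config = SimConfig() if seed is None else replace(SimConfig(), seed=seed)
    return generate(config)


def background_genes(bundle: CohortBundle) -> list[str]:
    """Genes whose territory intersects no planted structure (pure noise)."""
    structured: list[tuple[str, int, int]] = [
        (c, s, e) for _g, (c, s, e) in bundle.config.planted_curs.items()
    ]
    structured.append(
        (PANEL_CHROM, min(bundle.config.panel_loci) - 1, max(bundle.config.panel_loci))
    )
    by_id = {g.gene_id: g for g in bundle.gene_models}
    from .annotation import promoter_interval

    for gene_id in bundle.config.coupled_genes:
        iv = promoter_interval(by_id[gene_id])
        structured.append((iv.chrom, iv.start, iv.end))
    for gene_id, (rtype, _d) in bundle.config.planted_dmrs.items():
        for iv in _region_intervals(by_id[gene_id], rtype):
            structured.append((iv.chrom, iv.start, iv.end))
    out = []
    for g in bundle.gene_models:
        t = gene_territory(g)
        clean = all(
            not (c == t.chrom and s < t.end and e > t.start) for c, s, e in structured
        )
        if clean:
            out.append(g.gene_id)
    return out


def load_bundle_dir(path: str | Path):
    """Re-read a written bundle directory as (genes, metadata, coverage, counts)."""
    from .annotation import parse_annotation
    from .methcov import read_coverage

    path = Path(path)
    genes = parse_annotation(path / "annotation.gtf", "gtf")
    metadata = read_metadata(path / "metadata.tsv")
    coverage = {
        row.sample_id: read_coverage(
            path / "coverage" / f"{row.sample_id}.cov.tsv", row.sample_id
        )
        for row in metadata.itertuples()
    }
    counts = pd.read_csv(path / "counts.tsv", sep="\t", index_col="gene_id")
    return genes, metadata, coverage, counts
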