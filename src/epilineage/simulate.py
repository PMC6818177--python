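"""Synthetic genome, lineage and read-track generator with planted ground truth.

The generator emulates the statistical structure the analysis assumes, for
four neural cell types on a known lineage (NSC -> GNP -> glia, with neurons
branching directly from NSCs):

* **Expression and promoter H3K9ac** follow a two-block structure: a
  progenitor-high gene block (NSC + GNP), a differentiated-high block
  (neuron + glia), and disjoint neuron- and glia-specific sub-blocks.
  Promoter H3K9ac is positively coupled to per-cell expression.
* **Promoter and enhancer H3K27me3** carry the lineage signal: per-element
  log-levels perform independent Gaussian drifts along the tree edges
  (default standard deviations NSC->GNP 0.3, GNP->Glia 0.6, NSC->Neuron
  1.0), so expected between-cell-type Euclidean distances respect tree path
  lengths. A cell-invariant component anti-coupled to the gene's baseline
  expression makes H3K27me3 a (negative) predictor of activity without
  touching the between-cell-type geometry.
* **MNase-seq** reads come from a phased nucleosome array around each TSS
  (Gaussian peaks at -180, +120, +295, +470 bp, sd 40 bp, plus flanking
  background), with the nucleosome-depleted region [-150, +50) scaled by
  exp(-coupling x standardised expression).
* **H3K4me1** is enriched ``enhancer_fold``-fold over background inside
  planted enhancers, in the cell types where the enhancer is active.

All read counts are Poisson draws from the expected densities; reads are
emitted as 49 bp intervals. A fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    GenomeTable,
    GenomicInterval,
    ReadTrack,
    write_bed,
    write_gtf,
)

CELL_TYPES = ("NSC", "GNP", "Glia", "Neuron")
DEFAULT_TOPOLOGY = ((("NSC", "GNP"), "Glia"), "Neuron")
READ_LEN = 49
CHROM = "chr1"

# nucleosome array geometry (bp relative to the oriented TSS)
NUC_PEAK_OFFSETS = (-180, 120, 295, 470)
NUC_PEAK_SD = 40.0
NDR_WINDOW = (-150, 50)
PROFILE_FLANK = 1000

# per-element expected-read scales (reads per element at latent level 0)
NUC_PEAK_READS = 50.0
FLANK_RATE = 0.03  # MNase reads per bp in the TSS window outside the NDR
PROM_K9_BASE = 80.0
PROM_K27_BASE = 40.0
ENH_K9_BASE = 60.0
ENH_K9_SPECIFIC = 250.0  # expected reads at a class-specific enhancer in its cell
ENH_K27_BASE = 40.0

# latent-model constants
EXPR_BASE_SD = 1.6
EXPR_NOISE_SD = 0.25
BLOCK_DELTA = 1.2  # log-scale separation between high and low block states
K9_COUPLING = 0.9
K9_NOISE_SD = 0.3
K27_EXPR_COUPLING = 3.0
K27_NOISE_SD = 0.15
K27_LATENT_CAP = 3.5  # saturation of the log latent; bounds per-element reads
EXPR_LIBRARY = 1_000_000

ENHANCER_CLASS_FRACTIONS = {"shared": 0.70, "neuron_specific": 0.15, "glia_specific": 0.15}


@dataclass(frozen=True)
class LineageTree:
    """Rooted merge structure over the cell types with per-edge drift scales."""

    leaves: tuple[str, ...] = CELL_TYPES
    topology: tuple = DEFAULT_TOPOLOGY
    edge_scales: tuple[float, float, float] = (0.3, 0.6, 1.0)
    # edge order: NSC->GNP, GNP->Glia, NSC->Neuron
    star: bool = False

    def __post_init__(self) -> None:
        flat: list[str] = []

        def walk(node):
            if isinstance(node, str):
                flat.append(node)
            else:
                for child in node:
                    walk(child)

        walk(self.topology)
        if sorted(flat) != sorted(self.leaves) or len(set(flat)) != len(flat):
            raise ValueError("every leaf must appear exactly once in the topology")
        if any(s <= 0 for s in self.edge_scales):
            raise ValueError("edge_scales must be > 0")

    def drift(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n x 4 latent drifts (columns in CELL_TYPES order) along the tree.

        With ``star=True`` every non-root cell drifts independently from the
        NSC state with the first edge scale (topology carries no signal).
        """
        s1, s2, s3 = self.edge_scales
        t = np.zeros((n, 4))
        if self.star:
            for j in (1, 2, 3):
                t[:, j] = rng.normal(0.0, s1, n)
            return t
        a = rng.normal(0.0, s1, n)  # NSC -> GNP
        c = rng.normal(0.0, s2, n)  # GNP -> Glia
        e = rng.normal(0.0, s3, n)  # NSC -> Neuron
        t[:, 1] = a
        t[:, 2] = a + c
        t[:, 3] = e
        return t


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 1000
    n_enhancers: int = 300
    chrom_length: int = 6_000_000
    reads_per_track: int = 2_000_000
    # fractions: progenitor-high, differentiated-high, neuron-specific, glia-specific
    expression_blocks: tuple[float, float, float, float] = (0.25, 0.25, 0.10, 0.10)
    h3k27me3_edge_scales: tuple[float, float, float] = (0.3, 0.6, 1.0)
    ndr_depth_coupling: float = 1.0
    enhancer_fold: float = 10.0
    background_rate: float = 0.01  # reads per bp, all tracks
    star_tree: bool = False

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_enhancers", "chrom_length", "reads_per_track"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(f < 0 or f > 1 for f in self.expression_blocks):
            raise ValueError("block fractions must lie in [0, 1]")
        if sum(self.expression_blocks) > 1 + 1e-12:
            raise ValueError("block fractions must sum to <= 1")
        if self.background_rate < 0 or self.enhancer_fold < 1:
            raise ValueError("background_rate >= 0 and enhancer_fold >= 1 required")

    @property
    def tree(self) -> LineageTree:
        return LineageTree(edge_scales=self.h3k27me3_edge_scales, star=self.star_tree)


@dataclass
class GroundTruth:
    tree: LineageTree
    log_expression: pd.DataFrame  # genes x cells, latent log expression
    promoter_h3k9ac: pd.DataFrame  # genes x cells, latent log level
    promoter_h3k27me3: pd.DataFrame
    enhancer_h3k27me3: pd.DataFrame  # enhancers x cells
    gene_blocks: pd.Series  # per gene: progenitor/differentiated/neuron/glia/none
    enhancers: pd.DataFrame  # interval columns + target + class + active cells
    expected_counts: dict = field(default_factory=dict)

    def gene_sets(self) -> dict[str, list[str]]:
        """GMT-style gene sets matching the planted expression blocks."""
        out: dict[str, list[str]] = {}
        names = {
            "progenitor": "progenitor_high",
            "differentiated": "differentiated_high",
            "neuron": "neuron_specific",
            "glia": "glia_specific",
        }
        for block, set_name in names.items():
            members = list(self.gene_blocks.index[self.gene_blocks == block])
            if members:
                out[set_name] = members
        return out

    def tree_newick(self) -> str:
        def walk(node):
            if isinstance(node, str):
                return node
            return "(" + ",".join(walk(c) for c in node) + ")"

        return walk(self.tree.topology) + ";"


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: GenomeTable
    genes: list[GeneModel]
    tracks: dict[tuple[str, str], ReadTrack]  # (cell_type, assay) -> track
    expression_counts: pd.DataFrame  # genes x cells
    truth: GroundTruth

    def track(self, cell: str, assay: str) -> ReadTrack:
        return self.tracks[(cell, assay)]

    def enhancer_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in self.truth.enhancers.itertuples()
        ]

    def write(self, outdir) -> None:
        """Write genome.tsv, genes.gtf, reads/, expression_counts.tsv and truth/."""
        import os

        os.makedirs(outdir, exist_ok=True)
        self.genome.write_tsv(os.path.join(outdir, "genome.tsv"))
        write_gtf(self.genes, os.path.join(outdir, "genes.gtf"))
        reads_dir = os.path.join(outdir, "reads")
        os.makedirs(reads_dir, exist_ok=True)
        for (cell, assay), track in self.tracks.items():
            track.to_bed(os.path.join(reads_dir, f"{cell}_{assay}.bed"))
        self.expression_counts.to_csv(
            os.path.join(outdir, "expression_counts.tsv"), sep="\t",
            index_label="gene_id",
        )
        truth_dir = os.path.join(outdir, "truth")
        os.makedirs(truth_dir, exist_ok=True)
        for name, df in (
            ("latent_log_expression", self.truth.log_expression),
            ("latent_promoter_h3k9ac", self.truth.promoter_h3k9ac),
            ("latent_promoter_h3k27me3", self.truth.promoter_h3k27me3),
            ("latent_enhancer_h3k27me3", self.truth.enhancer_h3k27me3),
        ):
            df.to_csv(os.path.join(truth_dir, f"{name}.tsv"), sep="\t",
                      index_label="id", float_format="%.10g")
        self.truth.gene_blocks.to_csv(
            os.path.join(truth_dir, "gene_blocks.tsv"), sep="\t",
            index_label="gene_id", header=["block"],
        )
        enh = self.truth.enhancers
        write_bed(
            [GenomicInterval(r.chrom, r.start, r.end) for r in enh.itertuples()],
            os.path.join(truth_dir, "enhancers.bed"),
            names=list(enh["target"]),
            scores=[0.0] * len(enh),
        )
        enh.to_csv(os.path.join(truth_dir, "enhancers.tsv"), sep="\t",
                   index_label="enhancer_id")
        with open(os.path.join(truth_dir, "tree.nwk"), "w") as fh:
            fh.write(self.truth.tree_newick() + "\n")
        from .enhancers import write_gmt

        write_gmt(self.truth.gene_sets(), os.path.join(truth_dir, "gene_sets.gmt"))


# ---------------------------------------------------------------------------
# Generator internals
# ---------------------------------------------------------------------------

def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    spacing = cfg.chrom_length // cfg.n_genes
    if spacing < 4000:
        raise ValueError(
            f"chromosome too short: {cfg.n_genes} genes need >= 4 kb spacing, "
            f"got {spacing} bp"
        )
    width = len(str(cfg.n_genes - 1))
    genes: list[GeneModel] = []
    # constant TSS offset: leaves [tss-3400, tss-1100] upstream of every gene
    # free of promoters, so planted enhancers stay pairwise disjoint
    offset = 2750
    strands = rng.choice(np.array(["+", "-"]), cfg.n_genes)
    lengths = rng.integers(500, 3001, cfg.n_genes)
    for i in range(cfg.n_genes):
        tss = int(i * spacing + offset)
        L = int(lengths[i])
        if strands[i] == "+":
            iv = GenomicInterval(CHROM, tss, min(tss + L, cfg.chrom_length), "+")
        else:
            start = max(tss - L + 1, 0)
            iv = GenomicInterval(CHROM, start, tss + 1, "-")
        genes.append(
            GeneModel.from_span(f"g{i:0{width}d}", iv, length_kb=iv.width / 1000.0)
        )
    return genes


def _assign_blocks(cfg: SimulationConfig) -> tuple[pd.Series, np.ndarray]:
    """Block label per gene and the n x 4 log-effect matrix."""
    n = cfg.n_genes
    f_prog, f_diff, f_neu, f_gli = cfg.expression_blocks
    counts = [int(round(f * n)) for f in (f_prog, f_diff, f_neu, f_gli)]
    labels = (
        ["progenitor"] * counts[0]
        + ["differentiated"] * counts[1]
        + ["neuron"] * counts[2]
        + ["glia"] * counts[3]
    )
    labels += ["none"] * (n - len(labels))
    labels = labels[:n]
    half = BLOCK_DELTA / 2.0
    effect = {
        "progenitor": (+half, +half, -half, -half),
        "differentiated": (-half, -half, +half, +half),
        "neuron": (-half, -half, -half, +half),
        "glia": (-half, -half, +half, -half),
        "none": (0.0, 0.0, 0.0, 0.0),
    }
    B = np.array([effect[l] for l in labels])
    return pd.Series(labels, name="block"), B


def _place_enhancers(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genes: list[GeneModel],
    blocks: pd.Series,
) -> pd.DataFrame:
    """Plant enhancers 1.1-3.4 kb upstream (in genomic coordinates) of their
    target TSS: with >= 4 kb gene spacing this region never touches a promoter
    or another gene's enhancer, keeping planted enhancers pairwise disjoint."""
    n_enh = cfg.n_enhancers
    n_neu = int(round(ENHANCER_CLASS_FRACTIONS["neuron_specific"] * n_enh))
    n_gli = int(round(ENHANCER_CLASS_FRACTIONS["glia_specific"] * n_enh))
    n_shared = n_enh - n_neu - n_gli
    idx = np.arange(len(genes))
    eligible = idx[1:]  # gene 0 has no upstream room
    lab = blocks.values
    neuron_pool = [i for i in eligible if lab[i] == "neuron"]
    glia_pool = [i for i in eligible if lab[i] == "glia"]
    other_pool = [i for i in eligible if lab[i] not in ("neuron", "glia")]

    def pick(pool: list[int], k: int) -> np.ndarray:
        if k > len(pool):
            raise ValueError(
                f"cannot place {k} class-specific enhancers on {len(pool)} genes"
            )
        return rng.choice(np.array(pool), size=k, replace=False)

    t_neu = pick(neuron_pool, n_neu)
    t_gli = pick(glia_pool, n_gli)
    t_shared = pick(other_pool, n_shared)
    spacing = cfg.chrom_length // cfg.n_genes
    reach_max = min(3400, spacing - 1050)  # keep clear of the upstream promoter
    w_max = min(1200, reach_max - 1300)
    w_min = min(700, w_max)
    rows = []
    spec = [("neuron_specific", t_neu), ("glia_specific", t_gli), ("shared", t_shared)]
    for cls, targets in spec:
        widths = rng.integers(w_min, w_max + 1, len(targets))
        for t, w in zip(targets.tolist(), widths.tolist()):
            d = int(rng.integers(1300, reach_max - w + 1))
            tss = genes[t].tss
            end = tss - d
            start = end - int(w)
            if start < 0:
                continue
            active = {
                "shared": "NSC,GNP,Glia,Neuron",
                "neuron_specific": "Neuron",
                "glia_specific": "Glia",
            }[cls]
            rows.append((CHROM, start, end, genes[t].gene_id, cls, active))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "target", "enh_class", "active_cells"]
    ).sort_values(["start"]).reset_index(drop=True)
    df.index = [f"e{i:04d}" for i in range(len(df))]
    return df


def _emit_region_reads(
    rng: np.random.Generator,
    starts: np.ndarray,
    ends: np.ndarray,
    expected: np.ndarray,
) -> np.ndarray:
    """Poisson read midpoints placed uniformly within regions."""
    k = rng.poisson(expected)
    reps = np.repeat(np.arange(len(starts)), k)
    if reps.size == 0:
        return np.empty(0, dtype=np.int64)
    u = rng.random(reps.size)
    w = (ends - starts)[reps]
    return (starts[reps] + np.floor(u * w)).astype(np.int64)


def _mids_to_reads(
    mids: np.ndarray, chrom_length: int
) -> tuple[np.ndarray, np.ndarray]:
    starts = np.clip(mids - READ_LEN // 2, 0, chrom_length - READ_LEN)
    return starts, starts + READ_LEN


def _background_mids(
    rng: np.random.Generator, rate: float, chrom_length: int
) -> np.ndarray:
    n = rng.poisson(rate * chrom_length)
    return rng.integers(0, chrom_length, n, dtype=np.int64)


def _track_from_mids(
    cell: str,
    assay: str,
    mids_parts: list[np.ndarray],
    cfg: SimulationConfig,
    genome: GenomeTable,
) -> ReadTrack:
    mids = np.concatenate(mids_parts) if mids_parts else np.empty(0, dtype=np.int64)
    mids.sort()
    starts, ends = _mids_to_reads(mids, cfg.chrom_length)
    return ReadTrack(
        cell, assay, {CHROM: (starts, ends)},
        total_mapped=cfg.reads_per_track, genome=genome,
    )


def _mnase_mids(
    rng: np.random.Generator,
    genes: list[GeneModel],
    ndr_scale: np.ndarray,
    cfg: SimulationConfig,
) -> np.ndarray:
    """Phased-array MNase midpoints for one cell type.

    ``ndr_scale`` is exp(-coupling x standardised expression) per gene.
    """
    n = len(genes)
    tss = np.array([g.tss for g in genes], dtype=np.int64)
    sign = np.array([1 if g.interval.strand == "+" else -1 for g in genes])
    parts = []
    # nucleosome peaks
    for mu in NUC_PEAK_OFFSETS:
        k = rng.poisson(NUC_PEAK_READS, n)
        reps = np.repeat(np.arange(n), k)
        off = rng.normal(mu, NUC_PEAK_SD, reps.size)
        parts.append(tss[reps] + (sign[reps] * off).astype(np.int64))
    # flanking background in the TSS window outside the NDR
    lo, hi = NDR_WINDOW
    for seg_lo, seg_hi in ((-PROFILE_FLANK, lo), (hi, PROFILE_FLANK)):
        expect = FLANK_RATE * (seg_hi - seg_lo)
        k = rng.poisson(expect, n)
        reps = np.repeat(np.arange(n), k)
        off = rng.uniform(seg_lo, seg_hi, reps.size)
        parts.append(tss[reps] + (sign[reps] * off).astype(np.int64))
    # NDR floor, scaled by expression
    expect = FLANK_RATE * (hi - lo) * ndr_scale
    k = rng.poisson(expect)
    reps = np.repeat(np.arange(n), k)
    off = rng.uniform(lo, hi, reps.size)
    parts.append(tss[reps] + (sign[reps] * off).astype(np.int64))
    mids = np.concatenate(parts)
    return np.clip(mids, 0, cfg.chrom_length - 1)


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Generate the toy genome, lineage-structured latents, all 16 read
    tracks, the expression count table and the planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    genome = GenomeTable({CHROM: cfg.chrom_length})
    genes = _place_genes(cfg, rng)
    gene_ids = [g.gene_id for g in genes]
    n = cfg.n_genes
    tree = cfg.tree

    blocks, B = _assign_blocks(cfg)
    blocks.index = gene_ids

    # latent expression
    zbase = rng.normal(0.0, EXPR_BASE_SD, n)
    log_expr = zbase[:, None] + B + rng.normal(0.0, EXPR_NOISE_SD, (n, 4))
    lam = np.exp(log_expr)
    lam = lam / lam.sum(axis=0, keepdims=True) * EXPR_LIBRARY
    expr_counts = rng.poisson(lam)
    expr_z = (log_expr - log_expr.mean(axis=0)) / log_expr.std(axis=0)
    zbase_std = (zbase - zbase.mean()) / zbase.std()

    # latent promoter marks
    l9 = K9_COUPLING * expr_z + rng.normal(0.0, K9_NOISE_SD, (n, 4))
    drift = tree.drift(rng, n)
    l27 = np.minimum(
        -K27_EXPR_COUPLING * zbase_std[:, None]
        + drift
        + rng.normal(0.0, K27_NOISE_SD, (n, 4)),
        K27_LATENT_CAP,
    )

    # enhancers and their latents
    enh = _place_enhancers(cfg, rng, genes, blocks)
    m = len(enh)
    target_idx = np.array([gene_ids.index(t) for t in enh["target"]])
    e9 = K9_COUPLING * expr_z[target_idx] + rng.normal(0.0, K9_NOISE_SD, (m, 4))
    e_drift = tree.drift(rng, m)
    e27 = np.minimum(
        -K27_EXPR_COUPLING * zbase_std[target_idx][:, None]
        + e_drift
        + rng.normal(0.0, K27_NOISE_SD, (m, 4)),
        K27_LATENT_CAP,
    )
    active = np.zeros((m, 4), dtype=bool)
    for j, cell in enumerate(CELL_TYPES):
        active[:, j] = [cell in a.split(",") for a in enh["active_cells"]]

    prom_starts = np.array([max(g.tss - PROFILE_FLANK, 0) for g in genes])
    prom_ends = np.array(
        [min(g.tss + PROFILE_FLANK, cfg.chrom_length) for g in genes]
    )
    enh_starts = enh["start"].to_numpy()
    enh_ends = enh["end"].to_numpy()

    tracks: dict[tuple[str, str], ReadTrack] = {}
    expected_counts: dict = {}
    for j, cell in enumerate(CELL_TYPES):
        # MNase
        ndr_scale = np.exp(-cfg.ndr_depth_coupling * expr_z[:, j])
        mn_mids = _mnase_mids(rng, genes, ndr_scale, cfg)
        bg = _background_mids(rng, cfg.background_rate, cfg.chrom_length)
        tracks[(cell, "mnase")] = _track_from_mids(
            cell, "mnase", [mn_mids, bg], cfg, genome
        )
        # H3K9ac: promoters + enhancers + background
        exp_p9 = PROM_K9_BASE * np.exp(l9[:, j])
        exp_e9 = ENH_K9_BASE * np.exp(e9[:, j])
        # class-specific enhancers are strongly acetylated in their own cell
        spec_here = (
            (enh["enh_class"] == "neuron_specific").to_numpy() & (cell == "Neuron")
        ) | ((enh["enh_class"] == "glia_specific").to_numpy() & (cell == "Glia"))
        exp_e9 = np.where(spec_here, ENH_K9_SPECIFIC, exp_e9)
        mids9 = [
            _emit_region_reads(rng, prom_starts, prom_ends, exp_p9),
            _emit_region_reads(rng, enh_starts, enh_ends, exp_e9),
            _background_mids(rng, cfg.background_rate, cfg.chrom_length),
        ]
        tracks[(cell, "h3k9ac")] = _track_from_mids(cell, "h3k9ac", mids9, cfg, genome)
        # H3K27me3: promoters + enhancers + background
        exp_p27 = PROM_K27_BASE * np.exp(l27[:, j])
        exp_e27 = ENH_K27_BASE * np.exp(e27[:, j])
        mids27 = [
            _emit_region_reads(rng, prom_starts, prom_ends, exp_p27),
            _emit_region_reads(rng, enh_starts, enh_ends, exp_e27),
            _background_mids(rng, cfg.background_rate, cfg.chrom_length),
        ]
        tracks[(cell, "h3k27me3")] = _track_from_mids(
            cell, "h3k27me3", mids27, cfg, genome
        )
        # H3K4me1: planted enrichment where active + background
        exp_k4 = (
            (cfg.enhancer_fold - 1.0)
            * cfg.background_rate
            * (enh_ends - enh_starts)
            * active[:, j]
        )
        mids4 = [
            _emit_region_reads(rng, enh_starts, enh_ends, exp_k4),
            _background_mids(rng, cfg.background_rate, cfg.chrom_length),
        ]
        tracks[(cell, "h3k4me1")] = _track_from_mids(
            cell, "h3k4me1", mids4, cfg, genome
        )
        expected_counts[cell] = {
            "promoter_h3k9ac": exp_p9,
            "promoter_h3k27me3": exp_p27,
            "enhancer_h3k9ac": exp_e9,
            "enhancer_h3k27me3": exp_e27,
            "enhancer_h3k4me1": exp_k4,
        }

    cells = list(CELL_TYPES)
    truth = GroundTruth(
        tree=tree,
        log_expression=pd.DataFrame(log_expr, index=gene_ids, columns=cells),
        promoter_h3k9ac=pd.DataFrame(l9, index=gene_ids, columns=cells),
        promoter_h3k27me3=pd.DataFrame(l27, index=gene_ids, columns=cells),
        enhancer_h3k27me3=pd.DataFrame(e27, index=list(enh.index), columns=cells),
        gene_blocks=blocks,
        enhancers=enh,
        expected_counts=expected_counts,
    )
    expression_counts = pd.DataFrame(expr_counts, index=gene_ids, columns=cells)
    return SimulationResult(cfg, genome, genes, tracks, expression_counts, truth)


def simulate_state_pair(
    seed: int,
    chrom_length: int = 2_000_000,
    bin_size: int = 200,
    switch_fraction: float = 0.3,
    marked_reads_per_bin: float = 40.0,
    background_rate: float = 0.01,
    frac_k9: float = 0.15,
    frac_k27: float = 0.10,
    frac_both: float = 0.05,
) -> tuple[dict, dict, np.ndarray, np.ndarray]:
    """Two cell types with planted chromatin-state maps and emitted HM reads.

    Cell A gets a random state per bin (fractions of H3K9ac+, H3K27me3+ and
    both as configured); cell B inherits A's states except that
    ``switch_fraction`` of A's H3K9ac+ bins turn unmarked. Returns
    ``(tracks_a, tracks_b, codes_a, codes_b)`` where each tracks dict maps
    assay -> ReadTrack and codes use the state encoding of
    :mod:`epilineage.chromstate` (0 unmarked, 1 H3K9ac+, 2 H3K27me3+, 3 both).
    """
    rng = np.random.default_rng(seed)
    genome = GenomeTable({CHROM: chrom_length})
    n_bins = -(-chrom_length // bin_size)
    u = rng.random(n_bins)
    codes_a = np.zeros(n_bins, dtype=np.int8)
    codes_a[u < frac_k9] = 1
    codes_a[(u >= frac_k9) & (u < frac_k9 + frac_k27)] = 2
    codes_a[(u >= frac_k9 + frac_k27) & (u < frac_k9 + frac_k27 + frac_both)] = 3
    codes_b = codes_a.copy()
    k9_bins = np.flatnonzero(codes_a == 1)
    n_switch = int(round(switch_fraction * len(k9_bins)))
    switched = rng.choice(k9_bins, size=n_switch, replace=False)
    codes_b[switched] = 0

    starts = np.arange(n_bins, dtype=np.int64) * bin_size
    ends = np.minimum(starts + bin_size, chrom_length)

    def emit(codes: np.ndarray, mark_bit: int, cell: str, assay: str) -> ReadTrack:
        has_mark = (codes == mark_bit) | (codes == 3)
        expected = np.where(has_mark, marked_reads_per_bin, 0.0)
        mids = [
            _emit_region_reads(rng, starts, ends, expected),
            _background_mids(rng, background_rate, chrom_length),
        ]
        cfg = SimulationConfig(seed=seed, chrom_length=chrom_length)
        return _track_from_mids(cell, assay, mids, cfg, genome)

    tracks_a = {
        "h3k9ac": emit(codes_a, 1, "A", "h3k9ac"),
        "h3k27me3": emit(codes_a, 2, "A", "h3k27me3"),
    }
    tracks_b = {
        "h3k9ac": emit(codes_b, 1, "B", "h3k9ac"),
        "h3k27me3": emit(codes_b, 2, "B", "h3k27me3"),
    }
    return tracks_a, tracks_b, codes_a, codes_b


def shuffle_labels(expression: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Uniformly permute the gene-to-expression assignment (negative control)."""
    if len(expression) == 0:
        raise ValueError("empty expression table")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(expression))
    return pd.DataFrame(
        expression.values[perm], index=expression.index, columns=expression.columns
    )
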