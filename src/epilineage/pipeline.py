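"""End-to-end orchestration: configuration, staged execution, reproducibility report.

Stages run in dependency order (simulate -> expression -> nucleosome ->
states -> enhancers -> signal -> roc -> cluster -> report); any subset can
be requested, and a stage whose upstream outputs are missing fails with an
error naming the stage that should have produced them. All stage parameters
default to the study's stated values (10 bp TSS bins, +/-1 kb promoters,
[-150,+50) NDR, 200 bp state bins, 1 kb enhancer windows at FDR 0.001,
top/bottom-1500 ROC labels, DEG FDR 0.05).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import chromstate, clustering, enhancers, expression, nucleosome, regsignal, roc
from .core import (
    GenomeTable,
    GenomicInterval,
    ReadTrack,
    SignalMatrix,
    read_bed,
    read_gtf_genes,
    read_matrix,
)
from .simulate import CELL_TYPES, LineageTree, SimulationConfig, simulate

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "expression",
    "nucleosome",
    "states",
    "enhancers",
    "signal",
    "roc",
    "cluster",
    "report",
)

HM_MARKS = ("h3k9ac", "h3k27me3")

# lineage edges reported as alluvial flows
FLOW_PAIRS = (("NSC", "GNP"), ("GNP", "Glia"), ("NSC", "Neuron"))


class PipelineError(RuntimeError):
    pass


class SimulateSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_genes: int = Field(1000, gt=0)
    n_enhancers: int = Field(300, gt=0)
    chrom_length: int = Field(6_000_000, gt=0)
    reads_per_track: int = Field(2_000_000, gt=0)
    expression_blocks: tuple[float, float, float, float] = (0.25, 0.25, 0.10, 0.10)
    h3k27me3_edge_scales: tuple[float, float, float] = (0.3, 0.6, 1.0)
    ndr_depth_coupling: float = 1.0
    enhancer_fold: float = Field(10.0, ge=1.0)
    background_rate: float = Field(0.01, ge=0.0)
    star_tree: bool = False

    def to_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(seed=seed, **self.model_dump())


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    outdir: str = "epilineage_out"
    simulate: SimulateSettings = SimulateSettings()
    deg_fdr: float = Field(0.05, gt=0, lt=1)
    deg_pseudocount: float = Field(1.0, gt=0)
    promoter_flank: int = Field(1000, gt=0)
    state_bin_bp: int = Field(200, gt=0)
    state_p_threshold: float = Field(1.0e-4, gt=0, lt=1)
    smooth_states: bool = False
    enhancer_window: int = Field(1000, gt=0)
    enhancer_step: int = Field(100, gt=0)
    enhancer_fdr: float = Field(0.001, gt=0, lt=1)
    roc_k: int = Field(1500, gt=0)
    linkage: Literal["complete", "average", "ward"] = "complete"

    @model_validator(mode="after")
    def _cross_field(self):
        if self.enhancer_window < self.enhancer_step:
            raise ValueError(
                f"enhancer_window ({self.enhancer_window}) must be >= "
                f"enhancer_step ({self.enhancer_step})"
            )
        return self


def validate_config(path: str | None = None, **overrides) -> PipelineConfig:
    """Load and validate a YAML (.yaml/.yml) or TOML (.toml) config; unknown
    keys and bad values are collected into one error. With no path, defaults
    (plus overrides) apply."""
    data: dict = {}
    if path is not None:
        if str(path).endswith(".toml"):
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise PipelineError(f"{path}: config must be a mapping")
    data.update(overrides)
    try:
        cfg = PipelineConfig(**data)
    except ValidationError as exc:
        raise PipelineError(str(exc)) from exc
    logger.info("normalized config: %s", cfg.model_dump())
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineState:
    """In-memory intermediates plus file-based handoff between stages."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.outdir = cfg.outdir
        self.sim = None
        self.genome: GenomeTable | None = None
        self.genes = None
        self.tracks: dict[tuple[str, str], ReadTrack] = {}
        self.counts: dict[str, int] = {}

    # -- loaders -----------------------------------------------------------
    def path(self, *parts) -> str:
        return os.path.join(self.outdir, *parts)

    def _require(self, relpath: str, producer: str) -> str:
        p = self.path(relpath)
        if not os.path.exists(p):
            raise PipelineError(
                f"missing {relpath}; run the '{producer}' stage first"
            )
        return p

    def get_genome(self) -> GenomeTable:
        if self.genome is None:
            self.genome = GenomeTable.read_tsv(self._require("genome.tsv", "simulate"))
        return self.genome

    def get_genes(self):
        if self.genes is None:
            self.genes = sorted(
                read_gtf_genes(self._require("genes.gtf", "simulate")),
                key=lambda g: g.gene_id,
            )
        return self.genes

    def get_track(self, cell: str, assay: str) -> ReadTrack:
        key = (cell, assay)
        if key not in self.tracks:
            if self.sim is not None:
                self.tracks[key] = self.sim.tracks[key]
            else:
                p = self._require(f"reads/{cell}_{assay}.bed", "simulate")
                total = self.cfg.simulate.reads_per_track
                self.tracks[key] = ReadTrack.from_bed(
                    p, cell, assay, total_mapped=total, genome=self.get_genome()
                )
        return self.tracks[key]

    def get_expression_counts(self) -> pd.DataFrame:
        if self.sim is not None:
            return self.sim.expression_counts
        p = self._require("expression_counts.tsv", "simulate")
        return pd.read_csv(p, sep="\t", index_col=0)

    def get_expression_table(self) -> expression.ExpressionTable:
        counts = self.get_expression_counts()
        genes = self.get_genes()
        lengths = pd.Series({g.gene_id: g.length_kb for g in genes})
        return expression.ExpressionTable.from_counts(counts, lengths)

    def get_matrix(self, relpath: str, producer: str, units="RPM") -> SignalMatrix:
        return read_matrix(self._require(relpath, producer), units=units)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(state: PipelineState) -> None:
    cfg = state.cfg
    sim = simulate(cfg.simulate.to_config(cfg.seed))
    sim.write(state.outdir)
    state.sim = sim
    state.genome = sim.genome
    state.genes = sim.genes
    state.tracks.update(sim.tracks)
    state.counts["genes"] = len(sim.genes)
    state.counts["planted_enhancers"] = len(sim.truth.enhancers)


def _stage_expression(state: PipelineState) -> None:
    cfg = state.cfg
    table = state.get_expression_table()
    os.makedirs(state.path("expression"), exist_ok=True)
    table.rpkm_values.to_csv(
        state.path("expression", "rpkm.tsv"), sep="\t", index_label="gene_id",
        float_format="%.10g",
    )
    results = expression.call_degs_all_pairs(
        table, fdr=cfg.deg_fdr, pseudo=cfg.deg_pseudocount
    )
    expression.write_deg_report(results, state.path("expression", "deg_results.tsv"))
    matrix = expression.deg_union_matrix(table, results)
    matrix.write_tsv(state.path("expression", "deg_rpkm_matrix.tsv"))
    state.counts["deg_union"] = len(matrix.row_ids)


def _stage_nucleosome(state: PipelineState) -> None:
    genes = state.get_genes()
    genome = state.get_genome()
    os.makedirs(state.path("nucleosome"), exist_ok=True)
    tracks = [state.get_track(c, "mnase") for c in CELL_TYPES]
    for track in tracks:
        prof = nucleosome.tss_profile(track, genes, genome)
        prof.to_matrix().write_tsv(
            state.path("nucleosome", f"profile_{track.cell_type}.tsv")
        )
    ndr = nucleosome.ndr_matrix(tracks, genes)
    ndr.write_tsv(state.path("nucleosome", "ndr_rpm.tsv"))
    for cell in CELL_TYPES:
        order = nucleosome.order_genes_by_ndr(ndr, cell)
        with open(state.path("nucleosome", f"order_{cell}.txt"), "w") as fh:
            fh.write("\n".join(order) + "\n")


def _stage_states(state: PipelineState) -> None:
    cfg = state.cfg
    genome = state.get_genome()
    os.makedirs(state.path("states"), exist_ok=True)
    maps = {}
    for cell in CELL_TYPES:
        smap = chromstate.state_map_from_tracks(
            state.get_track(cell, "h3k9ac"),
            state.get_track(cell, "h3k27me3"),
            genome,
            bin_size=cfg.state_bin_bp,
            p_threshold=cfg.state_p_threshold,
            smooth=cfg.smooth_states,
        )
        maps[cell] = smap
        smap.write_tsv(state.path("states", f"states_{cell}.tsv"))
    fractions = pd.DataFrame({c: maps[c].fractions() for c in CELL_TYPES})
    fractions.to_csv(state.path("states", "fractions.tsv"), sep="\t",
                     index_label="state")
    for a, b in FLOW_PAIRS:
        flow = chromstate.state_flow(maps[a], maps[b])
        flow.write_tsv(state.path("states", f"flow_{a}_to_{b}.tsv"))
    state.counts["state_bins"] = len(next(iter(maps.values())).codes)


def _stage_enhancers(state: PipelineState) -> None:
    cfg = state.cfg
    genome = state.get_genome()
    genes = state.get_genes()
    promoters = regsignal.promoter_regions(genes, genome, cfg.promoter_flank)
    os.makedirs(state.path("enhancers"), exist_ok=True)
    sets = []
    for cell in CELL_TYPES:
        es = enhancers.call_enhancers(
            state.get_track(cell, "h3k4me1"),
            genome,
            promoters,
            window=cfg.enhancer_window,
            step=cfg.enhancer_step,
            fdr=cfg.enhancer_fdr,
        )
        es.write_bed(state.path("enhancers", f"enhancers_{cell}.bed"))
        sets.append(es)
        state.counts[f"enhancers_{cell}"] = len(es)
    consensus = enhancers.consensus_enhancers(sets)
    with open(state.path("enhancers", "consensus.bed"), "w") as fh:
        for iv in consensus:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    targets = enhancers.assign_targets(consensus, genes)
    targets.table.to_csv(state.path("enhancers", "targets.tsv"), sep="\t")
    state.counts["consensus_enhancers"] = len(consensus)
    # cell-type-specific H3K9ac+ enhancers (neuron vs glia), via state maps
    try:
        maps = {
            c: _load_state_map(state, c) for c in ("Neuron", "Glia")
        }
    except PipelineError:
        logger.info("state maps unavailable; skipping specific-enhancer split")
        return
    neuron_idx = CELL_TYPES.index("Neuron")
    pos = {
        c: enhancers.h3k9ac_positive(s, maps[c])
        for c, s in (("Neuron", sets[neuron_idx]), ("Glia", sets[CELL_TYPES.index("Glia")]))
    }
    split = enhancers.specific_h3k9ac_enhancers(
        sets[neuron_idx], pos["Neuron"],
        sets[CELL_TYPES.index("Glia")], pos["Glia"],
    )
    for key, label in (("a_specific", "neuron_specific"),
                       ("b_specific", "glia_specific"), ("shared", "shared")):
        with open(state.path("enhancers", f"h3k9ac_{label}.bed"), "w") as fh:
            for iv in split[key]:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        state.counts[f"h3k9ac_{label}"] = len(split[key])
    # gene-set enrichment of specific-enhancer target genes, when sets exist
    gmt_path = state.path("truth", "gene_sets.gmt")
    if os.path.exists(gmt_path):
        gene_sets = enhancers.read_gmt(gmt_path)
        universe = [g.gene_id for g in genes]
        for label in ("neuron_specific", "glia_specific"):
            ivs = split["a_specific" if label == "neuron_specific" else "b_specific"]
            ta = enhancers.assign_targets(ivs, genes)
            query = sorted(set(ta.table.loc[ta.table["assigned"], "target"]))
            if query:
                enr = enhancers.gene_set_enrichment(query, gene_sets, universe)
                enr.to_csv(
                    state.path("enhancers", f"enrichment_{label}.tsv"),
                    sep="\t", index=False,
                )


def _load_state_map(state: PipelineState, cell: str) -> chromstate.ChromatinStateMap:
    p = state._require(f"states/states_{cell}.tsv", "states")
    df = pd.read_csv(p, sep="\t")
    label_to_code = {"unmarked": 0, "H3K9ac+": 1, "H3K27me3+": 2, "both": 3}
    codes = df["state"].map(label_to_code).to_numpy(dtype=np.int8)
    return chromstate.ChromatinStateMap(
        cell, state.get_genome(), state.cfg.state_bin_bp, codes
    )


def _stage_signal(state: PipelineState) -> None:
    cfg = state.cfg
    genes = state.get_genes()
    genome = state.get_genome()
    promoters = regsignal.promoter_regions(genes, genome, cfg.promoter_flank)
    gene_ids = [g.gene_id for g in genes]
    consensus = [
        GenomicInterval(iv.chrom, iv.start, iv.end)
        for iv in read_bed(state._require("enhancers/consensus.bed", "enhancers"))
    ]
    os.makedirs(state.path("signal"), exist_ok=True)
    for assay in HM_MARKS:
        tracks = [state.get_track(c, assay) for c in CELL_TYPES]
        pm = regsignal.signal_matrix(tracks, promoters, row_ids=gene_ids)
        pm.write_tsv(state.path("signal", f"promoter_{assay}.tsv"))
        em = regsignal.signal_matrix(tracks, consensus)
        em.write_tsv(state.path("signal", f"enhancer_{assay}.tsv"))


def _stage_roc(state: PipelineState) -> None:
    cfg = state.cfg
    os.makedirs(state.path("roc"), exist_ok=True)
    rpkm = pd.read_csv(
        state._require("expression/rpkm.tsv", "expression"), sep="\t", index_col=0
    )
    prom = {
        a: state.get_matrix(f"signal/promoter_{a}.tsv", "signal") for a in HM_MARKS
    }
    enh = {
        a: state.get_matrix(f"signal/enhancer_{a}.tsv", "signal") for a in HM_MARKS
    }
    targets_df = pd.read_csv(
        state._require("enhancers/targets.tsv", "enhancers"), sep="\t", index_col=0
    )
    targets = enhancers.TargetAssignment(targets_df)
    n_genes = len(rpkm)
    k = cfg.roc_k
    if k >= n_genes:
        k = n_genes // 4
        logger.warning(
            "roc_k=%d >= %d genes; using k=%d", cfg.roc_k, n_genes, k
        )
    table = roc.roc_suite(prom, rpkm, k=k, enhancer_matrices=enh, targets=targets)
    table.to_csv(state.path("roc", "auc_summary.tsv"), sep="\t", index=False)
    for (mark, element, cell), curve in table.attrs.get("curves", {}).items():
        curve.points_frame().to_csv(
            state.path("roc", f"roc_{mark}_{element}_{cell}.tsv"),
            sep="\t", index=False,
        )


CLUSTER_MATRICES = (
    ("expression_deg", "expression/deg_rpkm_matrix.tsv", "expression"),
    ("ndr", "nucleosome/ndr_rpm.tsv", "nucleosome"),
    ("promoter_h3k9ac", "signal/promoter_h3k9ac.tsv", "signal"),
    ("promoter_h3k27me3", "signal/promoter_h3k27me3.tsv", "signal"),
    ("enhancer_h3k9ac", "signal/enhancer_h3k9ac.tsv", "signal"),
    ("enhancer_h3k27me3", "signal/enhancer_h3k27me3.tsv", "signal"),
)


def _stage_cluster(state: PipelineState) -> None:
    cfg = state.cfg
    os.makedirs(state.path("clustering"), exist_ok=True)
    reference = LineageTree()
    rows = []
    for name, relpath, producer in CLUSTER_MATRICES:
        matrix = state.get_matrix(relpath, producer)
        dend = clustering.hcluster_cells(
            clustering.zscore_rows(matrix), method=cfg.linkage
        )
        comp = clustering.compare_topology(dend, reference)
        with open(state.path("clustering", f"dendrogram_{name}.nwk"), "w") as fh:
            fh.write(dend.newick() + "\n")
        rows.append(
            {
                "matrix": name,
                "newick": dend.newick(),
                "nested_order_match": comp.nested_order_match,
                "progenitor_split": clustering.has_bipartition(
                    dend, {"NSC", "GNP"}
                ),
                "unresolved": comp.unresolved,
            }
        )
    pd.DataFrame(rows).to_csv(
        state.path("clustering", "topology_report.tsv"), sep="\t", index=False
    )


def _stage_report(state: PipelineState) -> None:
    cfg = state.cfg
    artifacts: dict[str, str] = {}
    for root, _, files in os.walk(state.outdir):
        for f in sorted(files):
            if f == "report.json":
                continue
            p = os.path.join(root, f)
            rel = os.path.relpath(p, state.outdir)
            artifacts[rel] = _sha256(p)
    report = {
        "version": 1,
        "config": cfg.model_dump(),
        "counts": state.counts,
        "artifacts": artifacts,
    }
    auc_path = state.path("roc", "auc_summary.tsv")
    if os.path.exists(auc_path):
        report["auc"] = pd.read_csv(auc_path, sep="\t").to_dict(orient="records")
    topo_path = state.path("clustering", "topology_report.tsv")
    if os.path.exists(topo_path):
        report["topology"] = pd.read_csv(topo_path, sep="\t").to_dict(orient="records")
    with open(state.path("report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "expression": _stage_expression,
    "nucleosome": _stage_nucleosome,
    "states": _stage_states,
    "enhancers": _stage_enhancers,
    "signal": _stage_signal,
    "roc": _stage_roc,
    "cluster": _stage_cluster,
    "report": _stage_report,
}


def evaluate_simulation(seed: int, roc_k: int = 250) -> dict:
    """Run the in-memory analysis chain on one default simulation and report
    the lineage/ROC outcomes used for calibration studies.

    Returns per-matrix topology flags (nested merge order, progenitor split),
    per-mark promoter AUCs, and planted-enhancer recovery, all computed from
    freshly simulated reads.
    """
    from . import expression as expr_mod
    from . import nucleosome as nuc_mod
    from . import roc as roc_mod
    from .clustering import compare_topology, has_bipartition, hcluster_cells, zscore_rows
    from .simulate import SimulationConfig, simulate

    sim = simulate(SimulationConfig(seed=seed))
    genes, genome = sim.genes, sim.genome
    gene_ids = [g.gene_id for g in genes]
    promoters = regsignal.promoter_regions(genes, genome)
    reference = LineageTree()

    def topo(matrix):
        dend = hcluster_cells(zscore_rows(matrix))
        comp = compare_topology(dend, reference)
        return {
            "nested": comp.nested_order_match,
            "progenitor_split": has_bipartition(dend, {"NSC", "GNP"}),
        }

    out: dict = {"seed": seed}
    k27_tracks = [sim.track(c, "h3k27me3") for c in CELL_TYPES]
    k9_tracks = [sim.track(c, "h3k9ac") for c in CELL_TYPES]
    k27_prom = regsignal.signal_matrix(k27_tracks, promoters, row_ids=gene_ids)
    k9_prom = regsignal.signal_matrix(k9_tracks, promoters, row_ids=gene_ids)
    out["promoter_h3k27me3"] = topo(k27_prom)
    out["promoter_h3k9ac"] = topo(k9_prom)

    sets = [
        enhancers.call_enhancers(sim.track(c, "h3k4me1"), genome, promoters)
        for c in CELL_TYPES
    ]
    consensus = enhancers.consensus_enhancers(sets)
    out["enhancer_h3k27me3"] = topo(
        regsignal.signal_matrix(k27_tracks, consensus)
    )

    lengths = pd.Series({g.gene_id: g.length_kb for g in genes})
    table = expr_mod.ExpressionTable.from_counts(sim.expression_counts, lengths)
    degs = expr_mod.call_degs_all_pairs(table)
    out["expression_deg"] = topo(expr_mod.deg_union_matrix(table, degs))
    out["ndr"] = topo(
        nuc_mod.ndr_matrix([sim.track(c, "mnase") for c in CELL_TYPES], genes)
    )

    auc = roc_mod.roc_suite(
        {"h3k9ac": k9_prom, "h3k27me3": k27_prom}, table.rpkm_values, k=roc_k
    )
    out["auc"] = {
        (r["mark"], r["cell"]): r["auc"] for r in auc.to_dict(orient="records")
    }

    # planted-enhancer recovery at >=50% reciprocal overlap
    def reciprocal(iv, s, e):
        ov = max(0, min(iv.end, e) - max(iv.start, s))
        return min(ov / (iv.end - iv.start), ov / (e - s)) if ov else 0.0

    n_active = n_found = 0
    for j, cell in enumerate(CELL_TYPES):
        for r in sim.truth.enhancers.itertuples():
            if cell not in r.active_cells.split(","):
                continue
            n_active += 1
            n_found += any(
                reciprocal(iv, r.start, r.end) >= 0.5 for iv in sets[j].intervals
            )
    out["enhancer_recovery"] = n_found / n_active
    return out


def run_pipeline(
    cfg: PipelineConfig, stages: list[str] | None = None
) -> PipelineState:
    """Execute the requested stages (all by default) in dependency order."""
    if stages is None:
        stages = list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]
    os.makedirs(cfg.outdir, exist_ok=True)
    state = PipelineState(cfg)
    for stage in stages:
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](state)
    return state
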