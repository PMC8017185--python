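"""End-to-end orchestration: simulate -> detect -> quantify -> DE -> trends
-> ceRNA network -> enrichment, with a run manifest and deterministic
outputs under a fixed seed."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bsj, cerna, diffexpr, io
from .simulate import (
    SimulationConfig,
    circles_to_frame,
    simulate_expression,
    simulate_genome,
    simulate_reads,
)

logger = logging.getLogger(__name__)

OMICS = ("circ", "mir", "mrna")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    data_dir: str = "dataset"
    out_dir: str = "results"
    seed: int = 0
    anchor_len: int = 20
    min_support: int = 2
    max_span: int = 100_000
    fc_cut: float = 2.0
    alpha: float = 0.05
    fdr: bool = False
    scc_max: float = -0.7
    pcc_min: float = 0.9
    sponge_alpha: float = 0.05
    restrict_to_de: bool = True
    skip_detect: bool = False
    simulate: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.sponge_alpha < 1):
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.fc_cut <= 1:
            raise ValueError("fc_cut must exceed 1")
        if not (-1 <= self.scc_max <= 1 and -1 <= self.pcc_min <= 1):
            raise ValueError("correlation thresholds must lie in [-1, 1]")
        if isinstance(self.simulate, dict):
            self.simulate = SimulationConfig(**self.simulate)
        self.simulate.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        for key, value in payload["simulate"].items():
            if isinstance(value, tuple):
                payload["simulate"][key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


# ----------------------------------------------------------------- simulate stage

def run_simulate(config: RunConfig) -> Path:
    """Write the complete synthetic dataset plus truth manifests."""
    data = Path(config.data_dir)
    (data / "truth").mkdir(parents=True, exist_ok=True)
    sim = config.simulate

    genome, circles = simulate_genome(sim)
    io.write_fasta(genome.chromosomes, data / "genome.fa")
    io.write_gtf(genome, data / "annotation.gtf")
    reads, manifest = simulate_reads(genome, circles, sim)
    io.write_fastq(reads, data / "reads.fastq")
    io.write_tsv(circles_to_frame(circles), data / "truth" / "circles.tsv")
    io.write_tsv(manifest, data / "truth" / "reads_manifest.tsv")

    expr = simulate_expression(sim)
    for omic in OMICS:
        io.write_tsv(expr.counts[omic], data / f"counts_{omic}.tsv")
    io.write_tsv(expr.sample_sheet, data / "sample_sheet.tsv", index=False)
    io.write_fasta(expr.mirna_seqs, data / "mirna.fa")
    circ_seqs = {k: v for k, v in expr.transcript_seqs.items() if k in expr.circular_ids}
    mrna_seqs = {k: v for k, v in expr.transcript_seqs.items() if k not in expr.circular_ids}
    io.write_fasta(circ_seqs, data / "transcripts_circ.fa")
    io.write_fasta(mrna_seqs, data / "transcripts_mrna.fa")
    io.write_tsv(expr.truth, data / "truth" / "expression_truth.tsv")
    io.write_tsv(expr.triplets, data / "truth" / "triplets.tsv", index=False)
    io.write_tsv(expr.target_sites, data / "truth" / "target_sites.tsv", index=False)
    _write_gene_sets(expr, data / "gene_sets.gmt")

    manifest_doc = {
        "seed": sim.seed,
        "config_digest": sim.digest(),
        "files": sorted(str(p.relative_to(data)) for p in data.rglob("*") if p.is_file()
                        and p.name != "manifest.yaml"),
    }
    with open(data / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest_doc, fh, sort_keys=True)
    logger.info("simulate: dataset written to %s (digest %s)", data, sim.digest())
    return data


def _write_gene_sets(expr, path) -> None:
    """Toy GMT: the planted-triplet mRNAs plus deterministic decoy sets."""
    mrnas = sorted(m for m in expr.transcript_seqs if m not in expr.circular_ids)
    planted = sorted(expr.triplets["mrna_id"])
    with open(path, "w") as fh:
        fh.write("planted_triplet_mrnas\tplanted\t" + "\t".join(planted) + "\n")
        for i in range(3):
            decoy = mrnas[i::4][:15]
            fh.write(f"decoy_set_{i + 1}\tdecoy\t" + "\t".join(decoy) + "\n")


# ------------------------------------------------------------------ detect stage

def run_detect(config: RunConfig) -> pd.DataFrame:
    data, out = Path(config.data_dir), Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = io.load_genome(data / "genome.fa", data / "annotation.gtf")
    reads = io.read_fastq(data / "reads.fastq")
    candidates = bsj.linear_filter(reads, genome)
    junctions = bsj.detect_bsj(
        candidates, genome, anchor_len=config.anchor_len,
        min_support=config.min_support, max_span=config.max_span)
    catalog = bsj.build_catalog(junctions, genome.genes)
    frame = bsj.catalog_to_frame(catalog)
    io.write_tsv(frame, out / "catalog.tsv")
    bsj.catalog_to_bed(catalog).to_csv(out / "junctions.bed", sep="\t",
                                       header=False, index=False)
    for name, table in bsj.summarize_catalog(
            catalog, chromosomes=sorted(genome.chromosomes)).items():
        io.write_tsv(table, out / f"{name}.tsv")
    logger.info("detect: %d junctions from %d candidate reads", len(catalog), len(candidates))
    return frame


# ---------------------------------------------------------------- quantify stage

def run_quantify(config: RunConfig) -> dict[str, pd.DataFrame]:
    """RPM-normalize the tri-omic count matrices (denominator: all mapped
    reads of the sample, here the column totals)."""
    data, out = Path(config.data_dir), Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rpm = {}
    for omic in OMICS:
        counts = io.read_matrix(data / f"counts_{omic}.tsv")
        rpm[omic] = bsj.quantify_rpm(counts, counts.sum(axis=0))
        io.write_tsv(rpm[omic], out / f"rpm_{omic}.tsv")
    return rpm


# ---------------------------------------------------------------------- DE stage

def run_de_stage(config: RunConfig) -> dict[str, pd.DataFrame]:
    data, out = Path(config.data_dir), Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = io.read_sample_sheet(data / "sample_sheet.tsv")
    stages = list(dict.fromkeys(sheet["stage"]))
    contrasts = tuple((a, b) for i, a in enumerate(stages) for b in stages[i + 1:])
    results = {}
    for omic in OMICS:
        counts = io.read_matrix(data / f"counts_{omic}.tsv")
        res = diffexpr.run_de(counts, sheet, contrasts, alpha=config.alpha,
                              fc_cut=config.fc_cut, fdr=config.fdr)
        io.write_tsv(res, out / f"de_{omic}.tsv")
        results[omic] = res
        for a, b in contrasts:
            sub = res[res["contrast"] == f"{a}_vs_{b}"]
            logger.info("de[%s] %s vs %s: %d significant", omic, a, b,
                        int(sub["significant"].sum()))
    return results


# -------------------------------------------------------------------- trend stage

def run_trend(config: RunConfig, de_circ: pd.DataFrame | None = None) -> pd.DataFrame:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if de_circ is None:
        de_circ = pd.read_csv(out / "de_circ.tsv", sep="\t", index_col=0)
    sheet = io.read_sample_sheet(Path(config.data_dir) / "sample_sheet.tsv")
    stages = tuple(dict.fromkeys(sheet["stage"]))
    trends = diffexpr.assign_trends(de_circ, stages=stages)
    enrichment = diffexpr.profile_enrichment(trends)
    io.write_tsv(trends, out / "trends.tsv")
    io.write_tsv(enrichment, out / "profile_enrichment.tsv")
    logger.info("trend: %d features assigned to profiles", len(trends))
    return trends


# -------------------------------------------------------------------- ceRNA stage

def run_cerna(
    config: RunConfig,
    rpm: dict[str, pd.DataFrame] | None = None,
    de_results: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    data, out = Path(config.data_dir), Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if rpm is None:
        rpm = {omic: io.read_matrix(out / f"rpm_{omic}.tsv") for omic in OMICS}
    if de_results is None:
        de_results = {omic: pd.read_csv(out / f"de_{omic}.tsv", sep="\t", index_col=0)
                      for omic in OMICS}
    mirna_seqs = io.read_fasta(data / "mirna.fa")
    circ_seqs = io.read_fasta(data / "transcripts_circ.fa")
    mrna_seqs = io.read_fasta(data / "transcripts_mrna.fa")
    edges = cerna.predict_targets(
        mirna_seqs, {**circ_seqs, **mrna_seqs}, circular_ids=set(circ_seqs))
    io.write_tsv(cerna.edges_to_frame(edges), out / "target_edges.tsv", index=False)

    de_sets = None
    if config.restrict_to_de:
        de_sets = {omic: set(res.index[res["significant"]]) for omic, res in de_results.items()}
    triplets = cerna.build_network(
        rpm, edges, de_features=de_sets, scc_max=config.scc_max,
        pcc_min=config.pcc_min, sponge_alpha=config.sponge_alpha)
    triplets = triplets.sort_values(["circ_id", "mirna_id", "mrna_id"]).reset_index(drop=True)
    io.write_tsv(triplets, out / "triplets.tsv", index=False)
    cerna.write_sif(triplets, out / "network.sif")
    cerna.write_graphml(triplets, out / "network.graphml")
    logger.info("cerna: %d candidate triplets, %d passing",
                len(triplets), int(triplets["passes"].sum()))
    return triplets


# ------------------------------------------------------------------- enrich stage

def run_enrich(config: RunConfig, triplets: pd.DataFrame | None = None) -> pd.DataFrame:
    data, out = Path(config.data_dir), Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if triplets is None:
        triplets = pd.read_csv(out / "triplets.tsv", sep="\t")
    gene_sets = cerna.read_gmt(data / "gene_sets.gmt")
    background = set(io.read_matrix(data / "counts_mrna.tsv").index)
    study = set(triplets.loc[triplets["passes"], "mrna_id"])
    result = cerna.overrepresentation(study, gene_sets, background)
    io.write_tsv(result, out / "enrichment.tsv")
    return result


# ------------------------------------------------------------------------ run all

def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; halts (raises) on the first failure."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_run_log(out / "run.log")
    config.to_yaml(out / "resolved_config.yaml")

    summary: dict = {"seed": config.seed}
    stages: list[tuple[str, callable]] = []
    catalog_holder: dict = {}

    def detect_stage():
        catalog_holder["catalog"] = run_detect(config)

    def quantify_stage():
        catalog_holder["rpm"] = run_quantify(config)

    def de_stage():
        catalog_holder["de"] = run_de_stage(config)

    def trend_stage():
        catalog_holder["trends"] = run_trend(config, catalog_holder["de"]["circ"])

    def cerna_stage():
        catalog_holder["triplets"] = run_cerna(
            config, catalog_holder["rpm"], catalog_holder["de"])

    def enrich_stage():
        catalog_holder["enrichment"] = run_enrich(config, catalog_holder["triplets"])

    if not config.skip_detect:
        stages.append(("detect", detect_stage))
    stages += [("quantify", quantify_stage), ("de", de_stage),
               ("trend", trend_stage), ("cerna", cerna_stage), ("enrich", enrich_stage)]

    for name, fn in stages:
        try:
            fn()
        except Exception:
            logger.exception("stage %r failed; pipeline halted", name)
            raise

    if "catalog" in catalog_holder:
        cat = catalog_holder["catalog"]
        summary["n_detected_junctions"] = int(len(cat))
        summary["class_counts"] = {
            k: int(v) for k, v in cat["genomic_class"].value_counts().items()}
    de = catalog_holder["de"]
    summary["n_de"] = {
        omic: {c: int(g["significant"].sum()) for c, g in res.groupby("contrast")}
        for omic, res in de.items()
    }
    trends = catalog_holder["trends"]
    summary["n_trend_assigned"] = int(len(trends))
    summary["profile_counts"] = {
        int(k): int(v) for k, v in trends["profile_id"].value_counts().sort_index().items()}
    trip = catalog_holder["triplets"]
    summary["n_candidate_triplets"] = int(len(trip))
    summary["n_passing_triplets"] = int(trip["passes"].sum())
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    return summary


def _setup_run_log(path: Path) -> None:
    root = logging.getLogger("circsponge")
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
            h.close()
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root.addHandler(handler)
    root.setLevel(logging.INFO)
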