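"""End-to-end pipeline: simulate/qc/quantify/de/enrich/network/cohort.

One YAML configuration drives every stage. A single global seed is fanned
out deterministically to per-stage seeds (CRC32 of the stage name XOR the
global seed), so identical configurations produce byte-identical TSV
outputs while each stage remains reproducible in isolation. Timestamps
appear only in the log, never in data files.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import de as de_mod
from . import network as net_mod
from .enrich import cluster_terms, clusters_to_frame, enrich as enrich_query
from .cohort import CytokineSeverityModel
from .io import (
    CountMatrix,
    GROUPS,
    design_samples,
    read_design,
    read_gmt,
    read_tsv,
    validate_design,
    write_gmt,
    write_tsv,
)
from .qc import QCConfig, qc_fastq
from .quant import log_transform, rpkm
from .simulate import (
    SimConfig,
    simulate_counts,
    simulate_cytokine_cohort,
    simulate_fastq,
)

log = logging.getLogger("altinet")

STAGES = ("simulate", "qc", "quantify", "de", "enrich", "network", "cohort")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed & 0xFFFFFFFF)) % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str = "altinet_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # input paths (filled automatically by the simulate stage)
    fastq: str | None = None
    adaptors: tuple[str, ...] | None = None
    counts: str | None = None
    design: str | None = None
    gmt: str | None = None
    cohort: str | None = None
    # stage parameters
    sim: dict[str, Any] = field(default_factory=dict)
    qc_params: dict[str, Any] = field(default_factory=dict)
    pseudocount: float = 1.0
    de_params: dict[str, Any] = field(default_factory=dict)
    enrich_params: dict[str, Any] = field(default_factory=dict)
    beta: float = 6.0
    n_perm: int = 200
    edge_threshold: float = 0.5
    network_max_genes: int = 300
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            try:
                raw = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ValueError(f"cannot parse config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "adaptors" in raw and raw["adaptors"] is not None:
            raw["adaptors"] = tuple(raw["adaptors"])
        return cls(**raw)


def validate(config: PipelineConfig) -> list[str]:
    """Collect every configuration problem (empty list = runnable)."""
    issues: list[str] = []
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        issues.append(f"unknown stages: {sorted(unknown)}")
    simulate_on = "simulate" in config.stages

    def need(path: str | None, stage: str, what: str) -> None:
        if stage not in config.stages:
            return
        if path is None:
            if not simulate_on:
                issues.append(f"stage '{stage}' enabled but no {what} path configured")
        elif not Path(path).exists():
            issues.append(f"{what} file not found: {path}")

    need(config.fastq, "qc", "FASTQ")
    need(config.counts, "quantify", "counts")
    need(config.design, "quantify", "design")
    need(config.design, "de", "design")
    need(config.gmt, "enrich", "GMT")
    need(config.cohort, "cohort", "cohort")
    try:
        de_mod.DEParams(**config.de_params)
    except (TypeError, ValueError) as exc:
        issues.append(f"de_params: {exc}")
    try:
        QCConfig(**config.qc_params)
    except (TypeError, ValueError) as exc:
        issues.append(f"qc_params: {exc}")
    try:
        SimConfig(**config.sim)
    except (TypeError, ValueError) as exc:
        issues.append(f"sim: {exc}")
    if config.pseudocount <= 0:
        issues.append("pseudocount must be positive")
    if not 0 <= config.edge_threshold <= 1:
        issues.append("edge_threshold must lie in [0, 1]")
    if config.n_perm < 20:
        issues.append("n_perm must be >= 20")
    if config.design is not None and Path(config.design).exists():
        try:
            issues.extend(validate_design(read_tsv(config.design)))
        except Exception as exc:  # unreadable file
            issues.append(f"design: {exc}")
    return issues


@dataclass
class RunReport:
    config: dict[str, Any]
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, outputs: list[str], **counts: Any) -> None:
        self.stages[stage] = {"outputs": outputs, **counts}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages}, fh, indent=2, sort_keys=True)


def run(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order; see module docstring."""
    issues = validate(config)
    if issues:
        raise ValueError("invalid pipeline config: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))
    marker = out / "INCOMPLETE"
    marker.write_text("pipeline running\n")

    try:
        _run_stages(config, out, report)
    except Exception as exc:
        marker.write_text(f"pipeline failed: {exc}\n")
        raise
    marker.unlink()
    report.to_json(out / "run_report.json")
    return report


def _run_stages(config: PipelineConfig, out: Path, report: RunReport) -> None:
    de_sets: dict[str, frozenset[str]] = {}
    log_expr: pd.DataFrame | None = None
    design: pd.DataFrame | None = None

    if "simulate" in config.stages:
        sim_cfg = SimConfig(**{**config.sim, "seed": stage_seed(config.seed, "simulate")})
        cm, design, truth = simulate_counts(sim_cfg)
        cm.to_tsv(out / "counts.tsv")
        write_tsv(design, out / "design.tsv")
        truth_df = pd.DataFrame(
            {
                "gene_id": sorted(truth.de_genes_group1 | truth.de_genes_group2),
            }
        ).set_index("gene_id")
        truth_df["in_group1"] = [g in truth.de_genes_group1 for g in truth_df.index]
        truth_df["in_group2"] = [g in truth.de_genes_group2 for g in truth_df.index]
        truth_df["direction"] = [truth.de_direction[g] for g in truth_df.index]
        write_tsv(truth_df, out / "truth_de.tsv")
        cohort, cohort_truth = simulate_cytokine_cohort(sim_cfg)
        write_tsv(cohort, out / "cohort.tsv")
        simulate_fastq(sim_cfg, 200, 100, out / "reads.fastq", out / "truth_reads.tsv")
        collection = _synthetic_gmt(cm.gene_ids, truth.de_genes_group1, sim_cfg.seed)
        write_gmt(collection, out / "sets.gmt")
        config.counts = str(out / "counts.tsv")
        config.design = str(out / "design.tsv")
        config.cohort = str(out / "cohort.tsv")
        config.fastq = str(out / "reads.fastq")
        config.gmt = str(out / "sets.gmt")
        report.record(
            "simulate",
            [str(out / p) for p in (
                "counts.tsv", "design.tsv", "truth_de.tsv", "cohort.tsv",
                "reads.fastq", "truth_reads.tsv", "sets.gmt",
            )],
            n_genes=sim_cfg.n_genes,
            n_planted_de_group1=len(truth.de_genes_group1),
            n_planted_de_group2=len(truth.de_genes_group2),
            cohort_slope=cohort_truth.cohort_slope,
        )

    if "qc" in config.stages:
        qc_cfg = QCConfig(**config.qc_params)
        if config.adaptors:
            qc_cfg.adaptor_sequences = tuple(config.adaptors)
        qc_report = qc_fastq(
            config.fastq, out / "reads.kept.fastq", qc_cfg, out / "qc_report.tsv"
        )
        log.info("qc: %s", qc_report)
        report.record(
            "qc",
            [str(out / "reads.kept.fastq"), str(out / "qc_report.tsv")],
            n_input=qc_report.n_input,
            n_kept=qc_report.n_kept,
            n_removed_adaptor=qc_report.n_removed_adaptor,
            n_removed_unknown=qc_report.n_removed_unknown,
            n_removed_lowqual=qc_report.n_removed_lowqual,
        )

    if {"quantify", "de", "network"} & set(config.stages):
        cm = CountMatrix.from_tsv(config.counts)
        design = read_design(config.design)
        expr = rpkm(cm)
        log_expr = log_transform(expr, config.pseudocount)
        if "quantify" in config.stages:
            rp = expr.copy()
            rp.index.name = "gene_id"
            write_tsv(rp, out / "rpkm.tsv")
            report.record("quantify", [str(out / "rpkm.tsv")], n_genes=len(rp))

    if "de" in config.stages:
        params = de_mod.DEParams(**config.de_params)
        for group in GROUPS:
            res = de_mod.DensityBoundaryDE(log_expr, design, group).fit(params)
            tag = group.replace("-", "")
            table = res.table.copy()
            table.index.name = "gene_id"
            write_tsv(table, out / f"de_{tag}.tsv")
            de_sets[group] = res.de_genes
        venn = de_mod.compare_de_sets(de_sets[GROUPS[0]], de_sets[GROUPS[1]])
        venn_df = pd.DataFrame(
            {"count": [venn.n1_only, venn.common, venn.n2_only]},
            index=pd.Index(["group1_only", "common", "group2_only"], name="partition"),
        )
        write_tsv(venn_df, out / "venn.tsv")
        report.record(
            "de",
            [str(out / f"de_{g.replace('-', '')}.tsv") for g in GROUPS] + [str(out / "venn.tsv")],
            n_de_group1=len(de_sets[GROUPS[0]]),
            n_de_group2=len(de_sets[GROUPS[1]]),
            venn=[venn.n1_only, venn.common, venn.n2_only],
        )

    if "enrich" in config.stages:
        collection = read_gmt(config.gmt)
        kept_counts = {}
        for group, query in de_sets.items():
            if not query:
                continue
            tag = group.replace("-", "")
            results = enrich_query(query & collection.universe, collection)
            write_tsv(results, out / f"enrichment_{tag}.tsv")
            clusters = cluster_terms(results, collection, query=query, **config.enrich_params)
            write_tsv(clusters_to_frame(clusters), out / f"clusters_{tag}.tsv")
            kept_counts[group] = sum(c.kept for c in clusters)
        report.record(
            "enrich",
            sorted(str(p) for p in out.glob("enrichment_*.tsv"))
            + sorted(str(p) for p in out.glob("clusters_*.tsv")),
            clusters_kept={g.replace("-", ""): int(v) for g, v in kept_counts.items()},
        )

    if "network" in config.stages:
        # post-exposure expression per group; restrict to the DE union (the
        # genes under study) capped for tractability, highest-|M| first
        genes = sorted(de_sets.get(GROUPS[0], frozenset()) | de_sets.get(GROUPS[1], frozenset()))
        if not genes:
            genes = list(log_expr.index)
        if len(genes) > config.network_max_genes:
            genes = genes[: config.network_max_genes]
        post1 = design_samples(design, GROUPS[0], "post")
        post2 = design_samples(design, GROUPS[1], "post")
        x1 = log_expr.loc[genes, post1]
        x2 = log_expr.loc[genes, post2]
        model = net_mod.DifferentialConnectivity(x1, x2, beta=config.beta)
        res = model.fit(n_perm=config.n_perm, seed=stage_seed(config.seed, "network"),
                        alpha=config.alpha)
        write_tsv(res.table, out / "diff_connectivity.tsv")
        n_edges = {}
        for tag, x in (("group1", x1), ("group2", x2)):
            t = net_mod.tom(net_mod.adjacency(x, config.beta))
            write_tsv(connectivity_frame(t), out / f"connectivity_{tag}.tsv")
            n_edges[tag] = net_mod.export_edges(t, config.edge_threshold, out / f"edges_{tag}.tsv")
        report.record(
            "network",
            [str(out / "diff_connectivity.tsv")]
            + [str(out / f"connectivity_{t}.tsv") for t in ("group1", "group2")]
            + [str(out / f"edges_{t}.tsv") for t in ("group1", "group2")],
            n_genes=len(genes),
            n_significant=len(res.significant_genes),
            n_edges=n_edges,
        )

    if "cohort" in config.stages:
        cohort = read_tsv(config.cohort)
        res = CytokineSeverityModel(cohort).fit()
        write_tsv(res.to_frame(), out / "cohort_results.tsv")
        report.record(
            "cohort",
            [str(out / "cohort_results.tsv")],
            r=res.r,
            p=res.correlation.p_two_sided,
            n=res.correlation.n,
        )


def connectivity_frame(t: "net_mod.TOMatrix") -> pd.DataFrame:
    return net_mod.connectivity(t)


def _synthetic_gmt(genes: list[str], de_genes: frozenset[str], seed: int):
    """A small synthetic gene-set collection over the simulated universe:
    one term enriched in the planted DE genes plus random background terms."""
    import numpy as np

    from .io import GeneSetCollection

    rng = np.random.default_rng(seed)
    de_sorted = sorted(de_genes)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    n_de_term = max(5, len(de_sorted) // 2)
    enriched = set(rng.choice(de_sorted, size=min(n_de_term, len(de_sorted)), replace=False))
    enriched |= set(rng.choice(genes, size=10, replace=False))
    terms["T0001"] = ("planted-response process", frozenset(enriched))
    for i in range(2, 12):
        size = int(rng.integers(20, 80))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        terms[f"T{i:04d}"] = (f"background process {i}", members)
    return GeneSetCollection(terms=terms, universe=frozenset(genes))
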