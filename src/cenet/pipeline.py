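"""End-to-end orchestration: seeds → networks → enrichment → report.

For every configured stage the pipeline builds both polarity networks
(the UP ceNET from down-regulated seed miRNAs and the DOWN ceNET from
up-regulated ones), exports them, runs over-representation analysis on
the filtered target gene sets and writes one aggregated JSON run
report. The pipeline is a pure function of (config, input files):
identical inputs produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import cenet_builder, concordance, enrichment, io_tables
from .errors import UsageError
from .synthetic_data import SimConfig, write_simulation

logger = logging.getLogger(__name__)

CONFIG_VERSION = 1


@dataclass
class Thresholds:
    lfc: float = 0.0
    padj: float = 0.05
    fdr_max: float = 0.05
    strength_min: float = 0.01
    min_hits: int = 2
    similarity_min: float = 0.2
    clip_support_min: int = 0


@dataclass
class RunConfig:
    """Validated run configuration (YAML-backed, versioned schema).

    Paths are resolved relative to the config file's directory when
    loaded via :meth:`from_yaml`. ``cerna_tables`` maps each stage to
    the DE tables covering its ceRNA classes (one or several files;
    the RNA class is a column of the tables themselves).
    """

    ev_mirna_table: Path
    tissue_mirna_tables: dict[str, Path]
    cerna_tables: dict[str, list[Path]]
    interaction_table: Path
    stages: list[str]
    output_dir: Path
    annotation_gmts: list[Path] = field(default_factory=list)
    background: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    rng_seed: int = 0

    def validate(self) -> "RunConfig":
        if not self.stages:
            raise UsageError("config lists no stages")
        missing = []
        for stage in self.stages:
            if stage not in self.tissue_mirna_tables:
                missing.append(f"tissue miRNA table for stage {stage!r}")
            if stage not in self.cerna_tables:
                missing.append(f"ceRNA tables for stage {stage!r}")
        for p in self._all_paths():
            if not Path(p).exists():
                missing.append(f"input file {p}")
        if missing:
            raise UsageError("missing: " + "; ".join(missing))
        return self

    def _all_paths(self) -> list[Path]:
        paths = [self.ev_mirna_table, self.interaction_table]
        paths += [self.tissue_mirna_tables[s] for s in self.stages
                  if s in self.tissue_mirna_tables]
        for s in self.stages:
            paths += list(self.cerna_tables.get(s, []))
        paths += list(self.annotation_gmts)
        if self.background is not None:
            paths.append(self.background)
        return paths

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise UsageError(f"{path}: not a mapping")
        version = raw.get("cenet_config_version")
        if version != CONFIG_VERSION:
            raise UsageError(
                f"{path}: cenet_config_version must be {CONFIG_VERSION}, "
                f"got {version!r}")
        base = path.parent

        def rel(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        thr = Thresholds(**raw.get("thresholds", {}))
        return cls(
            ev_mirna_table=rel(raw["ev_mirna_table"]),
            tissue_mirna_tables={s: rel(p) for s, p in
                                 raw["tissue_mirna_tables"].items()},
            cerna_tables={s: [rel(p) for p in ps] for s, ps in
                          raw["cerna_tables"].items()},
            interaction_table=rel(raw["interaction_table"]),
            annotation_gmts=[rel(p) for p in raw.get("annotation_gmts", [])],
            background=rel(raw["background"]) if raw.get("background") else None,
            stages=list(raw["stages"]),
            output_dir=rel(raw["output_dir"]),
            thresholds=thr,
            rng_seed=int(raw.get("rng_seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "cenet_config_version": CONFIG_VERSION,
            "ev_mirna_table": str(self.ev_mirna_table),
            "tissue_mirna_tables": {s: str(p) for s, p in
                                    self.tissue_mirna_tables.items()},
            "cerna_tables": {s: [str(p) for p in ps] for s, ps in
                             self.cerna_tables.items()},
            "interaction_table": str(self.interaction_table),
            "annotation_gmts": [str(p) for p in self.annotation_gmts],
            "background": str(self.background) if self.background else None,
            "stages": list(self.stages),
            "output_dir": str(self.output_dir),
            "thresholds": dataclasses.asdict(self.thresholds),
            "rng_seed": self.rng_seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the whole workflow and write all artifacts.

    Per (stage, seed direction): a seed-set TSV (+ JSON sidecar), the
    unfiltered network edge list, the polarity-filtered network in
    SIF/GraphML/TSV, and (when annotations are configured) a grouped
    enrichment TSV. One ``report.json`` aggregates counts, missing
    seeds and an edge-level evidence trace; the report dict is also
    returned.
    """
    cfg.validate()
    thr = cfg.thresholds
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    ev = io_tables.read_de_table(
        cfg.ev_mirna_table, compartment="EV", stage="all",
        lfc_threshold=thr.lfc, padj_threshold=thr.padj)
    interactions = io_tables.read_interaction_table(cfg.interaction_table)

    annotations: list[io_tables.AnnotationSet] = []
    for gmt in cfg.annotation_gmts:
        annotations.extend(io_tables.read_gmt(gmt))
    if cfg.background is not None:
        background = {line.strip() for line in
                      Path(cfg.background).read_text(encoding="utf-8")
                      .splitlines() if line.strip()}
    else:
        background = set().union(*(a.genes for a in annotations)) \
            if annotations else set()

    ev_dir_map = {r.feature_id: r.direction for r in ev}
    report: dict[str, Any] = {
        "config": {"stages": list(cfg.stages),
                   "thresholds": dataclasses.asdict(thr)},
        "n_interactions": len(interactions),
        "runs": {},
    }
    seed_sets: dict[tuple[str, str], concordance.SeedSet] = {}

    for stage in cfg.stages:
        tissue_mirna = io_tables.read_de_table(
            cfg.tissue_mirna_tables[stage], compartment="tissue", stage=stage,
            lfc_threshold=thr.lfc, padj_threshold=thr.padj)
        cerna: list[io_tables.DERecord] = []
        for p in cfg.cerna_tables[stage]:
            cerna.extend(io_tables.read_de_table(
                p, compartment="tissue", stage=stage,
                lfc_threshold=thr.lfc, padj_threshold=thr.padj))
        tissue_dir_map = {r.feature_id: r.direction for r in tissue_mirna}

        for direction in ("up", "down"):
            tag = f"{stage}_{direction}"
            seeds = concordance.select_concordant(
                ev, tissue_mirna, direction, stage)
            seed_sets[(stage, direction)] = seeds
            io_tables.write_seed_set(seeds, outdir / f"seeds_{tag}.tsv")

            net0 = cenet_builder.build_whole_genome_net(
                seeds, interactions, clip_support_min=thr.clip_support_min)
            net = cenet_builder.apply_cerna_filter(net0, cerna)
            cenet_builder.export_network(
                net0, "TSV", outdir / f"cenet_{tag}_unfiltered.tsv")
            cenet_builder.export_network(net, "SIF", outdir / f"cenet_{tag}.sif")
            cenet_builder.export_network(
                net, "GraphML", outdir / f"cenet_{tag}.graphml")
            cenet_builder.export_network(net, "TSV", outdir / f"cenet_{tag}.tsv")

            enriched = []
            if annotations:
                results = enrichment.enrich(
                    sorted(net.target_gene_set), annotations, background,
                    fdr_max=thr.fdr_max, strength_min=thr.strength_min,
                    min_hits=thr.min_hits)
                enriched = enrichment.group_terms(results, thr.similarity_min)
                io_tables.write_enrichment_table(
                    enriched, outdir / f"enrichment_{tag}.tsv")

            class_counts: dict[str, int] = {}
            for _, cls in net.target_nodes:
                class_counts[cls] = class_counts.get(cls, 0) + 1
            report["runs"][tag] = {
                "stage": stage,
                "seed_direction": direction,
                "polarity": seeds.cenet_polarity,
                "n_seeds": len(seeds.members),
                "seed_members": list(seeds.members),
                "conflicting_excluded": list(seeds.excluded_conflicts),
                "missing_seeds": list(net.missing_seeds),
                "filtered_out_seeds": list(net.filtered_out_seeds),
                "n_edges_unfiltered": len(net0.edges),
                "n_edges_filtered": len(net.edges),
                "n_targets_by_class": class_counts,
                "n_enriched_terms": len(enriched),
                "edge_evidence": [
                    {
                        "mirna_id": e.mirna_id,
                        "target_id": e.target_id,
                        "target_class": e.target_class,
                        "clip_support": e.clip_support,
                        "ev_mirna_direction": ev_dir_map.get(e.mirna_id),
                        "tissue_mirna_direction": tissue_dir_map.get(e.mirna_id),
                        "target_direction": e.target_direction,
                    }
                    for e in net.edges
                ],
            }

    if len(cfg.stages) >= 2:
        report["cross_stage_overlap"] = {
            direction: sorted(concordance.cross_stage_overlap(
                [seed_sets[(s, direction)] for s in cfg.stages]))
            for direction in ("up", "down")
        }

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def simulate_run(sim: SimConfig, outdir: str | Path) -> RunConfig:
    """Write a simulated input directory plus a ready-to-run config.

    The returned :class:`RunConfig` points at the generated tables and
    at ``<outdir>/results`` for pipeline output; it is also written to
    ``<outdir>/config.yaml``.
    """
    outdir = Path(outdir)
    paths = write_simulation(sim, outdir)
    cfg = RunConfig(
        ev_mirna_table=paths["ev_mirna"],
        tissue_mirna_tables={sim.stage: paths["tissue_mirna"]},
        cerna_tables={sim.stage: [paths["tissue_cerna"]]},
        interaction_table=paths["interactions"],
        annotation_gmts=[paths["annotations"]],
        background=paths["background"],
        stages=[sim.stage],
        output_dir=outdir / "results",
        rng_seed=sim.rng_seed,
    )
    cfg.to_yaml(outdir / "config.yaml")
    return cfg
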