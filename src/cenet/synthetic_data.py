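"""Synthetic inputs with planted, recoverable structure.

Generates the three table kinds the pipeline consumes — two-compartment
miRNA DE tables, tissue ceRNA DE tables across the three ceRNA classes,
a CLIP-style interaction table and a GMT annotation file — together
with a ``truth`` record of what was planted, so that end-to-end
parameter recovery can be asserted without any external download.

What is emulated: direction concordance between vesicle cargo and
tissue (with a controllable label-flip noise on the tissue side),
polarity-consistent miRNA→ceRNA edges over mRNA/lncRNA/circRNA, a
background of random interactions, and one annotation term enriched in
the filtered network's gene set. What is *not* emulated: count-level
noise models, miRNA family/seed-sequence structure, or any mechanistic
sponging kinetics — expression means are log-normal dressing whose
only job is to respect the direction/means ordering invariant.

All sampling flows from one :class:`numpy.random.Generator` keyed by
``rng_seed``, drawn in a fixed documented order, so identical configs
give byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import numpy as np

from .errors import UsageError
from .io_tables import (
    CERNA_CLASSES,
    DERecord,
    InteractionRecord,
    AnnotationSet,
    write_de_table,
    write_gmt,
    write_interaction_table,
)

_EXPR_BASELINE_LOG = {  # log-scale mean of the normalized-count baseline
    "miRNA": np.log(500.0),
    "mRNA": np.log(800.0),
    "lncRNA": np.log(120.0),
    "circRNA": np.log(40.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study.

    Defaults emulate a small two-compartment miRNA screen of the kind
    the pipeline targets: a few dozen vesicle-detectable miRNAs of
    which a minority are direction-concordant with the tissue, a
    CLIP-style interaction table dominated by background edges with a
    handful of planted polarity-consistent targets per seed, and an
    annotation file with one term covering most of the recovered
    network.
    """

    n_mirna: int = 60
    n_cerna_per_class: int = 300
    frac_concordant_up: float = 0.10
    frac_concordant_down: float = 0.08
    edge_density: float = 0.005
    planted_edges_per_seed: int = 3
    n_terms: int = 50
    planted_term_size: int = 25
    planted_term_coverage: float = 0.8
    noise_flip_prob: float = 0.0
    stage: str = "6m"
    rng_seed: int = 0

    def validate(self) -> "SimConfig":
        if self.frac_concordant_up + self.frac_concordant_down > 1:
            raise UsageError("concordant fractions must sum to <= 1")
        for name in ("n_mirna", "n_cerna_per_class", "planted_edges_per_seed",
                     "n_terms", "planted_term_size"):
            if getattr(self, name) <= 0:
                raise UsageError(f"{name} must be positive")
        if not 0 < self.edge_density <= 1:
            raise UsageError("edge_density must lie in (0, 1]")
        if not 0 <= self.noise_flip_prob < 0.5:
            raise UsageError("noise_flip_prob must lie in [0, 0.5)")
        if not 0 <= self.planted_term_coverage <= 1:
            raise UsageError("planted_term_coverage must lie in [0, 1]")
        return self


def _mirna_ids(cfg: SimConfig) -> list[str]:
    return [f"sim-miR-{i:04d}" for i in range(cfg.n_mirna)]


def _cerna_ids(cfg: SimConfig) -> dict[str, list[str]]:
    prefix = {"mRNA": "Gene", "lncRNA": "Lnc", "circRNA": "Circ"}
    return {cls: [f"{prefix[cls]}{i:04d}" for i in range(cfg.n_cerna_per_class)]
            for cls in CERNA_CLASSES}


def _make_record(
    rng: np.random.Generator,
    feature_id: str,
    rna_class: str,
    compartment: str,
    stage: str,
    direction: str,
) -> DERecord:
    """Dress a direction label with self-consistent means/log2fc/padj."""
    base = float(rng.lognormal(_EXPR_BASELINE_LOG[rna_class], 1.0))
    if direction == "ns":
        lfc = float(rng.uniform(-0.2, 0.2))
        # nudge off exactly 0 so the mean ordering stays strict
        if lfc == 0.0:
            lfc = 0.01
        padj = float(rng.uniform(0.1, 1.0))
    else:
        magnitude = float(rng.uniform(0.5, 2.5))
        lfc = magnitude if direction == "up" else -magnitude
        padj = float(rng.uniform(1e-6, 0.01))
    mean_ctrl = round(base, 3)
    mean_case = round(base * 2.0 ** lfc, 3)
    if mean_case == mean_ctrl:  # rounding collision at tiny means
        mean_case = mean_ctrl + (0.001 if lfc > 0 else -0.001)
    return DERecord(
        feature_id=feature_id, rna_class=rna_class, compartment=compartment,
        stage=stage, mean_ctrl=mean_ctrl, mean_case=max(mean_case, 0.0),
        log2fc=round(lfc, 4), padj=round(padj, 6), direction=direction)


def gen_de_tables(
    cfg: SimConfig,
) -> tuple[list[DERecord], list[DERecord], list[DERecord], dict[str, Any]]:
    """Generate EV miRNA, tissue miRNA and tissue ceRNA DE tables.

    The first ``frac_concordant_up`` (resp. ``_down``) share of miRNAs
    is planted concordant; every other miRNA receives deliberately
    discordant compartment labels. Each tissue miRNA label then flips
    direction with probability ``noise_flip_prob`` (flips can both
    remove planted members and create spurious ones, as in real data).
    For each planted seed, ``planted_edges_per_seed`` distinct target
    ceRNAs (cycled over the three classes) are reserved and their
    tissue direction set polarity-consistent with the seed (up-seed →
    down target); every other ceRNA direction is drawn uniformly over
    up/down/ns.

    Returns ``(ev_mirna, tissue_mirna, tissue_cerna, truth)`` where
    ``truth`` records the planted concordant sets and reserved targets
    (post-noise sets are what the pipeline should recover only at
    ``noise_flip_prob=0``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    mirnas = _mirna_ids(cfg)
    n_up = round(cfg.frac_concordant_up * cfg.n_mirna)
    n_down = round(cfg.frac_concordant_down * cfg.n_mirna)

    ev_dir: dict[str, str] = {}
    tissue_dir: dict[str, str] = {}
    for i, m in enumerate(mirnas):
        if i < n_up:
            ev_dir[m] = tissue_dir[m] = "up"
        elif i < n_up + n_down:
            ev_dir[m] = tissue_dir[m] = "down"
        else:
            d = str(rng.choice(["up", "down", "ns"]))
            others = [x for x in ("up", "down", "ns") if x != d]
            ev_dir[m] = d
            tissue_dir[m] = str(rng.choice(others))
    flips = rng.random(cfg.n_mirna) < cfg.noise_flip_prob
    for m, flip in zip(mirnas, flips):
        if flip and tissue_dir[m] != "ns":
            tissue_dir[m] = "down" if tissue_dir[m] == "up" else "up"

    ev_mirna = [_make_record(rng, m, "miRNA", "EV", "all", ev_dir[m])
                for m in mirnas]
    tissue_mirna = [_make_record(rng, m, "miRNA", "tissue", cfg.stage,
                                 tissue_dir[m]) for m in mirnas]

    # reserve polarity-consistent targets for the planted seeds, cycling
    # the ceRNA classes so every class participates
    cerna = _cerna_ids(cfg)
    seeds = [(m, "up") for m in mirnas[:n_up]] + \
            [(m, "down") for m in mirnas[n_up:n_up + n_down]]
    need = -(-len(seeds) * cfg.planted_edges_per_seed // len(CERNA_CLASSES))
    if need > cfg.n_cerna_per_class:
        raise UsageError("not enough ceRNAs per class for the planted edges")
    reserved = {cls: [cerna[cls][i]
                      for i in rng.permutation(cfg.n_cerna_per_class)[:need]]
                for cls in CERNA_CLASSES}
    cursor = {cls: 0 for cls in CERNA_CLASSES}
    cerna_dir: dict[tuple[str, str], str] = {}
    planted_targets: list[dict[str, Any]] = []
    ci = 0
    for mirna, direction in seeds:
        for _ in range(cfg.planted_edges_per_seed):
            cls = CERNA_CLASSES[ci % len(CERNA_CLASSES)]
            ci += 1
            target = reserved[cls][cursor[cls]]
            cursor[cls] += 1
            cerna_dir[(target, cls)] = "down" if direction == "up" else "up"
            planted_targets.append({
                "mirna_id": mirna, "target_id": target, "target_class": cls,
                "polarity": "DOWN" if direction == "up" else "UP"})

    tissue_cerna: list[DERecord] = []
    for cls in CERNA_CLASSES:
        for gene in cerna[cls]:
            d = cerna_dir.get((gene, cls))
            if d is None:
                d = str(rng.choice(["up", "down", "ns"]))
                cerna_dir[(gene, cls)] = d
            tissue_cerna.append(
                _make_record(rng, gene, cls, "tissue", cfg.stage, d))

    truth: dict[str, Any] = {
        "config": asdict(cfg),
        "concordant_up": sorted(mirnas[:n_up]),
        "concordant_down": sorted(mirnas[n_up:n_up + n_down]),
        "ev_direction": ev_dir,
        "tissue_direction": tissue_dir,
        "planted_targets": planted_targets,
        "cerna_direction": {f"{cls}:{g}": d
                            for (g, cls), d in cerna_dir.items()},
    }
    return ev_mirna, tissue_mirna, tissue_cerna, truth


def gen_interaction_table(
    cfg: SimConfig, truth: dict[str, Any]
) -> list[InteractionRecord]:
    """Generate a CLIP-style interaction table with planted edges.

    Every target reserved by :func:`gen_de_tables` becomes a planted
    edge with CLIP support uniform on 1..10. All remaining miRNA×ceRNA
    pairs enter independently with probability ``edge_density``.
    ``truth`` gains ``planted_edges`` and ``consistent_edges`` (every
    table edge — planted or background — that survives an ideal
    polarity filter given the planted seed sets).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed + 1)
    cerna = _cerna_ids(cfg)
    records: list[InteractionRecord] = []
    planted: list[dict[str, Any]] = []
    planted_pairs: set[tuple[str, str]] = set()
    for spec in truth["planted_targets"]:
        support = int(rng.integers(1, 11))
        records.append(InteractionRecord(
            spec["mirna_id"], spec["target_id"], spec["target_class"],
            support))
        planted.append({**spec, "clip_support": support})
        planted_pairs.add((spec["mirna_id"], spec["target_id"]))

    mirnas = _mirna_ids(cfg)
    for mirna in mirnas:
        for cls in CERNA_CLASSES:
            mask = rng.random(cfg.n_cerna_per_class) < cfg.edge_density
            supports = rng.integers(1, 11, size=cfg.n_cerna_per_class)
            for gene, hit, support in zip(cerna[cls], mask, supports):
                if hit and (mirna, gene) not in planted_pairs:
                    records.append(
                        InteractionRecord(mirna, gene, cls, int(support)))

    truth["planted_edges"] = planted
    truth["consistent_edges"] = _ideal_filter(records, truth)
    return records


def _ideal_filter(
    records: list[InteractionRecord], truth: dict[str, Any]
) -> list[dict[str, Any]]:
    """Edges an ideal polarity filter would keep, given planted
    (pre-noise) seed sets and the final ceRNA direction labels."""
    seed_dir = {m: "up" for m in truth["concordant_up"]}
    seed_dir.update({m: "down" for m in truth["concordant_down"]})
    kept = []
    for r in records:
        d = seed_dir.get(r.mirna_id)
        if d is None:
            continue
        want = "down" if d == "up" else "up"
        if truth["cerna_direction"].get(f"{r.target_class}:{r.target_id}") == want:
            kept.append({"mirna_id": r.mirna_id, "target_id": r.target_id,
                         "target_class": r.target_class,
                         "clip_support": r.clip_support,
                         "polarity": "DOWN" if d == "up" else "UP"})
    kept.sort(key=lambda e: (e["polarity"], e["mirna_id"], e["target_id"]))
    return kept


def gen_annotation(
    cfg: SimConfig, truth: dict[str, Any]
) -> tuple[list[AnnotationSet], set[str]]:
    """Generate a GMT-style annotation list plus its background universe.

    The background is every ceRNA identifier. One planted term covers
    ``planted_term_coverage`` of the ideal filtered network's gene set
    (padded with off-network genes up to ``planted_term_size``); the
    other ``n_terms - 1`` terms are uniform random draws from the
    background. ``truth`` gains the planted term's id and gene list.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed + 2)
    cerna = _cerna_ids(cfg)
    background = {g for genes in cerna.values() for g in genes}
    net_genes = sorted({e["target_id"] for e in truth["consistent_edges"]})

    n_cover = round(cfg.planted_term_coverage * len(net_genes))
    covered = [net_genes[i]
               for i in rng.choice(len(net_genes), size=n_cover, replace=False)] \
        if n_cover else []
    off_net = sorted(background - set(net_genes))
    n_pad = max(cfg.planted_term_size - len(covered), 0)
    pad = [off_net[i]
           for i in rng.choice(len(off_net), size=min(n_pad, len(off_net)),
                               replace=False)]
    planted = AnnotationSet(
        term_id="SIM:0001", term_name="planted ceNET term",
        category="simulated", genes=frozenset(covered) | frozenset(pad))

    annotations = [planted]
    pool = sorted(background)
    for i in range(1, cfg.n_terms):
        size = int(rng.integers(10, 51))
        genes = [pool[j]
                 for j in rng.choice(len(pool), size=size, replace=False)]
        annotations.append(AnnotationSet(
            term_id=f"SIM:{i + 1:04d}", term_name=f"random term {i + 1}",
            category="simulated", genes=frozenset(genes)))

    truth["planted_term"] = {"term_id": planted.term_id,
                             "genes": sorted(planted.genes)}
    return annotations, background


def write_simulation(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run all three generators and write a ready-to-run input directory.

    Writes the DE tables, interaction table, annotation GMT, a
    background gene list and ``truth.json``; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ev, tissue_mirna, tissue_cerna, truth = gen_de_tables(cfg)
    interactions = gen_interaction_table(cfg, truth)
    annotations, background = gen_annotation(cfg, truth)

    paths = {
        "ev_mirna": outdir / "ev_mirna.tsv",
        "tissue_mirna": outdir / f"tissue_mirna_{cfg.stage}.tsv",
        "tissue_cerna": outdir / f"tissue_cerna_{cfg.stage}.tsv",
        "interactions": outdir / "interactions.tsv",
        "annotations": outdir / "annotations.gmt",
        "background": outdir / "background.txt",
        "truth": outdir / "truth.json",
    }
    write_de_table(ev, paths["ev_mirna"])
    write_de_table(tissue_mirna, paths["tissue_mirna"])
    write_de_table(tissue_cerna, paths["tissue_cerna"])
    write_interaction_table(interactions, paths["interactions"])
    write_gmt(annotations, paths["annotations"])
    paths["background"].write_text(
        "\n".join(sorted(background)) + "\n", encoding="utf-8")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
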