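"""Construction, polarity filtering and export of ceRNA networks.

A ceNET is a bipartite directed network: seed miRNAs point at the
competing endogenous RNAs (mRNA, lncRNA, circRNA) they physically bind
per CLIP-supported interaction evidence. Construction is two-phase,
mirroring the ceRNA hypothesis:

1. :func:`build_whole_genome_net` expands the seed miRNAs into every
   CLIP-supported interaction in the table (no expression filter yet);
2. :func:`apply_cerna_filter` keeps only targets whose tissue
   dysregulation direction matches the network polarity — an UP
   network retains up-regulated ceRNAs of down-regulated miRNAs, and
   dually for DOWN.

Exports are Cytoscape-compatible (SIF, GraphML) plus a flat TSV edge
list; all output is deterministically sorted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import networkx as nx

from .concordance import SeedSet
from .errors import UsageError
from .io_tables import DERecord, InteractionRecord

logger = logging.getLogger(__name__)

#: network polarity -> ceRNA direction it retains
DIRECTION_OF_POLARITY = {"UP": "up", "DOWN": "down"}

SIF_RELATION = "cerna_of"


@dataclass(frozen=True)
class Edge:
    """One retained miRNA→ceRNA interaction inside a ceNET."""

    mirna_id: str
    target_id: str
    target_class: str
    clip_support: int
    target_direction: str | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.target_id)


@dataclass(frozen=True)
class CeNET:
    """A polarity-consistent bipartite miRNA→ceRNA network for one stage.

    ``seed_members`` records the originating seed set;
    ``missing_seeds`` are seeds absent from the interaction table and
    ``filtered_out_seeds`` those whose every edge was removed by the
    polarity filter. Connected nodes are derivable from ``edges``.
    """

    stage: str
    polarity: str
    seed_members: tuple[str, ...]
    edges: tuple[Edge, ...]
    missing_seeds: tuple[str, ...] = ()
    filtered_out_seeds: tuple[str, ...] = ()
    filtered: bool = False

    def __post_init__(self) -> None:
        if self.polarity not in DIRECTION_OF_POLARITY:
            raise UsageError(f"unknown polarity {self.polarity!r}")

    @property
    def mirna_nodes(self) -> tuple[str, ...]:
        return tuple(sorted({e.mirna_id for e in self.edges}))

    @property
    def target_nodes(self) -> tuple[tuple[str, str], ...]:
        """Sorted (target_id, target_class) pairs with degree >= 1."""
        return tuple(sorted({(e.target_id, e.target_class)
                             for e in self.edges}))

    @property
    def nodes(self) -> tuple[tuple[str, str], ...]:
        """All connected nodes as sorted (id, rna_class) pairs."""
        mirnas = {(m, "miRNA") for m in self.mirna_nodes}
        return tuple(sorted(mirnas | set(self.target_nodes)))

    @property
    def target_gene_set(self) -> set[str]:
        """Target identifiers, the query set for enrichment analysis."""
        return {e.target_id for e in self.edges}


def build_whole_genome_net(
    seeds: SeedSet,
    interactions: Sequence[InteractionRecord],
    *,
    clip_support_min: int = 0,
) -> CeNET:
    """Expand seed miRNAs into their full CLIP-supported interaction
    neighbourhood (unfiltered ceNET).

    Interactions must already be deduplicated (as
    :func:`~cenet.io_tables.read_interaction_table` guarantees). Seeds
    with no interaction row at all are reported in ``missing_seeds``;
    an empty seed set yields an empty network with a warning. No
    minimum CLIP support is applied unless requested.
    """
    members = set(seeds.members)
    if not members:
        logger.warning("empty seed set (%s/%s): empty network",
                       seeds.stage, seeds.mirna_direction)
    edges = tuple(sorted(
        (Edge(r.mirna_id, r.target_id, r.target_class, r.clip_support)
         for r in interactions
         if r.mirna_id in members and r.clip_support >= clip_support_min),
        key=lambda e: e.key))
    connected = {e.mirna_id for e in edges}
    missing = tuple(sorted(members - connected))
    if missing:
        logger.info("seeds with no reported interactions: %s",
                    ", ".join(missing))
    return CeNET(
        stage=seeds.stage,
        polarity=seeds.cenet_polarity,
        seed_members=tuple(seeds.members),
        edges=edges,
        missing_seeds=missing,
    )


def apply_cerna_filter(
    net: CeNET, cerna_records: Sequence[DERecord]
) -> CeNET:
    """Keep only edges whose target is dysregulated in the network's
    polarity direction in the tissue.

    Targets are matched against the DE evidence by (id, RNA class)
    pair; when a target id exists in the DE tables only under a
    different class than the interaction table claims, the mismatch is
    logged, the interaction table's class annotation wins and that DE
    record's direction is used. Targets absent from the DE evidence
    (or present but not in the polarity direction) are dropped; seed
    miRNAs left with degree 0 move to ``filtered_out_seeds``.
    """
    want = DIRECTION_OF_POLARITY[net.polarity]
    by_id_class: dict[tuple[str, str], DERecord] = {}
    by_id: dict[str, DERecord] = {}
    for rec in cerna_records:
        by_id_class.setdefault((rec.feature_id, rec.rna_class), rec)
        by_id.setdefault(rec.feature_id, rec)

    kept: list[Edge] = []
    for edge in net.edges:
        rec = by_id_class.get((edge.target_id, edge.target_class))
        if rec is None:
            rec = by_id.get(edge.target_id)
            if rec is not None:
                logger.warning(
                    "%s: DE class %s conflicts with interaction class %s; "
                    "keeping interaction class", edge.target_id,
                    rec.rna_class, edge.target_class)
        if rec is not None and rec.direction == want:
            kept.append(replace(edge, target_direction=rec.direction))

    kept_edges = tuple(sorted(kept, key=lambda e: e.key))
    retained_mirnas = {e.mirna_id for e in kept_edges}
    had_edges = {e.mirna_id for e in net.edges}
    dropped = tuple(sorted(had_edges - retained_mirnas))
    if dropped:
        logger.info("seed miRNAs with no polarity-consistent target: %s",
                    ", ".join(dropped))
    return replace(net, edges=kept_edges, filtered_out_seeds=dropped,
                   filtered=True)


# ---------------------------------------------------------------------------
# export / import


def to_networkx(net: CeNET) -> nx.DiGraph:
    """Render a ceNET as a directed networkx graph with node attributes
    ``rna_class`` and ``direction`` and edge attribute ``clip_support``."""
    g = nx.DiGraph(stage=net.stage, polarity=net.polarity,
                   filtered=str(net.filtered))
    mirna_dir = DIRECTION_OF_POLARITY["UP" if net.polarity == "DOWN" else "DOWN"]
    for node_id, rna_class in net.nodes:
        direction = mirna_dir if rna_class == "miRNA" else (
            DIRECTION_OF_POLARITY[net.polarity] if net.filtered else "")
        g.add_node(node_id, rna_class=rna_class, direction=direction)
    for e in sorted(net.edges, key=lambda e: e.key):
        g.add_edge(e.mirna_id, e.target_id, clip_support=e.clip_support)
    return g


def export_network(net: CeNET, fmt: str, path: str | Path) -> Path:
    """Write a ceNET to ``path`` in SIF, GraphML or TSV form.

    SIF rows are ``<mirna>\\t cerna_of \\t<target>``; GraphML carries
    the node/edge attributes of :func:`to_networkx`; TSV mirrors the
    GraphML attributes as a flat edge list. Output ordering is fully
    deterministic (sorted by edge key).
    """
    path = Path(path)
    edges = sorted(net.edges, key=lambda e: e.key)
    if fmt == "SIF":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for e in edges:
                fh.write(f"{e.mirna_id}\t{SIF_RELATION}\t{e.target_id}\n")
    elif fmt == "GraphML":
        g = to_networkx(net)
        nx.write_graphml(g, path, named_key_ids=True, edge_id_from_attribute=None)
    elif fmt == "TSV":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("mirna_id\ttarget_id\ttarget_class\ttarget_direction\t"
                     "clip_support\n")
            for e in edges:
                fh.write(f"{e.mirna_id}\t{e.target_id}\t{e.target_class}\t"
                         f"{e.target_direction or ''}\t{e.clip_support}\n")
    else:
        raise UsageError(f"unknown export format {fmt!r}; "
                         f"expected SIF, GraphML or TSV")
    return path


def read_graphml_network(path: str | Path) -> CeNET:
    """Re-import a GraphML export as a ceNET (round-trip counterpart of
    :func:`export_network`). Seed bookkeeping lists are not serialized,
    so only stage, polarity, nodes and edges survive the round trip."""
    g = nx.read_graphml(path)
    class_of = {n: d.get("rna_class", "") for n, d in g.nodes(data=True)}
    dir_of = {n: d.get("direction", "") or None for n, d in g.nodes(data=True)}
    edges = tuple(sorted(
        (Edge(u, v, class_of.get(v, ""), int(d.get("clip_support", 0)),
              dir_of.get(v))
         for u, v, d in g.edges(data=True)),
        key=lambda e: e.key))
    return CeNET(
        stage=g.graph.get("stage", ""),
        polarity=g.graph.get("polarity", "UP"),
        seed_members=tuple(sorted({e.mirna_id for e in edges})),
        edges=edges,
        filtered=g.graph.get("filtered", "False") == "True",
    )
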