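"""Direction-concordant miRNA seed selection.

Vesicle-borne miRNAs only become network seeds when their
dysregulation direction agrees between the extracellular-vesicle (EV)
cargo and the tissue at a given disease stage. Under the competing
endogenous RNA hypothesis the seed direction fixes the network
polarity with opposite sign: up-regulated miRNAs imply their sponges
are off, so they seed the DOWN-regulated ceRNA network; down-regulated
miRNAs seed the UP network.

The EV compartment is treated as stage-independent — a single EV DE
table is intersected with each tissue stage — reflecting the
assumption that stressed neurons release a stable set of dysregulated
miRNAs over the modelled ages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Sequence

from .errors import UsageError
from .io_tables import DERecord

logger = logging.getLogger(__name__)

#: seed miRNA direction -> polarity of the ceRNA network it builds
POLARITY_OF_DIRECTION = {"up": "DOWN", "down": "UP"}


def infer_direction(
    record: DERecord, lfc_threshold: float, padj_threshold: float
) -> str:
    """Classify a DE record as ``up``/``down``/``ns`` from its
    log2 fold-change and adjusted p-value.

    ``up`` requires ``log2fc > lfc_threshold`` and
    ``padj <= padj_threshold``; ``down`` is the mirror. Everything
    else, including records missing the needed fields, is ``ns``
    (missing fields are logged). A ``padj_threshold >= 1`` disables
    the significance requirement, so a missing padj is acceptable.
    """
    if lfc_threshold < 0:
        raise UsageError("lfc_threshold must be nonnegative")
    if record.log2fc is None:
        logger.warning("%s: no log2fc, classified ns", record.feature_id)
        return "ns"
    if record.padj is None:
        if padj_threshold < 1.0:
            logger.warning("%s: no padj, classified ns", record.feature_id)
            return "ns"
        significant = True
    else:
        significant = record.padj <= padj_threshold
    if significant and record.log2fc > lfc_threshold:
        return "up"
    if significant and record.log2fc < -lfc_threshold:
        return "down"
    return "ns"


@dataclass(frozen=True)
class SeedSet:
    """Direction-concordant miRNAs for one (stage, direction).

    ``members`` is lexicographically ordered and duplicate-free.
    ``cenet_polarity`` is derived: up-miRNAs → DOWN network,
    down-miRNAs → UP network. ``excluded_conflicts`` lists miRNAs
    dropped because one compartment reported both directions for them.
    """

    stage: str
    mirna_direction: str
    members: tuple[str, ...]
    excluded_conflicts: tuple[str, ...] = ()
    cenet_polarity: str = field(init=False)

    def __post_init__(self) -> None:
        if self.mirna_direction not in POLARITY_OF_DIRECTION:
            raise UsageError(
                f"seed direction must be 'up' or 'down', "
                f"got {self.mirna_direction!r}")
        object.__setattr__(
            self, "cenet_polarity",
            POLARITY_OF_DIRECTION[self.mirna_direction])
        if not self.members:
            logger.warning("empty seed set for stage=%s direction=%s",
                           self.stage, self.mirna_direction)


def _compartment_of(records: Sequence[DERecord]) -> str | None:
    """The single compartment a record list belongs to (None if empty)."""
    comps = {r.compartment for r in records}
    if len(comps) > 1:
        raise UsageError(f"record list mixes compartments: {sorted(comps)}")
    return next(iter(comps)) if comps else None


def _direction_map(
    records: Iterable[DERecord], compartment: str
) -> tuple[dict[str, str], set[str]]:
    """Map miRNA id -> direction, excluding ids with conflicting calls.

    Returns the map (significant directions only) and the set of
    conflicted ids.
    """
    directions: dict[str, str] = {}
    conflicts: set[str] = set()
    for rec in records:
        if rec.rna_class != "miRNA":
            raise UsageError(
                f"{rec.feature_id}: expected rna_class=miRNA, "
                f"got {rec.rna_class}")
        if rec.direction == "ns":
            continue
        mirna = rec.feature_id.strip()
        prev = directions.get(mirna)
        if prev is not None and prev != rec.direction:
            conflicts.add(mirna)
            logger.warning("%s: conflicting directions (%s vs %s) in %s; "
                           "excluded", mirna, prev, rec.direction, compartment)
        else:
            directions[mirna] = rec.direction
    for mirna in conflicts:
        directions.pop(mirna, None)
    return directions, conflicts


def select_concordant(
    ev_records: Sequence[DERecord],
    tissue_records: Sequence[DERecord],
    direction: str,
    stage: str,
) -> SeedSet:
    """Intersect EV and tissue miRNA calls of one direction into a
    stage-specific seed set.

    A miRNA is a member iff it is called ``direction`` in *both*
    compartments. Tissue records must carry the requested stage; the
    EV table is stage-independent. The compartment roles are read from
    the records themselves, so the result is invariant under swapping
    the two arguments; passing two lists from the same compartment is
    a usage error.
    """
    if direction not in POLARITY_OF_DIRECTION:
        raise UsageError(f"direction must be 'up' or 'down', got {direction!r}")
    comp_a, comp_b = _compartment_of(ev_records), _compartment_of(tissue_records)
    if comp_a == "tissue" or comp_b == "EV":
        ev_records, tissue_records = tissue_records, ev_records
        comp_a, comp_b = comp_b, comp_a
    if comp_a not in (None, "EV") or comp_b not in (None, "tissue"):
        raise UsageError(
            f"need one EV and one tissue record list, got "
            f"{comp_a!r} and {comp_b!r}")
    for rec in tissue_records:
        if rec.stage != stage:
            raise UsageError(
                f"{rec.feature_id}: tissue record stage {rec.stage!r} "
                f"does not match requested stage {stage!r}")
    ev_dir, ev_conf = _direction_map(ev_records, "EV")
    ti_dir, ti_conf = _direction_map(tissue_records, "tissue")
    members = tuple(sorted(
        m for m, d in ev_dir.items()
        if d == direction and ti_dir.get(m) == direction))
    return SeedSet(
        stage=stage,
        mirna_direction=direction,
        members=members,
        excluded_conflicts=tuple(sorted(ev_conf | ti_conf)),
    )


def cross_stage_overlap(seed_sets: Sequence[SeedSet]) -> set[str]:
    """Intersect seed-set membership across stages/groups.

    Used to spot miRNAs dysregulated at every modelled age (e.g. a
    single miRNA up-regulated in both the early- and later-stage
    seed sets). Requires at least two sets.
    """
    if len(seed_sets) < 2:
        raise UsageError("cross_stage_overlap needs at least two seed sets")
    return reduce(lambda acc, s: acc & set(s.members),
                  seed_sets[1:], set(seed_sets[0].members))
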