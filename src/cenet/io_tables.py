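"""Tabular input/output with stable column contracts.

All tables are UTF-8 TSV with a mandatory header row; lines starting
with ``#`` are comments and are skipped everywhere. Three table kinds
are handled:

* differential-expression (DE) tables — one row per feature per
  compartment (extracellular-vesicle cargo or tissue) per disease stage;
* miRNA→target interaction tables in the style of CLIP-support
  databases such as ENCORI (flat file, no live API);
* GMT annotation files (term, description, tab-separated gene symbols).

Readers validate against the domain invariants and raise
:class:`~cenet.errors.FormatError` with the offending column name or
1-based line number; writers emit deterministic, sorted-where-stated
output so that reruns are byte-identical.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

RNA_CLASSES = ("miRNA", "mRNA", "lncRNA", "circRNA")
CERNA_CLASSES = ("mRNA", "lncRNA", "circRNA")
COMPARTMENTS = ("EV", "tissue")
DIRECTIONS = ("up", "down", "ns")

_DE_COLUMNS = ("feature_id", "rna_class", "mean_ctrl", "mean_case",
               "log2fc", "padj", "direction")


@dataclass(frozen=True)
class DERecord:
    """One feature's differential-expression evidence in one
    compartment and stage.

    ``mean_ctrl``/``mean_case`` are normalized counts on the
    median-of-ratios scale used by DESeq2-style pipelines; either may be
    absent. ``direction`` is the DE call: ``up``/``down``/``ns``
    (not significant). ``ns`` records never enter seed sets.
    """

    feature_id: str
    rna_class: str
    compartment: str
    stage: str
    mean_ctrl: float | None = None
    mean_case: float | None = None
    log2fc: float | None = None
    padj: float | None = None
    direction: str = "ns"

    def validate(self) -> "DERecord":
        if not self.feature_id:
            raise ValidationError("feature_id must be non-empty")
        if self.rna_class not in RNA_CLASSES:
            raise ValidationError(
                f"unknown rna_class {self.rna_class!r} for {self.feature_id}")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {self.compartment!r} for {self.feature_id}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"unknown direction {self.direction!r} for {self.feature_id}")
        for name in ("mean_ctrl", "mean_case"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(
                    f"{name} must be a nonnegative real for {self.feature_id}")
        if self.padj is not None and not 0.0 <= self.padj <= 1.0:
            raise ValidationError(
                f"padj must lie in [0, 1] for {self.feature_id}")
        if self.mean_ctrl is not None and self.mean_case is not None:
            if self.direction == "up" and not self.mean_case > self.mean_ctrl:
                raise ValidationError(
                    f"{self.feature_id}: direction=up but mean_case "
                    f"({self.mean_case}) <= mean_ctrl ({self.mean_ctrl})")
            if self.direction == "down" and not self.mean_case < self.mean_ctrl:
                raise ValidationError(
                    f"{self.feature_id}: direction=down but mean_case "
                    f"({self.mean_case}) >= mean_ctrl ({self.mean_ctrl})")
        # An explicit direction must agree with the sign of log2fc; the
        # direction column wins only when the two are consistent.
        if self.log2fc is not None:
            if self.direction == "up" and self.log2fc <= 0:
                raise ValidationError(
                    f"{self.feature_id}: direction=up conflicts with "
                    f"log2fc={self.log2fc}")
            if self.direction == "down" and self.log2fc >= 0:
                raise ValidationError(
                    f"{self.feature_id}: direction=down conflicts with "
                    f"log2fc={self.log2fc}")
        return self


@dataclass(frozen=True)
class InteractionRecord:
    """One CLIP-supported miRNA→ceRNA edge.

    ``clip_support`` counts the independent CLIP experiments backing
    the physical interaction.
    """

    mirna_id: str
    target_id: str
    target_class: str
    clip_support: int = 0

    def validate(self) -> "InteractionRecord":
        if not self.mirna_id or not self.target_id:
            raise ValidationError("mirna_id and target_id must be non-empty")
        if self.target_class not in CERNA_CLASSES:
            raise ValidationError(
                f"unknown target_class {self.target_class!r} for "
                f"{self.mirna_id}->{self.target_id}")
        if self.clip_support < 0:
            raise ValidationError("clip_support must be nonnegative")
        return self


@dataclass(frozen=True)
class AnnotationSet:
    """One annotation term (GO, phenotype ontology, compartment, ...)
    with its gene membership."""

    term_id: str
    term_name: str
    category: str
    genes: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# low-level TSV scaffolding


def _data_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank
    lines of a TSV file."""
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            yield lineno, [f.strip() for f in row]


def _float_or_none(value: str, column: str, lineno: int) -> float | None:
    if value in ("", "NA", "NaN", "nan", "None"):
        return None
    try:
        return float(value.replace(",", ""))
    except ValueError:
        raise FormatError(
            f"line {lineno}: cannot parse {column}={value!r} as a number"
        ) from None


# ---------------------------------------------------------------------------
# DE tables


def read_de_table(
    path: str | Path,
    compartment: str,
    stage: str,
    *,
    lfc_threshold: float = 0.0,
    padj_threshold: float = 0.05,
) -> list[DERecord]:
    """Read a differential-expression TSV into validated records.

    The header must name at least ``feature_id`` and ``rna_class``, and
    either ``direction`` or both ``log2fc`` and ``padj``. When the
    ``direction`` column is absent, the call is inferred from
    ``log2fc``/``padj`` using the supplied thresholds. Row order is
    preserved.
    """
    rows = iter(_data_rows(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header row") from None

    idx = {name: i for i, name in enumerate(header)}
    for mandatory in ("feature_id", "rna_class"):
        if mandatory not in idx:
            raise FormatError(f"{path}: missing mandatory column {mandatory!r}")
    has_direction = "direction" in idx
    if not has_direction and not ("log2fc" in idx and "padj" in idx):
        raise FormatError(
            f"{path}: needs a 'direction' column or both 'log2fc' and 'padj'")

    from .concordance import infer_direction  # deferred: avoids import cycle

    records: list[DERecord] = []
    for lineno, row in rows:
        def get(col: str) -> str:
            i = idx.get(col)
            return row[i] if i is not None and i < len(row) else ""

        rec = DERecord(
            feature_id=get("feature_id"),
            rna_class=get("rna_class"),
            compartment=compartment,
            stage=stage,
            mean_ctrl=_float_or_none(get("mean_ctrl"), "mean_ctrl", lineno),
            mean_case=_float_or_none(get("mean_case"), "mean_case", lineno),
            log2fc=_float_or_none(get("log2fc"), "log2fc", lineno),
            padj=_float_or_none(get("padj"), "padj", lineno),
            direction=get("direction") if has_direction and get("direction")
            else "ns",
        )
        if not has_direction or not get("direction"):
            rec = replace(rec, direction=infer_direction(
                rec, lfc_threshold, padj_threshold))
        try:
            rec.validate()
        except ValidationError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        records.append(rec)
    return records


def write_de_table(records: Sequence[DERecord], path: str | Path) -> None:
    """Write DE records as TSV, preserving record order."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_DE_COLUMNS)
        for r in records:
            writer.writerow([
                r.feature_id, r.rna_class,
                _fmt(r.mean_ctrl), _fmt(r.mean_case),
                _fmt(r.log2fc), _fmt(r.padj), r.direction,
            ])


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return repr(value)  # repr round-trips floats exactly


# ---------------------------------------------------------------------------
# interaction tables


def read_interaction_table(path: str | Path) -> list[InteractionRecord]:
    """Read a miRNA→target interaction TSV, collapsing duplicate
    (miRNA, target) pairs to the maximum ``clip_support``.

    The first occurrence fixes a pair's position in the returned list,
    so reading is idempotent: re-reading a deduplicated dump yields the
    identical record list.
    """
    rows = iter(_data_rows(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header row") from None
    idx = {name: i for i, name in enumerate(header)}
    for mandatory in ("mirna_id", "target_id", "target_class", "clip_support"):
        if mandatory not in idx:
            raise FormatError(f"{path}: missing mandatory column {mandatory!r}")

    seen: dict[tuple[str, str], InteractionRecord] = {}
    n_rows = 0
    for lineno, row in rows:
        n_rows += 1
        try:
            support = int(row[idx["clip_support"]])
        except (ValueError, IndexError):
            raise FormatError(
                f"line {lineno}: cannot parse clip_support as an integer"
            ) from None
        rec = InteractionRecord(
            mirna_id=row[idx["mirna_id"]],
            target_id=row[idx["target_id"]],
            target_class=row[idx["target_class"]],
            clip_support=support,
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        key = (rec.mirna_id, rec.target_id)
        if key not in seen or rec.clip_support > seen[key].clip_support:
            prev = seen.get(key)
            # keep first-seen position; only the support value is lifted
            if prev is None:
                seen[key] = rec
            else:
                seen[key] = replace(prev, clip_support=rec.clip_support)
    records = list(seen.values())
    if n_rows != len(records):
        logger.info("read %d interaction rows, collapsed %d duplicates",
                    n_rows, n_rows - len(records))
    return records


def write_interaction_table(
    records: Sequence[InteractionRecord], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("mirna_id", "target_id", "target_class",
                         "clip_support"))
        for r in records:
            writer.writerow((r.mirna_id, r.target_id, r.target_class,
                             r.clip_support))


# ---------------------------------------------------------------------------
# GMT annotations


def read_gmt(path: str | Path, category: str | None = None) -> list[AnnotationSet]:
    """Read a GMT file (term, description, genes...).

    ``category`` labels every term in the file (e.g. "GO-CC",
    "Monarch"); it defaults to the file stem. Duplicate genes within a
    line collapse under set semantics.
    """
    if category is None:
        category = Path(path).stem
    terms: list[AnnotationSet] = []
    for lineno, row in _data_rows(path):
        if len(row) < 3:
            raise FormatError(
                f"line {lineno}: GMT lines need >= 3 tab-separated fields "
                f"(term, description, genes...)")
        genes = frozenset(g for g in row[2:] if g)
        if not genes:
            raise FormatError(f"line {lineno}: term {row[0]!r} has no genes")
        terms.append(AnnotationSet(term_id=row[0], term_name=row[1],
                                   category=category, genes=genes))
    return terms


def write_gmt(terms: Sequence[AnnotationSet], path: str | Path) -> None:
    """Write annotation sets as GMT; genes sorted for determinism."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for t in terms:
            writer.writerow([t.term_id, t.term_name, *sorted(t.genes)])


# ---------------------------------------------------------------------------
# derived outputs (seed sets, enrichment results)


def write_seed_set(seed_set, path: str | Path) -> None:
    """Write a seed set as a 2-column TSV plus a JSON sidecar carrying
    stage, network polarity and provenance counts."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("mirna_id", "direction"))
        for m in seed_set.members:
            writer.writerow((m, seed_set.mirna_direction))
    sidecar = {
        "stage": seed_set.stage,
        "mirna_direction": seed_set.mirna_direction,
        "cenet_polarity": seed_set.cenet_polarity,
        "n_members": len(seed_set.members),
        "n_conflicting_excluded": len(seed_set.excluded_conflicts),
        "excluded_conflicts": sorted(seed_set.excluded_conflicts),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w",
              encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_enrichment_table(terms, path: str | Path) -> None:
    """Write over-representation results as TSV; members pipe-joined."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("term_id", "term_name", "category", "k", "K", "n",
                         "N", "p_hyper", "fdr_bh", "strength", "group_id",
                         "members"))
        for t in terms:
            writer.writerow((
                t.term_id, t.term_name, t.category, t.k, t.K, t.n, t.N,
                repr(t.p_hyper), repr(t.fdr_bh), repr(t.strength),
                t.group_id, "|".join(sorted(t.members)),
            ))
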