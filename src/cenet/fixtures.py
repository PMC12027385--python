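"""Packaged worked-example fixture: concordant miRNA sets of the
APP/PSEN1 cortex / vesicle-cargo study.

The fixture reproduces the published stage-resolved cortex miRNA calls
(6- and 9-month APP/PSEN1 vs wild type, DESeq2 median-of-ratios means)
plus non-concordant decoys, and a *reconstructed* extracellular-vesicle
table: the EV-side DE lists were never published, so the EV file
carries the directions implied by the concordance rule with synthetic
expression values (see ``data/ev_mirna_synthetic.tsv``).

Expected seed-set sizes when run through
:func:`cenet.concordance.select_concordant`: 5 (6m, up), 2 (6m, down),
10 (9m, up), 6 (9m, down); the two up sets overlap only in
mmu-miR-369-5p.
"""

from __future__ import annotations

from importlib import resources

from .io_tables import DERecord, read_de_table

FIXTURE_STAGES = ("6m", "9m")


def _data_path(name: str):
    return resources.files("cenet").joinpath("data", name)


def load_table1_fixture() -> tuple[list[DERecord], dict[str, list[DERecord]]]:
    """Load the packaged fixture.

    Returns ``(ev_records, tissue_records_by_stage)`` where the EV
    table is stage-independent and the tissue dict is keyed by the
    stage labels ``6m`` and ``9m``.
    """
    with resources.as_file(_data_path("ev_mirna_synthetic.tsv")) as p:
        ev = read_de_table(p, compartment="EV", stage="all")
    tissue: dict[str, list[DERecord]] = {}
    for stage in FIXTURE_STAGES:
        with resources.as_file(
                _data_path(f"table1_tissue_mirna_{stage}.tsv")) as p:
            tissue[stage] = read_de_table(p, compartment="tissue", stage=stage)
    return ev, tissue
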