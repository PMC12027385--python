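import pytest

from cenet import DERecord, load_table1_fixture

_MEANS = {"up": (10.0, 20.0), "down": (20.0, 10.0), "ns": (10.0, 10.0)}


def make_de(feature_id, direction="up", compartment="tissue", stage="6m",
            rna_class="miRNA", **overrides):
    """A DERecord with means consistent with the requested direction."""
    ctrl, case = _MEANS[direction]
    fields = dict(feature_id=feature_id, rna_class=rna_class,
                  compartment=compartment, stage=stage,
                  mean_ctrl=ctrl, mean_case=case, direction=direction)
    fields.update(overrides)
    return DERecord(**fields)


@pytest.fixture(scope="session")
def table1():
    """Packaged worked-example fixture: (ev_records, tissue_by_stage)."""
    return load_table1_fixture()
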