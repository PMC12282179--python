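import numpy as np
import pytest

from crisprcomp.synthetic_data import build_strain_panel, demo_panel_plans


@pytest.fixture(scope="session")
def small_panel():
    """A 6-strain planted panel shared by read-level and interval tests."""
    return build_strain_panel(demo_panel_plans(6, seed=7), seed=11)


@pytest.fixture(scope="session")
def full_panel():
    """The 20-strain panel used for recall/typing/context checks."""
    return build_strain_panel(demo_panel_plans(20, seed=7), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def truth_spacers_of(truth, strain_id, contig_id, array_index):
    sp = truth.spacers
    sel = sp[
        (sp.strain_id == strain_id)
        & (sp.contig_id == contig_id)
        & (sp.array_index == array_index)
    ]
    return list(sel.sort_values("spacer_index").seq)
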