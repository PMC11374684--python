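import numpy as np
import pytest

from ductclones.io import CloneRecord, CloneTable
from ductclones.minimal import MinimalModelParams
from ductclones.synth import LabellingDesign


@pytest.fixture
def wt_params():
    return MinimalModelParams()


@pytest.fixture
def small_design():
    return LabellingDesign(n_mice=3, glands_per_mouse=2, clones_per_gland_at_induction=40)


@pytest.fixture
def tiny_table():
    records = [
        CloneRecord("m1", "m1_g1", "WT", "luminal", 14, 3, "main_duct", 0, False, "GFP"),
        CloneRecord("m1", "m1_g1", "WT", "basal", 14, 1, "side_branch", 2, False, "RFP"),
        CloneRecord("m2", "m2_g1", "BRCA1_TRP53", "luminal", 64, 40, "unknown", None, True, None),
    ]
    return CloneTable(records=records, provenance="fixture")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
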