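import dataclasses

import pytest

from sahcost import Profession, TriangularMinutes, builtin_parameters
from sahcost.parameters import WageBand


@pytest.fixture(scope="session")
def paper_config():
    return builtin_parameters()


@pytest.fixture(scope="session")
def degenerate_paper_config(paper_config):
    """Point activity times and single mean-rate wage bands: Monte Carlo
    runs collapse onto the deterministic estimate."""
    acts = tuple(
        dataclasses.replace(
            a, time=TriangularMinutes(a.time.mode, a.time.mode, a.time.mode)
        )
        for a in paper_config.activities
    )
    bands = tuple(
        WageBand(p, "mean", paper_config.wages.mean_rate(p), 100.0)
        for p in Profession
    )
    wages = dataclasses.replace(paper_config.wages, bands=bands)
    return dataclasses.replace(paper_config, activities=acts, wages=wages)


# Printed deterministic results the model reproduces (yen).
PRINTED_TOTALS_NO_SVSP = {
    ("coiling", False): 229_228.38,
    ("coiling", True): 177_885.40,
    ("clipping", False): 290_971.93,
    ("clipping", True): 239_628.95,
}
PRINTED_TOTALS_SVSP = {
    ("coiling", False): 602_564.35,
    ("coiling", True): 563_409.00,
    ("clipping", False): 646_533.30,
    ("clipping", True): 607_377.95,
}
PRINTED_ARM_DIFFERENCE = {False: 51_342.98, True: 39_155.35}  # by svsp status
PRINTED_PROFESSION_DIFFERENCE = {
    False: {"physician": 13_824.68, "nurse": 37_518.29, "radiographer": 0.0},
    True: {"physician": 5_924.86, "nurse": 33_230.49, "radiographer": 0.0},
}
PRINTED_GRADE_DIFFERENCE = {
    False: {"resident": 6_476.73, "specialist": 14_329.49, "trainer": 19_486.08},
    True: {"resident": 2_775.74, "specialist": 6_141.21, "trainer": 8_351.18},
}
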