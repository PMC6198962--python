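import numpy as np
import pytest

from chlorotyping import FOUR_SITE_PANEL, SyntheticSpec, default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture()
def small_spec():
    """Four named haplotypes on the 4-site panel, two groups."""
    return SyntheticSpec(
        haplotypes=[("H1", "0101"), ("H2", "0011"), ("H3", "1110"), ("H4", "0111")],
        groups=[
            ("florida", 8, {"H1": 0.5, "H2": 0.25, "H4": 0.25}),
            ("kousa", 4, {"H3": 1.0}),
        ],
        panel=FOUR_SITE_PANEL,
        seed=11,
    )


def random_sequence(rng, n):
    return "".join(rng.choice(list("ACGT"), n))
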