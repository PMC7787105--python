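"""Shared fixtures: synthetic ring crystals at two scales.

``tiny_case`` is a fast C5 ring used by unit tests; the ``mini`` cases are
the portal-like C13/C12 fixtures used by the end-to-end and acceptance
tests. All are session-scoped: they are deterministic functions of their
parameters and seed, and building them dominates test runtime.
"""

import numpy as np
import pytest
from hypothesis import settings

from cyclophase import synthetic

# property tests must behave identically on every run/machine
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_case():
    """Small C5 ring crystal: fast enough for per-module tests."""
    return synthetic.make_ring_case(
        n=5, n_res=45, n_helices=3, ring_radius=20.0, cell_padding=18.0,
        partial_fraction=0.5, d_min=4.0, seed=11,
    )


@pytest.fixture(scope="session")
def mini_case():
    """The portal-like C13 case (scaled-down ring, 36% partial model)."""
    return synthetic.make_preset("portal-mini", seed=7)


@pytest.fixture(scope="session")
def mini_c12_case():
    """The dodecameric analog of the mini case."""
    return synthetic.make_preset("c12-mini", seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
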