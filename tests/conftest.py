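import warnings

import pytest

import xlrefine as xr
from xlrefine.restraints import Linker


@pytest.fixture(scope="session")
def compact_model():
    """Ground-truth compact toy tetramer (fixed seed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return xr.make_toy_tetramer(xr.SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def extended_model():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return xr.make_toy_tetramer(
            xr.SyntheticSpec(tail_mode="extended", seed=42))


@pytest.fixture(scope="session")
def compact_sasa(compact_model):
    return xr.sasa(xr.add_pseudo_side_chains(compact_model))


@pytest.fixture(scope="session")
def evidence(compact_model):
    """Cross-links (12 BS2G + 21 DSBU) simulated from the compact ground truth."""
    bs2g = xr.simulate_crosslinks(compact_model, Linker.BS2G, 12, seed=1)
    dsbu = xr.simulate_crosslinks(compact_model, Linker.DSBU, 21, seed=2)
    return bs2g, dsbu


@pytest.fixture(scope="session")
def footprint_sites(compact_model, compact_sasa):
    return xr.simulate_footprinting(compact_model, compact_sasa,
                                    noise_cv=0.2, seed=7)
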