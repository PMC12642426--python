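"""Shared fixtures: small seeded reference sets and simulations."""

import numpy as np
import pytest

import arraykit.simulate as sim


@pytest.fixture(scope="session")
def small_refs():
    """Compact reference set: 150 kb pseudo-stuffer, 40 kb host."""
    return sim.make_references(seed=101, stuffer_len=150_000, host_len=40_000)


@pytest.fixture(scope="session")
def small_shear():
    """Shear bounds that fit the 150 kb stuffer."""
    return sim.ShearParams(max_len=50_000)


@pytest.fixture(scope="session")
def small_sim(small_refs, small_shear):
    """One deterministic assembled-and-integrated run (N=200, no dups)."""
    mix = sim.default_mix(small_refs, n_fragments=200, seed=202,
                          shear_params=small_shear)
    return sim.simulate_run(mix, references=small_refs)


@pytest.fixture(scope="session")
def payload_refs(small_refs):
    return [small_refs[k] for k in ("pseudo_stuffer", "hygR_attP", "yfp_tg")]


@pytest.fixture()
def rng():
    return np.random.default_rng(4242)
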