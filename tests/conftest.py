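import io

import pytest

import rwrmtn as rw


@pytest.fixture(scope="session")
def tiny_iset():
    """Three miRNAs with overlapping target sets, built by hand."""
    txt = (
        "mir-a\tG1\nmir-a\tG2\nmir-a\tG3\n"
        "mir-b\tG2\nmir-b\tG3\nmir-b\tG4\nmir-b\tG5\n"
        "mir-c\tG9\n"
    )
    return rw.parse_interactions(io.StringIO(txt))


@pytest.fixture(scope="session")
def planted():
    """Default planted-module fixture shared across test modules."""
    spec = rw.FixtureSpec(rng_seed=1)
    base = rw.generate_interactions(spec)
    interactions, assoc, truth = rw.plant_module(base, spec)
    return spec, interactions, assoc, truth


@pytest.fixture(scope="session")
def planted_hetero(planted):
    _, interactions, _, _ = planted
    return rw.build_heterogeneous(interactions, "mutual")


@pytest.fixture(scope="session")
def planted_homo(planted):
    _, interactions, _, _ = planted
    return rw.build_homogeneous(interactions)
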