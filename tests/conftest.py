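"""Shared fixtures: one synthetic reference set reused across the suite."""

import pytest

import kinsert as K


@pytest.fixture(scope="session")
def refs():
    """Synthetic study references (printed flank/fragment lengths)."""
    return K.synthetic_references(seed=11)


@pytest.fixture(scope="session")
def categories(refs):
    return K.enumerate_categories(refs.library, refs.locus)


@pytest.fixture(scope="session")
def flank_probes(refs):
    return refs.flank_probes()


@pytest.fixture(scope="session")
def comp_probes(refs):
    return refs.component_probes()


@pytest.fixture(scope="session")
def panel(refs):
    return refs.panel()


@pytest.fixture(scope="session")
def cat_by_name(categories):
    return {c.name: c for c in categories}
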