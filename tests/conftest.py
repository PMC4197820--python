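import pytest

from mirededit import synthetic


@pytest.fixture(scope="session")
def bundle3():
    """Three species, six families; default divergence and strand mix."""
    return synthetic.generate_reference(3, 6, seed=7)


@pytest.fixture(scope="session")
def bundle1():
    """Single species, four families; minimal alignment target."""
    return synthetic.generate_reference(1, 4, seed=5)


@pytest.fixture()
def edited_mirna(bundle1):
    """(record, edit position) for the first mature miRNA of bundle1."""
    rec = next(a for a in bundle1.annotations if a.arm == "mature")
    pos = bundle1.family_edit_sites[rec.family_id]
    assert rec.sequence[pos - 1] == "A"
    return rec, pos
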