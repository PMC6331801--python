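import pytest

from protostane.io import library_features, load_contents, load_curves, load_library, load_lods


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def packaged_features(library):
    """The 25 packaged library records rendered as features, as printed."""
    return library_features(library)


@pytest.fixture(scope="session")
def contents():
    return load_contents()


@pytest.fixture(scope="session")
def curves():
    return load_curves()


@pytest.fixture(scope="session")
def lods():
    return load_lods()
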