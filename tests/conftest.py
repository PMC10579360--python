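import pytest

from mimicryscan.matrices import load_matrix


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def study_bundle():
    """One default synthetic study, shared across tests."""
    from mimicryscan.synthetic import SyntheticSpec, generate_study

    return generate_study(SyntheticSpec(seed=1))


@pytest.fixture()
def study_dir(study_bundle, tmp_path):
    from mimicryscan.synthetic import write_study

    return write_study(study_bundle, tmp_path / "study")
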