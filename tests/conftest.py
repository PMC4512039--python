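import pytest
from hypothesis import settings

from famprio import datasets

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


QUAD_PED_TEXT = """\
FAM1 sibA father mother 1 2
FAM1 sibB father mother 1 2
FAM1 father 0 0 1 1
FAM1 mother 0 0 2 1
"""


@pytest.fixture
def quad_ped_text():
    return QUAD_PED_TEXT


@pytest.fixture
def quad_pedigree():
    return datasets.quad_pedigree()


@pytest.fixture
def table_family():
    """The worked-example quad: genotypes + annotations + pedigree."""
    return (
        datasets.quad_genotypes(),
        datasets.quad_pedigree(),
        datasets.quad_annotations(),
    )
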