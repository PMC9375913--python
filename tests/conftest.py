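import pytest

from orfvar import annotate_variants, build_fixture_hey2


@pytest.fixture(scope="session")
def hey2():
    """(bundle, variants) for the dual-coding HEY2 locus fixture."""
    return build_fixture_hey2()


@pytest.fixture(scope="session")
def hey2_records(hey2):
    bundle, variants = hey2
    records, warnings = annotate_variants(variants, bundle)
    assert not warnings
    return records
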