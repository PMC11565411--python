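import pytest

from hipscreen.library import Library, LibraryEntry
from hipscreen.proinsulin import canonical_proinsulin


@pytest.fixture(scope="session")
def proinsulin():
    return canonical_proinsulin()


def make_dummy_library(n: int) -> Library:
    """A library of n distinct placeholder members (for pooling tests that
    only need ids, not real candidate provenance)."""
    entries = tuple(
        LibraryEntry(member_id=f"m{i:05d}", sequence=f"SEQ{i:05d}", provenances=())
        for i in range(n)
    )
    return Library(entries=entries)


@pytest.fixture(scope="session")
def paper_scale_library():
    from hipscreen.scenario import paper_scale_library as build

    return build()
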