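import hypothesis
import pytest

from varscreen.model import GenomeIndex

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def genome() -> GenomeIndex:
    return GenomeIndex.from_pairs([("chr1", 100_000), ("plasmid", 20_000)])


@pytest.fixture
def big_genome() -> GenomeIndex:
    return GenomeIndex.from_pairs([("chr1", 10_000_000)])
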