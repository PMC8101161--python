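import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from factories import build_collection, build_degs  # noqa: E402


@pytest.fixture
def make_collection():
    """Factory: {set_id: members} -> GeneSetCollection."""
    return build_collection


@pytest.fixture
def make_degs():
    """Factory: {gene_id: log2fc} -> DEGTable with uniform small q-values."""
    return build_degs
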