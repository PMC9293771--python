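import re

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# independent regex oracles for the two consensus rules (lookahead so
# overlapping windows are all found)
REVISED_RE = re.compile(r"(?=(C.[DN]....[FY].C))")
LEGACY_RE = re.compile(r"(?=(C.[DN]....[FY].C.C))")


def oracle_sites(sequence: str, rule: str) -> set[tuple[int, int]]:
    """(ring_start, site_position) pairs, 1-based, from the regex oracle."""
    rx = LEGACY_RE if rule == "legacy" else REVISED_RE
    return {(m.start() + 1, m.start() + 3) for m in rx.finditer(sequence)}


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_protein(rng, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))
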