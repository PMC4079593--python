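import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mthapnet.refcoords import (
    CircularReference,
    HaplotypeAlignment,
    RefPosition,
)

REF_LENGTH = 16357


@pytest.fixture(scope="session")
def small_reference() -> CircularReference:
    """A deterministic 240 bp circular reference used where real
    coordinates are not needed."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=240))
    return CircularReference(id="synthref", seq=seq)


@pytest.fixture()
def gapped_alignment() -> HaplotypeAlignment:
    """Four haplotypes over positions 16197..16200 plus an insertion column
    15581.1 placed (artificially) at the start, mirroring the two indel
    situations of interest: a deletion column to drop and a whitelisted
    insertion column to keep."""
    # columns: 15581.1 | 16197 | 16198 | 16199 | 16200
    colmap = [
        RefPosition(15581, 1),
        RefPosition(16197),
        RefPosition(16198),
        RefPosition(16199),
        RefPosition(16200),
    ]
    labels = ["h1", "h2", "h3", "h4"]
    rows = [
        "TACTA",
        "GACTA",
        "-AC-A",
        "-ACTA",
    ]
    return HaplotypeAlignment(labels=labels, rows=rows, colmap=colmap)
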