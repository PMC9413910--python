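import numpy as np
import pytest

from ubcs.core import ClusterParams
from ubcs.snd import Derivation, SubstitutionCatalog


@pytest.fixture
def params() -> ClusterParams:
    return ClusterParams()


def make_catalog(
    positions,
    biased,
    length: int | None = None,
    chromosome: str = "1",
    direction: Derivation = Derivation.TARGET,
) -> SubstitutionCatalog:
    """Small single-chromosome catalog for constructed examples."""
    pos = np.asarray(positions, dtype=np.int64)
    lab = np.asarray(biased, dtype=bool)
    if length is None:
        length = int(pos[-1]) + 1000 if pos.size else 1000
    return SubstitutionCatalog(
        direction=direction,
        chromosome_lengths={chromosome: length},
        positions={chromosome: pos},
        biased={chromosome: lab},
    )


@pytest.fixture
def make_cat():
    return make_catalog
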