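import numpy as np
import pytest

from cerealcas import amplicon_caller as ac
from cerealcas import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240813)


@pytest.fixture
def locus():
    """300-nt toy locus with the cut site at position 100."""
    ref = str(fixtures.make_reference(300, 0.45, seed=7).seq)
    return ac.LocusSpec.around_cut_site("chr6Hg0653951", ref, cut_site=100)
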