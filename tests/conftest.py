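import numpy as np
import pytest

import strclock as sc
from strclock.io import Haplotype, HaplotypeSet, LocusPanel


@pytest.fixture(scope="session")
def panel37():
    return sc.default_panel()


@pytest.fixture
def panel3():
    return LocusPanel(("A", "B", "C"), 0.0039)


def make_set(panel, states, populations=None, branches=None, ids=None,
             ancient=None) -> HaplotypeSet:
    """Build a HaplotypeSet from per-sample state vectors (lists over panel
    columns; None = missing)."""
    haps = []
    for i, st in enumerate(states):
        vec = np.array([np.nan if v is None else float(v) for v in st])
        haps.append(Haplotype(
            sample_id=ids[i] if ids else f"s{i:03d}",
            repeats=panel.decode(vec),
            population=populations[i] if populations else "pop",
            snp_branch=branches[i] if branches else "",
            ancient=bool(ancient[i]) if ancient else False,
        ))
    return HaplotypeSet(panel, haps)


@pytest.fixture
def make_hs():
    return make_set
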