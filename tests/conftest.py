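import numpy as np
import pandas as pd
import pytest

import hybridscan as hs
from hybridscan.containers import AncestryGenotypeMatrix


@pytest.fixture(scope="session")
def two_group_map():
    return hs.GenomeMap([("g1", 5_000_000), ("g2", 5_000_000)])


@pytest.fixture(scope="session")
def planted_pair_setup():
    """Two populations sharing one selected incompatibility pair.

    Used by the end-to-end recovery and conspecific-excess checks: four
    linkage groups, markers every 200 kb, selection against all hybrid
    genotype combinations (s = 0.35) at g1:1.3 Mb x g2:1.5 Mb, ten
    generations after the pulse.  The symmetric variant is used because
    one-directional BDM selection purges the incompatible alleles before
    building large LD (see the deterministic recursion), which would leave
    nothing to recover.
    """
    gmap = hs.GenomeMap(
        [(f"g{i}", 2_400_000) for i in range(1, 5)]
    ).uniform_markers(200_000, offset_bp=100_000)
    inc = hs.IncompatibilitySpec(
        ("g1", 1_300_000), ("g2", 1_500_000), "ALL_HYBRID", 0.35
    )
    pops = []
    for admix_p, seed in ((0.5, 33), (0.48, 8)):
        scen = hs.HybridZoneScenario(
            admix_p=admix_p, T_gen=10, N=800, incompatibilities=(inc,), seed=seed
        )
        pops.append(scen)
    return gmap, inc, pops


def iid_dosage_matrix(n_ind, markers, p, rng):
    """Independent HWE-ish dosage matrix over the given marker IDs."""
    data = rng.binomial(2, p, size=(n_ind, len(markers))).astype(float)
    return AncestryGenotypeMatrix(
        pd.DataFrame(data, index=[f"i{k}" for k in range(n_ind)], columns=list(markers))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
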