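import numpy as np
import pytest

from cyclopep.anneal import AnnealingSchedule
from cyclopep.builder import build_linear_peptide
from cyclopep.core import PeptideSpec


@pytest.fixture(scope="session")
def gly6_spec():
    return PeptideSpec("GGGGGG", "backbone", "charged_termini")


@pytest.fixture(scope="session")
def ss_spec():
    return PeptideSpec("ACGCAK", "disulfide", "charged_termini", (2, 4))


@pytest.fixture(scope="session")
def combined_spec():
    return PeptideSpec("ACGGGGCA", "combined", "charged_termini", (2, 7))


@pytest.fixture(scope="session")
def gly6_starts(gly6_spec):
    return [build_linear_peptide(gly6_spec, s) for s in ("beta", "polypro")]


@pytest.fixture(scope="session")
def tiny_schedule():
    """Heavily reduced annealing for unit tests (two dozen steps/phase)."""
    return AnnealingSchedule.cyclization(step_scale=0.012)


@pytest.fixture(scope="session")
def tiny_schedule_step3():
    return AnnealingSchedule.cyclization(step_scale=0.012, restraints_in_all=False)


def heavy_clashes(conf, min_dist=1.8):
    """Non-bonded heavy-atom pairs closer than ``min_dist`` Å."""
    from scipy.spatial.distance import pdist, squareform
    heavy = np.flatnonzero(conf.heavy_mask)
    d = squareform(pdist(conf.coords[heavy]))
    bonded = set(map(tuple, np.sort(conf.bonds, axis=1).tolist()))
    out = []
    for a in range(len(heavy)):
        for b in range(a + 1, len(heavy)):
            if d[a, b] < min_dist and (heavy[a], heavy[b]) not in bonded:
                out.append((int(heavy[a]), int(heavy[b]), float(d[a, b])))
    return out
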