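import numpy as np
import pytest

from bandscan import LoopDefinition, select
from bandscan.synthetic import HingeComplexSpec, make_hinge_complex


@pytest.fixture(scope="session")
def hinge():
    """One deterministic toy hinge complex shared across tests.

    Returns (structure, truth) where truth carries planted site labels, the
    loop definition fields, and the probe-atom address.
    """
    return make_hinge_complex(HingeComplexSpec(seed=1))


@pytest.fixture(scope="session")
def hinge_loop(hinge):
    _, truth = hinge
    lo, hi = truth["loop"]["res_range"]
    return LoopDefinition(truth["loop"]["chain_id"], lo, hi,
                          truth["loop"]["attached_selection"])


@pytest.fixture(scope="session")
def hinge_parts(hinge, hinge_loop):
    """Convenience bundle: sg index, moving mask indices, POI AtomSet."""
    s, truth = hinge
    sg = s.find_atom(**truth["cys_sg"])
    moving = np.flatnonzero(hinge_loop.attached_mask(s)
                            | ((s.chain_id == hinge_loop.chain_id)
                               & (s.res_seq > hinge_loop.res_start)))
    poi = select(s, truth["poi_selection"])
    return {"sg": sg, "moving": moving, "poi": poi}
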