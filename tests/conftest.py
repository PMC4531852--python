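import numpy as np
import pytest

from gssualign.gssu import decompose
from gssualign.superpose import AlignParams
from gssualign.synthetic import (HairpinSpec, SynthSpec, make_hairpin,
                                 make_helix, make_multi_hairpin)


@pytest.fixture
def params():
    return AlignParams()


@pytest.fixture
def hairpin():
    """5-bp stem, 4-nt loop hairpin with its ground-truth pairs."""
    return make_hairpin(5, 4, structure_id="hp")


@pytest.fixture
def helix():
    """Blunt 6-bp duplex (two chains) with ground-truth pairs."""
    return make_helix(6, structure_id="hx")


@pytest.fixture
def three_hairpin():
    """Cloverleaf-like chain of three hairpins joined by linkers."""
    spec = SynthSpec([HairpinSpec(5, 4), HairpinSpec(4, 5), HairpinSpec(6, 3)],
                     linker_nt=[4, 4])
    return make_multi_hairpin(spec, structure_id="clover")


@pytest.fixture
def decomposed_hairpin(hairpin):
    s, pairs = hairpin
    return s, pairs, decompose(s, pairs)


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus a bounded translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


def random_topology_structure(rng, max_gssus=3, max_loop=8, structure_id="rand"):
    """Random multi-hairpin chain: known topology, random dimensions."""
    k = int(rng.integers(1, max_gssus + 1))
    hairpins = [HairpinSpec(int(rng.integers(2, 5)),
                            int(rng.integers(3, max_loop + 1)))
                for _ in range(k)]
    linkers = [int(rng.integers(2, 6)) for _ in range(k - 1)]
    spec = SynthSpec(hairpins, linker_nt=linkers)
    return make_multi_hairpin(spec, structure_id=structure_id)
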