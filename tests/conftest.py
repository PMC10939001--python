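import numpy as np
import pytest

import glycosurf as g
from glycosurf.coordinates import measure_dihedral


@pytest.fixture(scope="session")
def xylose():
    return g.make_sugar("xylose_4C1")


@pytest.fixture(scope="session")
def xylose_1c4():
    return g.make_sugar("xylose_1C4")


@pytest.fixture(scope="session")
def xylotetraose():
    return g.make_sugar("xylotetraose")


@pytest.fixture(scope="session")
def diol():
    return g.make_sugar("diol")


@pytest.fixture(scope="session")
def small_slab():
    return g.build_slab(g.SlabSpec(3.632, 4, 4, 2, 60.0, 1))


@pytest.fixture(scope="session")
def toy_system():
    from glycosurf.workflow import make_toy_system
    return make_toy_system()


def current_vector(space, template):
    """The reduced vector matching a template's current geometry."""
    x = []
    for v in space.variables:
        if v.tag == "dihedral":
            d = v.payload
            x.append(measure_dihedral(template.positions, d.i, d.j, d.k, d.l))
        elif v.tag == "ringflip_coord":
            ring, which = v.payload
            a = ring.atoms
            if which == 0:
                x.append(measure_dihedral(template.positions, a[0], a[1], a[2], a[3]))
            else:
                x.append(measure_dihedral(template.positions, a[3], a[4], a[5], a[0]))
        else:
            raise ValueError(v.tag)
    return np.array(x)


def numerical_forces(calc, s, h=1e-5):
    f = np.zeros_like(s.positions)
    for i in range(len(s)):
        for c in range(3):
            sp = s.copy()
            sp.positions[i, c] += h
            sm = s.copy()
            sm.positions[i, c] -= h
            f[i, c] = -(calc.evaluate(sp)[0] - calc.evaluate(sm)[0]) / (2 * h)
    return f
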