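"""Shared fixtures: small hand-built trees and simulated/synthetic targets."""

import numpy as np
import pytest

import treeclone as tc


def make_chain(n=5, length=0.2, radius=0.05, direction=(0.0, 0.0, 1.0)):
    """Straight chain of n cylinders along a fixed direction."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    cyls = []
    start = np.zeros(3)
    for k in range(n):
        cyls.append(
            tc.Cylinder(start=start.copy(), axis=d.copy(), length=length,
                        radius=radius, parent=None if k == 0 else k - 1)
        )
        start = start + length * d
    return tc.Tree.from_cylinders(cyls)


def make_junction(child_radii=(0.05, 0.03), child_angles_deg=(30.0, 60.0)):
    """Vertical trunk cylinder with two tilted children at its tip."""
    cyls = [tc.Cylinder(start=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]),
                        length=1.0, radius=0.10, parent=None)]
    tip = np.array([0.0, 0.0, 1.0])
    for r, ang in zip(child_radii, child_angles_deg):
        a = np.radians(ang)
        axis = np.array([np.sin(a), 0.0, np.cos(a)])
        cyls.append(tc.Cylinder(start=tip.copy(), axis=axis, length=0.5,
                                radius=r, parent=0))
    return tc.Tree.from_cylinders(cyls)


@pytest.fixture(scope="session")
def fractal_tree():
    return tc.make_fractal_target(tc.SyntheticSpec(depth=5))


@pytest.fixture(scope="session")
def sot_tree():
    """One reduced-size simulated tree shared across tests."""
    return tc.simulate(tc.small_sot_params(), seed=11)


@pytest.fixture(scope="session")
def sot_target():
    tree, params = tc.make_sot_target(seed=7)
    return tree, params


@pytest.fixture(scope="session")
def dirs4():
    return tc.generate_directions(4, 256)


@pytest.fixture(scope="session")
def dirs5():
    return tc.generate_directions(5, 256)
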