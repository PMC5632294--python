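"""Synthetic QSM-like targets for testing the pipeline without scan data.

Two target kinds:

* a deterministic recursive fractal tree with closed-form height, girth
  and crown spread and pipe-consistent radii — exact oracles for the
  classical metrics and feature extraction;
* a self-target: a tree simulated by the growth model, returned together
  with its generating parameters, so inverse fitting can be exercised
  against a target whose true parameters are known.

``corrupt_tree`` perturbs radii and axis directions (propagating positions
so attachment is preserved), emulating measurement and reconstruction
noise on an otherwise clean structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .qsm import Cylinder, Tree, assign_orders
from .sot import SOTParams, simulate, update_radii

__all__ = [
    "SyntheticSpec",
    "make_fractal_target",
    "make_sot_target",
    "corrupt_tree",
    "small_sot_params",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic target tree."""

    kind: str = "deterministic_fractal"   # or "sot_self_target"
    depth: int = 5                        # bifurcation levels
    branching_angle_deg: float = 35.0
    length_decay: float = 0.75            # child length / parent length
    trunk_length: float = 2.0             # m
    tip_radius: float = 0.01              # m
    pipe_exponent: float = 2.0
    noise: float = 0.0                    # angular jitter, deg sd
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0.0 < self.length_decay <= 1.0):
            raise ValueError("length_decay must lie in (0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    a = axis / np.linalg.norm(axis)
    return (
        v * math.cos(angle_rad)
        + np.cross(a, v) * math.sin(angle_rad)
        + a * np.dot(a, v) * (1.0 - math.cos(angle_rad))
    )


def _perp_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(abs(d[0]) - 1.0) < 1e-6:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - d * np.dot(ref, d)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def make_fractal_target(spec: SyntheticSpec) -> Tree:
    """Deterministic bifurcating fractal tree.

    Level 0 is a single vertical trunk cylinder of ``trunk_length``; each
    cylinder at level k < depth-1 spawns two children tilted by the
    branching angle at opposite azimuths (rotated 90 degrees per level),
    with lengths scaled by ``length_decay``.  Radii follow the pipe model;
    ``noise > 0`` adds seeded Gaussian jitter to the branching angles.
    """
    if spec.depth < 1:
        raise ValueError("invalid spec: depth must be >= 1")
    rng = np.random.default_rng(spec.seed)
    cyls: list[Cylinder] = []

    def build(start, direction, length, level, parent):
        idx = len(cyls)
        cyls.append(
            Cylinder(
                start=np.asarray(start, float),
                axis=np.asarray(direction, float),
                length=float(length),
                radius=spec.tip_radius,  # placeholder; pipe model fills in
                parent=parent,
            )
        )
        if level + 1 >= spec.depth:
            return
        tip = np.asarray(start, float) + length * np.asarray(direction, float)
        e1, e2 = _perp_frame(direction)
        twist = math.radians(90.0 * level)
        for sign in (+1.0, -1.0):
            ang = math.radians(spec.branching_angle_deg)
            if spec.noise > 0:
                ang += math.radians(spec.noise * rng.standard_normal())
            lateral = math.cos(twist) * e1 + math.sin(twist) * e2
            child_dir = _rotate(direction, np.cross(direction, lateral), sign * ang)
            child_dir = child_dir / np.linalg.norm(child_dir)
            build(tip, child_dir, length * spec.length_decay, level + 1, idx)

    build(np.zeros(3), np.array([0.0, 0.0, 1.0]), spec.trunk_length, 0, None)
    tree = Tree.from_cylinders(cyls, meta={"source": "fractal", "seed": spec.seed})
    tree = update_radii(tree, spec.pipe_exponent, spec.tip_radius)
    tree = assign_orders(tree, force=True)
    tree.validate(check_attachment=True)
    return tree


def small_sot_params(**overrides) -> SOTParams:
    """Reduced-size growth parameters for fast experiments.

    A 6 m arena and about ten growth iterations give trees of a few
    hundred segments — large enough for stable feature tables, small
    enough for optimization loops.
    """
    base = dict(
        n_iterations=10,
        initial_metamers=3,
        arena_extent=6.0,
        max_order=4,
    )
    base.update(overrides)
    return SOTParams(**base)


def make_sot_target(
    params: Optional[SOTParams] = None, seed: int = 1
) -> tuple[Tree, SOTParams]:
    """Simulated self-target: a tree plus the parameters that generated it.

    Re-simulating with the returned (params, seed) reproduces the tree
    bit-for-bit, so the inverse machinery can be validated by recovering
    known parameters.
    """
    params = params or small_sot_params()
    tree = simulate(params, seed)
    return tree, params


def corrupt_tree(tree: Tree, noise: float, seed: int = 0) -> Tree:
    """Jitter radii and axis directions while preserving topology.

    Radii are scaled by ``1 + noise * N(0,1)`` (clipped to stay positive)
    and each axis is tilted by a random angle of magnitude ``~noise`` rad;
    cylinder starts are recomputed parent-to-child so children stay
    attached.  ``noise = 0`` returns an identical tree.
    """
    out = tree.copy()
    if noise == 0:
        return out
    rng = np.random.default_rng(seed)
    n = len(out)

    factors = np.clip(1.0 + noise * rng.standard_normal(n), 0.05, None)
    out.radius = out.radius * factors

    for i in range(n):
        d = out.axis[i]
        e1, e2 = _perp_frame(d)
        ang = noise * rng.standard_normal()
        azim = rng.uniform(0.0, 2.0 * math.pi)
        tilt_axis = math.cos(azim) * e1 + math.sin(azim) * e2
        nd = _rotate(d, tilt_axis, ang)
        out.axis[i] = nd / np.linalg.norm(nd)

    # re-chain starts so each child sits on its parent's tip
    order = []
    kids = out.children()
    stack = [out.root]
    while stack:
        j = stack.pop()
        order.append(j)
        stack.extend(kids[j])
    for j in order:
        p = int(out.parent[j])
        if p >= 0:
            out.start[j] = out.start[p] + out.length[p] * out.axis[p]
    out.meta = dict(out.meta, corrupted_noise=noise)
    return out
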