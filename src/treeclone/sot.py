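"""Self-organizing tree growth simulator (the stochastic structure model).

The simulator grows a tree of fixed-length metamers (segments) inside a
cubic arena on a voxel lattice.  Each iteration:

1. every metamer tip casts shadow into an inverted voxel pyramid below it
   (increment ``a * b**(-q)`` at depth ``q``), approximating mutual shading;
2. every bud reads its light exposure ``Q`` from the grid (own shadow
   removed, clamped at zero, scaled by a vertical light gradient);
3. exposures are aggregated basipetally (tips to root) and the collected
   resource is reallocated acropetally with an extended Borchert–Honda
   rule in which the dimensionless parameter ``lambda`` biases the split
   toward the terminal (apical dominance) or the laterals;
4. each bud converts its resource into ``floor(resource_coeff * v)`` new
   metamers of fixed length, oriented by branching/divergence angles,
   tropism, and stochastic angle noise.

After the last iteration, radii are assigned by the pipe model
(``r_parent**e = sum(r_child**e)``, tips at ``tip_radius``) and Gravelius
orders by the thickest-branch rule shared with QSM imports.

The model has 27 growth parameters: 23 grouped into five groups
(I growth/pipe, II environment, III apical dominance, IV shadow
propagation, V angular) and 4 fixed (segment length 0.2 m, voxel size
0.2 m, a 12 m cubic arena, and the base position at the center of the
arena floor).

Randomness is counter-based: a Philox stream keyed by (seed, iteration)
drives per-bud draws indexed by metamer id, so growth is reproducible and
independent of bud evaluation order.  The same (params, seed) always
yields a bit-identical cylinder table — the contract the inverse
optimization relies on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .qsm import Tree, assign_orders

__all__ = [
    "SOTParams",
    "ShadowGrid",
    "cast_shadow",
    "light_exposure",
    "allocate_resource",
    "GrowthState",
    "grow_step",
    "update_radii",
    "simulate",
]

logger = logging.getLogger(__name__)

#: metamers a single bud may add in one iteration (guards runaway growth)
_MAX_SHOOT = 10


@dataclass(frozen=True)
class SOTParams:
    """Grouped growth parameters of the self-organizing tree model.

    23 grouped parameters in five groups plus 4 fixed ones (27 total).
    Angles are degrees, lengths meters; ``apical_lambda`` is dimensionless
    in [0, 1].
    """

    # -- group I: initial growth and pipe model --------------------------
    n_iterations: int = 20          # growth cycles
    initial_metamers: int = 3       # vertical metamers planted before cycle 1
    resource_coeff: float = 1.2     # metamers produced per unit resource
    pipe_exponent: float = 2.0      # e in r_p**e = sum r_c**e
    tip_radius: float = 0.004       # m, radius of unbranched tips
    max_order: int = 5              # laterals beyond this order are suppressed

    # -- group II: environment -------------------------------------------
    shading_sensitivity: float = 1.0   # weight of accumulated shadow in Q
    light_gradient: float = 0.3        # vertical gain of exposure, per arena height
    tropism_strength: float = 0.10     # blend weight of the tropism direction
    tropism_elevation_deg: float = 90.0  # tropism direction: 90 = straight up
    tropism_azimuth_deg: float = 0.0

    # -- group III: apical dominance -------------------------------------
    apical_lambda: float = 0.52     # resource bias toward terminal buds, [0, 1]
    bud_break_prob: float = 0.6     # per-iteration chance a dormant lateral activates
    shed_threshold: float = 0.02    # lateral buds with Q below this abort

    # -- group IV: shadow propagation ------------------------------------
    shadow_a: float = 0.1           # increment at the bud's own voxel
    shadow_b: float = 2.0           # per-layer decay base
    base_exposure: float = 1.0      # C, full-light exposure
    shadow_depth: int = 4           # pyramid depth in voxel layers

    # -- group V: angular / branching ------------------------------------
    branching_angle_mean_deg: float = 40.0
    branching_angle_spread_deg: float = 8.0
    divergence_angle_deg: float = 137.5   # phyllotactic azimuth advance
    divergence_spread_deg: float = 15.0
    angle_noise_kind: str = "normal"      # "normal" | "uniform"

    # -- fixed ------------------------------------------------------------
    segment_length: float = 0.2     # m
    voxel_size: float = 0.2         # m
    arena_extent: float = 12.0      # m, cubic arena edge
    base_position: tuple = (0.0, 0.0, 0.0)  # center of the arena floor

    def __post_init__(self):
        if not (0.0 <= self.apical_lambda <= 1.0):
            raise ValueError("apical_lambda must lie in [0, 1]")
        if self.segment_length <= 0 or self.voxel_size <= 0:
            raise ValueError("segment_length and voxel_size must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.angle_noise_kind not in ("normal", "uniform"):
            raise ValueError("angle_noise_kind must be 'normal' or 'uniform'")

    GROUPS = {
        "I": ["n_iterations", "initial_metamers", "resource_coeff",
              "pipe_exponent", "tip_radius", "max_order"],
        "II": ["shading_sensitivity", "light_gradient", "tropism_strength",
               "tropism_elevation_deg", "tropism_azimuth_deg"],
        "III": ["apical_lambda", "bud_break_prob", "shed_threshold"],
        "IV": ["shadow_a", "shadow_b", "base_exposure", "shadow_depth"],
        "V": ["branching_angle_mean_deg", "branching_angle_spread_deg",
              "divergence_angle_deg", "divergence_spread_deg", "angle_noise_kind"],
    }
    FIXED = ["segment_length", "voxel_size", "arena_extent", "base_position"]
    INTEGER_PARAMS = ("n_iterations", "initial_metamers", "max_order", "shadow_depth")

    def with_values(self, **kw) -> "SOTParams":
        for k in ("n_iterations", "initial_metamers", "max_order", "shadow_depth"):
            if k in kw:
                kw[k] = int(round(kw[k]))
        return replace(self, **kw)


# ---------------------------------------------------------------------- #
# shadow grid
# ---------------------------------------------------------------------- #

class ShadowGrid:
    """Scalar shadow field on the voxel lattice of the cubic arena.

    x and y span [-E/2, E/2], z spans [0, E].  All values are >= 0 and an
    empty scene is all zeros.
    """

    def __init__(self, extent: float, voxel: float, a: float, b: float, depth: int):
        self.extent = float(extent)
        self.voxel = float(voxel)
        self.a = float(a)
        self.b = float(b)
        self.depth = int(depth)
        m = int(round(extent / voxel))
        self.shape = (m, m, m)
        self.values = np.zeros(self.shape)

    def reset(self) -> None:
        self.values.fill(0.0)

    def voxel_index(self, point: np.ndarray) -> tuple[int, int, int]:
        m = self.shape[0]
        half = self.extent / 2.0
        i = int(np.floor((point[0] + half) / self.voxel))
        j = int(np.floor((point[1] + half) / self.voxel))
        k = int(np.floor(point[2] / self.voxel))
        ci, cj, ck = (min(max(i, 0), m - 1), min(max(j, 0), m - 1), min(max(k, 0), m - 1))
        if (ci, cj, ck) != (i, j, k):
            logger.warning("shadow point outside arena; clipped to boundary voxel")
        return ci, cj, ck


def cast_shadow(grid: ShadowGrid, point: np.ndarray) -> ShadowGrid:
    """Accumulate one bud's inverted shadow pyramid into the grid.

    Layer q (0 = the bud's own voxel) is the (2q+1)^2 voxel square q
    layers below, incremented by ``a * b**(-q)``; contributions from
    multiple buds add.
    """
    i, j, k = grid.voxel_index(point)
    m = grid.shape[0]
    v = grid.values
    for q in range(grid.depth + 1):
        kz = k - q
        if kz < 0:
            break
        inc = grid.a * grid.b ** (-q)
        v[max(i - q, 0): min(i + q + 1, m), max(j - q, 0): min(j + q + 1, m), kz] += inc
    return grid


def light_exposure(
    grid: ShadowGrid,
    bud_point: np.ndarray,
    base_exposure: float = 1.0,
    sensitivity: float = 1.0,
    light_gradient: float = 0.0,
    own_shadow: bool = True,
) -> float:
    """Light exposure Q >= 0 of a bud at ``bud_point``.

    ``Q = max(C - sensitivity * (s - a_own), 0) * g(z)`` where ``s`` is the
    accumulated shadow in the bud's voxel, ``a_own`` removes the bud's own
    layer-0 contribution, and ``g(z) = max(1 + gradient * z / extent, 0)``
    is the vertical light gain.
    """
    i, j, k = grid.voxel_index(bud_point)
    s = float(grid.values[i, j, k])
    if own_shadow:
        s = max(s - grid.a, 0.0)
    gain = max(1.0 + light_gradient * float(bud_point[2]) / grid.extent, 0.0)
    return max(base_exposure - sensitivity * s, 0.0) * gain


def allocate_resource(
    q_terminal: float, q_laterals, lam: float, v_in: float
) -> tuple[float, np.ndarray]:
    """Extended Borchert–Honda split of incoming resource at a node.

    The terminal path receives ``v * lam*Qm / (lam*Qm + (1-lam)*sum(Ql))``;
    the laterals share the remainder in proportion to their exposures.
    Total resource is conserved.  ``lam = 1`` sends everything to the
    terminal, ``lam = 0`` everything to the laterals (when they have any
    exposure).
    """
    ql = np.asarray(list(q_laterals), float)
    denom = lam * q_terminal + (1.0 - lam) * ql.sum()
    if denom <= 0.0:
        return 0.0, np.zeros_like(ql)
    v_t = v_in * lam * q_terminal / denom
    rest = v_in - v_t
    if ql.sum() > 0:
        v_l = rest * ql / ql.sum()
    else:
        v_l = np.zeros_like(ql)
    return float(v_t), v_l


# ---------------------------------------------------------------------- #
# growth state
# ---------------------------------------------------------------------- #

# lateral bud states
_DORMANT, _ACTIVE, _GONE = 0, 1, 2


@dataclass
class GrowthState:
    """Mutable metamer lists during a simulation run."""

    params: SOTParams
    seed: int
    iteration: int = 0
    base: list = field(default_factory=list)       # (3,) arrays
    direction: list = field(default_factory=list)  # (3,) unit arrays
    parent: list = field(default_factory=list)     # metamer index or -1
    ext_child: list = field(default_factory=list)  # -1 if none
    lat_children: list = field(default_factory=list)  # list[int] per metamer
    gorder: list = field(default_factory=list)     # growth order (laterals +1)
    bpos: list = field(default_factory=list)       # position along growth branch
    lat_state: list = field(default_factory=list)  # _DORMANT/_ACTIVE/_GONE

    @property
    def n(self) -> int:
        return len(self.base)

    def tip(self, m: int) -> np.ndarray:
        return self.base[m] + self.params.segment_length * self.direction[m]

    def add_metamer(self, base, direction, parent, gorder, bpos) -> int:
        m = self.n
        self.base.append(np.asarray(base, float))
        self.direction.append(np.asarray(direction, float))
        self.parent.append(parent)
        self.ext_child.append(-1)
        self.lat_children.append([])
        self.gorder.append(gorder)
        self.bpos.append(bpos)
        self.lat_state.append(_DORMANT if gorder < self.params.max_order else _GONE)
        return m

    def inside(self, point: np.ndarray) -> bool:
        h = self.params.arena_extent / 2.0
        return (
            -h <= point[0] <= h and -h <= point[1] <= h
            and 0.0 <= point[2] <= self.params.arena_extent
        )


def _initial_state(params: SOTParams, seed: int) -> GrowthState:
    state = GrowthState(params=params, seed=int(seed))
    up = np.array([0.0, 0.0, 1.0])
    base = np.asarray(params.base_position, float)
    prev = -1
    for k in range(max(int(params.initial_metamers), 1)):
        m = state.add_metamer(base, up, prev, 0, k)
        if prev >= 0:
            state.ext_child[prev] = m
        base = state.tip(m)
        prev = m
    return state


# ---------------------------------------------------------------------- #
# orientation helpers
# ---------------------------------------------------------------------- #

def _frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the plane normal to unit d."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(abs(d[0]) - 1.0) < 1e-6:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - d * np.dot(ref, d)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def _tilt(d: np.ndarray, polar_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector at polar angle from d, at the given azimuth around it."""
    e1, e2 = _frame(d)
    th = math.radians(polar_deg)
    ph = math.radians(azim_deg)
    v = math.cos(th) * d + math.sin(th) * (math.cos(ph) * e1 + math.sin(ph) * e2)
    return v / np.linalg.norm(v)


def _tropism_vector(params: SOTParams) -> np.ndarray:
    el = math.radians(params.tropism_elevation_deg)
    az = math.radians(params.tropism_azimuth_deg)
    return np.array([math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)])


def _noise(u_normal: float, u_uniform: float, kind: str) -> float:
    """Unit-scale angular noise sample from pre-drawn uniforms/normals."""
    if kind == "uniform":
        return (2.0 * u_uniform - 1.0) * math.sqrt(3.0)  # unit variance
    return u_normal


# ---------------------------------------------------------------------- #
# one growth iteration
# ---------------------------------------------------------------------- #

def grow_step(state: GrowthState, grid: Optional[ShadowGrid] = None) -> GrowthState:
    """Advance the growth state by one iteration (in place; returns state).

    Shadow pass, per-bud exposure, basipetal aggregation, acropetal
    lambda-weighted allocation, then shoot production at every bud holding
    resource.  Randomness comes from a Philox stream keyed by
    (seed, iteration); per-bud draws are indexed by metamer id, so the
    result does not depend on bud evaluation order.
    """
    p = state.params
    if grid is None:
        grid = ShadowGrid(p.arena_extent, p.voxel_size, p.shadow_a, p.shadow_b, p.shadow_depth)
    grid.reset()

    n = state.n
    rng = np.random.Generator(np.random.Philox(key=[state.seed & 0x7FFFFFFF, state.iteration]))
    u_break = rng.random(n)
    z_norm = rng.standard_normal((n, _MAX_SHOOT, 2))
    u_unif = rng.random((n, _MAX_SHOOT, 2))
    u_azim = rng.random(n)  # terminal wobble azimuth

    # 1. shadow pass over all metamer tips
    for m in range(n):
        cast_shadow(grid, state.tip(m))

    # 2. bud fates and exposures
    for m in range(n):
        if state.lat_state[m] == _DORMANT and not state.lat_children[m]:
            if u_break[m] < p.bud_break_prob:
                state.lat_state[m] = _ACTIVE

    q_term = np.zeros(n)
    q_lat = np.zeros(n)
    for m in range(n):
        if state.ext_child[m] < 0:  # terminal bud present
            q_term[m] = light_exposure(
                grid, state.tip(m), p.base_exposure, p.shading_sensitivity, p.light_gradient
            )
        if state.lat_state[m] == _ACTIVE and not state.lat_children[m]:
            q = light_exposure(
                grid, state.tip(m), p.base_exposure, p.shading_sensitivity, p.light_gradient
            )
            if q < p.shed_threshold:
                state.lat_state[m] = _GONE
            else:
                q_lat[m] = q

    # 3. basipetal aggregation (children always have larger indices)
    q_sub = q_term + q_lat
    for m in range(n - 1, -1, -1):
        pa = state.parent[m]
        if pa >= 0:
            q_sub[pa] += q_sub[m]

    # 4. acropetal allocation with the apical-dominance split
    v_arr = np.zeros(n)          # resource entering each metamer
    v_term = np.zeros(n)         # resource reaching the terminal bud at m
    v_latbud = np.zeros(n)       # resource reaching the lateral bud at m
    roots = [m for m in range(n) if state.parent[m] < 0]
    for r in roots:
        v_arr[r] = q_sub[r]
    for m in range(n):
        v_in = v_arr[m]
        if v_in <= 0:
            continue
        # continuation: extension child subtree, or the terminal bud
        ext = state.ext_child[m]
        qm = q_sub[ext] if ext >= 0 else q_term[m]
        sinks = []   # (kind, index, q)
        if state.lat_state[m] == _ACTIVE and not state.lat_children[m] and q_lat[m] > 0:
            sinks.append(("bud", m, q_lat[m]))
        for c in state.lat_children[m]:
            sinks.append(("sub", c, q_sub[c]))
        vt, vl = allocate_resource(qm, [s[2] for s in sinks], p.apical_lambda, v_in)
        if ext >= 0:
            v_arr[ext] = vt
        else:
            v_term[m] = vt
        for (kind, idx, _), share in zip(sinks, vl):
            if kind == "bud":
                v_latbud[idx] = share
            else:
                v_arr[idx] = share

    # 5. shoot production
    trop = _tropism_vector(p)

    def _grow_shoot(attach: int, first_dir: np.ndarray, n_new: int,
                    gorder: int, bpos0: int, lateral: bool) -> None:
        base = state.tip(attach)
        d = first_dir
        parent = attach
        for k in range(n_new):
            if k > 0:
                wob = _noise(z_norm[attach, k, 0], u_unif[attach, k, 0], p.angle_noise_kind)
                azim = 360.0 * u_unif[attach, k, 1]
                d = _tilt(d, p.branching_angle_spread_deg * 0.25 * wob, azim)
            if p.tropism_strength != 0.0:
                d = d + p.tropism_strength * trop
                d = d / np.linalg.norm(d)
            tip = base + p.segment_length * d
            if not state.inside(tip):
                break
            m_new = state.add_metamer(base, d, parent, gorder, bpos0 + k)
            if k == 0 and lateral:
                state.lat_children[attach].append(m_new)
                state.lat_state[attach] = _GONE
            elif parent >= 0:
                state.ext_child[parent] = m_new
            base = state.tip(m_new)
            parent = m_new

    for m in range(n):
        # terminal shoot
        n_new = int(math.floor(p.resource_coeff * v_term[m]))
        if n_new > 0 and state.ext_child[m] < 0:
            n_new = min(n_new, _MAX_SHOOT)
            wob = _noise(z_norm[m, 0, 0], u_unif[m, 0, 0], p.angle_noise_kind)
            d0 = _tilt(
                state.direction[m],
                abs(p.branching_angle_spread_deg * 0.25 * wob),
                360.0 * u_azim[m],
            )
            _grow_shoot(m, d0, n_new, state.gorder[m], state.bpos[m] + 1, lateral=False)
        # lateral shoot
        n_new = int(math.floor(p.resource_coeff * v_latbud[m]))
        if n_new > 0 and state.lat_state[m] == _ACTIVE and not state.lat_children[m]:
            n_new = min(n_new, _MAX_SHOOT)
            wob = _noise(z_norm[m, 0, 1], u_unif[m, 0, 1], p.angle_noise_kind)
            theta = p.branching_angle_mean_deg + p.branching_angle_spread_deg * wob
            dwob = _noise(z_norm[m, 1, 1], u_unif[m, 1, 1], p.angle_noise_kind)
            phi = state.bpos[m] * p.divergence_angle_deg + p.divergence_spread_deg * dwob
            d0 = _tilt(state.direction[m], theta, phi)
            _grow_shoot(m, d0, n_new, state.gorder[m] + 1, 0, lateral=True)

    state.iteration += 1
    return state


# ---------------------------------------------------------------------- #
# pipe-model radii
# ---------------------------------------------------------------------- #

def update_radii(tree: Tree, pipe_exponent: float, tip_radius: float) -> Tree:
    """Assign radii by the pipe model: tips get ``tip_radius`` and every
    parent satisfies ``r_p**e = sum_children r_c**e`` exactly."""
    out = tree.copy()
    kids = out.children()
    e = float(pipe_exponent)
    # post-order via DFS
    order: list[int] = []
    stack = [out.root]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(kids[i])
    r = np.zeros(len(out))
    for i in reversed(order):
        if not kids[i]:
            r[i] = tip_radius
        else:
            r[i] = float(np.sum(r[kids[i]] ** e) ** (1.0 / e))
    out.radius = r
    return out


# ---------------------------------------------------------------------- #
# full simulation
# ---------------------------------------------------------------------- #

def _state_to_tree(state: GrowthState) -> Tree:
    p = state.params
    n = state.n
    return Tree(
        start=np.array(state.base, float).reshape(n, 3),
        axis=np.array(state.direction, float).reshape(n, 3),
        length=np.full(n, p.segment_length),
        radius=np.full(n, p.tip_radius),
        parent=np.array(state.parent, int),
        extension=np.array(
            [state.parent[m] >= 0 and state.ext_child[state.parent[m]] == m for m in range(n)],
            bool,
        ),
        branch_id=np.full(n, -1, int),
        order=np.full(n, -1, int),
        pos_in_branch=np.full(n, -1, int),
        meta={"source": "sot", "seed": state.seed},
    )


def simulate(params: SOTParams, seed: int) -> Tree:
    """Run the full growth simulation; deterministic given (params, seed).

    Grows for ``params.n_iterations`` iterations, assigns pipe-model radii
    and Gravelius orders (thickest-branch rule — for weak apical dominance
    the simulated topology is extracted with the same rule as QSM imports,
    and for strong apical dominance the rule coincides with the lineage
    bookkeeping), and returns a validated :class:`~treeclone.qsm.Tree`.
    """
    state = _initial_state(params, seed)
    grid = ShadowGrid(
        params.arena_extent, params.voxel_size,
        params.shadow_a, params.shadow_b, params.shadow_depth,
    )
    for _ in range(int(params.n_iterations)):
        grow_step(state, grid)
    tree = _state_to_tree(state)
    tree = update_radii(tree, params.pipe_exponent, params.tip_radius)
    tree = assign_orders(tree, force=True)
    tree.validate(check_attachment=True)
    return tree
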