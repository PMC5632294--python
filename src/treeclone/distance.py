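"""Structural distance by distribution tomography, plus classical tree metrics.

The structural distance D_S between two feature tables U_m and U_d treats
each table as an empirical point density in R^d and compares the two
densities through their one-dimensional line projections (the Radon-
transform view).  For a fixed set of n unit directions L_1..L_n,

    D_S(U_m, U_d) = (1/n) * sum_i K[ P_1D(U_m, L_i), P_1D(U_d, L_i) ]

where K[.,.] is the two-sample Kolmogorov–Smirnov statistic between the
empirical cumulative distributions of the projections.  D_S lies in [0, 1],
is 0 for identical tables, and is symmetric when both tables see the same
directions.

Directions are quasi-random: a deterministic low-discrepancy (Sobol)
sequence in the unit cube mapped through the standard-normal inverse CDF
and normalized, which covers the unit sphere asymptotically uniformly and
is bit-reproducible for a given (dim, n, sequence id).

Columns mix units (meters and degrees), so each table pair is standardized
column-wise by the pooled median and IQR before projection.

The module also provides the traditional scalar metrics — height h, girth
g, crown spread c — and their relative error distances d_h, d_g, d_c
against a reference tree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.stats import norm, qmc

from .features import FeatureTable
from .qsm import Tree

__all__ = [
    "DirectionSet",
    "DistanceResult",
    "ClassicalMetrics",
    "OpCounter",
    "generate_directions",
    "ks_two_sample",
    "standardize_pair",
    "sliced_distance",
    "structural_distance",
    "aggregate_distance",
    "height",
    "girth",
    "crown_spread",
    "classical_distances",
    "classical_metrics",
]


@dataclass(frozen=True)
class DirectionSet:
    """n deterministic unit vectors in R^dim for projection tomography."""

    dim: int
    n: int
    vectors: np.ndarray          # (n, dim), rows unit-norm
    sequence_id: str             # "<generator>:<offset>"

    def __post_init__(self):
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("direction vectors must be unit-norm within 1e-9")


@dataclass
class DistanceResult:
    """Per-pair structural distances and their unweighted mean."""

    per_pair: dict
    mean: float
    n_lines: int


@dataclass(frozen=True)
class ClassicalMetrics:
    """Traditional scalar tree shape descriptors, all in meters."""

    h: float
    g: float
    c: float


# ---------------------------------------------------------------------- #
# direction generation
# ---------------------------------------------------------------------- #

def generate_directions(dim: int, n: int = 1000, sequence_id: str = "sobol:0") -> DirectionSet:
    """Deterministic quasi-random unit directions on the sphere S^{dim-1}.

    A Sobol sequence point u in (0,1)^dim maps to a direction via the
    componentwise standard-normal inverse CDF followed by normalization;
    an isotropic Gaussian being spherically symmetric, the image points
    cover the sphere evenly.  The all-zeros first Sobol point is skipped.
    Regeneration with the same ``(dim, n, sequence_id)`` is bit-identical.
    """
    if dim < 1 or n < 1:
        raise ValueError("dim and n must be >= 1")
    gen, _, off = sequence_id.partition(":")
    if gen != "sobol":
        raise ValueError(f"unknown low-discrepancy generator {gen!r}")
    offset = int(off) if off else 0
    sob = qmc.Sobol(d=dim, scramble=False)
    sob.fast_forward(1 + offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # balance warning for n not a power of 2
        pts = sob.random(n + 8)  # headroom: the midpoint (0.5,..) maps to 0
    pts = np.clip(pts, 1e-12, 1.0 - 1e-12)
    vec = norm.ppf(pts)
    norms = np.linalg.norm(vec, axis=1)
    vec = vec[norms > 1e-9][:n]
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    return DirectionSet(dim=dim, n=n, vectors=vec, sequence_id=f"sobol:{offset}")


# ---------------------------------------------------------------------- #
# Kolmogorov–Smirnov
# ---------------------------------------------------------------------- #

def _ks_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sample KS statistic per column of (n,L) vs (m,L) arrays.

    Sup over pooled sample points of |ECDF_x - ECDF_y|, with tied pooled
    values handled by evaluating the ECDF gap only after the last
    occurrence of each distinct value.
    """
    nx, ny = x.shape[0], y.shape[0]
    pool = np.concatenate([x, y], axis=0)
    order = np.argsort(pool, axis=0, kind="stable")
    weights = np.where(np.arange(nx + ny) < nx, 1.0 / nx, -1.0 / ny)
    gaps = np.cumsum(weights[order], axis=0)
    vals = np.take_along_axis(pool, order, axis=0)
    last = np.ones_like(gaps, dtype=bool)
    last[:-1] = vals[1:] != vals[:-1]
    return np.max(np.abs(gaps) * last, axis=0)


def ks_two_sample(x, y) -> float:
    """Two-sample Kolmogorov–Smirnov statistic in [0, 1].

    The sup over the pooled points of the absolute difference of the two
    empirical cumulative distribution functions.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(_ks_columns(x[:, None], y[:, None])[0])


# ---------------------------------------------------------------------- #
# standardization and projection
# ---------------------------------------------------------------------- #

def standardize_pair(um: FeatureTable, ud: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale both tables by the pooled per-column median and IQR.

    Mixing meters and degrees in one table makes raw projections dominated
    by whichever unit has the larger spread; robust pooled standardization
    puts the columns on a common footing.  Columns with zero pooled IQR
    pass through centered but unscaled.
    """
    if um.kind != ud.kind or um.columns != ud.columns:
        raise ValueError("tables must share kind and column set")
    a, b = um.values, ud.values
    pooled = np.concatenate([a, b], axis=0)
    med = np.median(pooled, axis=0)
    q75, q25 = np.percentile(pooled, [75, 25], axis=0)
    iqr = q75 - q25
    iqr[iqr == 0] = 1.0
    return (a - med) / iqr, (b - med) / iqr


@dataclass
class OpCounter:
    """Tallies the dominant operation counts of the distance computation.

    ``projection_ops`` counts multiply-adds of the data-times-directions
    products (linear in rows, columns and lines); ``sort_ops`` counts
    comparison-sort work, ``pooled_rows * ceil(log2(pooled_rows))`` per
    line; ``scan_ops`` counts the linear ECDF sweeps.  Used to verify the
    complexity shape of the algorithm independently of wall-clock time.
    """

    projection_ops: int = 0
    sort_ops: int = 0
    scan_ops: int = 0

    @property
    def total(self) -> int:
        return self.projection_ops + self.sort_ops + self.scan_ops


def sliced_distance(
    a: np.ndarray, b: np.ndarray, dirs: DirectionSet,
    counter: Optional[OpCounter] = None,
) -> float:
    """Sliced KS distance between two raw point sets in R^dim.

    The mean over the direction set of the two-sample KS statistic
    between the 1-D projections.  ``a`` and ``b`` are (rows, dim) arrays,
    already on a common scale.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[1] != dirs.dim or b.shape[1] != dirs.dim:
        raise ValueError("point dimension must equal the direction dimension")
    pa = a @ dirs.vectors.T
    pb = b @ dirs.vectors.T
    if counter is not None:
        pooled = a.shape[0] + b.shape[0]
        counter.projection_ops += (a.shape[0] + b.shape[0]) * dirs.dim * dirs.n
        counter.sort_ops += pooled * max(1, math.ceil(math.log2(pooled))) * dirs.n
        counter.scan_ops += pooled * dirs.n
    return float(np.mean(_ks_columns(pa, pb)))


def structural_distance(
    um: FeatureTable, ud: FeatureTable, dirs: DirectionSet,
    counter: Optional[OpCounter] = None,
) -> float:
    """Mean over quasi-random lines of the KS statistic between projections.

    If exactly one of the two tables is empty (for instance the simulated
    tree grew no branches of a requested order) the distance is the
    maximal penalty 1, steering an optimizer toward producing the missing
    orders.  If both are empty they are indistinguishable and the distance
    is 0.
    """
    if um.kind != ud.kind or um.columns != ud.columns:
        raise ValueError("tables must share kind and column set")
    ncol = len(um.columns)
    if dirs.dim != ncol:
        raise ValueError(f"direction dim {dirs.dim} != column count {ncol}")
    if len(um) == 0 and len(ud) == 0:
        return 0.0
    if len(um) == 0 or len(ud) == 0:
        return 1.0
    a, b = standardize_pair(um, ud)
    return sliced_distance(a, b, dirs, counter=counter)


def aggregate_distance(
    pairs: Sequence[tuple[FeatureTable, FeatureTable]],
    dirs: Union[DirectionSet, Mapping[int, DirectionSet], Sequence[DirectionSet]],
) -> DistanceResult:
    """Per-pair structural distances plus their unweighted mean.

    With several data sets in play (e.g. S^{0,1} and B^{2,3,4}) each pair
    contributes one distance and the optimization objective is the plain
    average.  ``dirs`` may be a single DirectionSet (all pairs share the
    dimension), a mapping from dimension to DirectionSet, or a sequence
    parallel to ``pairs``.
    """
    if not pairs:
        raise ValueError("at least one table pair is required")
    per_pair: dict = {}
    n_lines = 0
    for k, (um, ud) in enumerate(pairs):
        dim = len(um.columns)
        if isinstance(dirs, DirectionSet):
            d = dirs
        elif isinstance(dirs, Mapping):
            d = dirs[dim]
        else:
            d = dirs[k]
        per_pair[um.label] = structural_distance(um, ud, d)
        n_lines = max(n_lines, d.n)
    mean = float(np.mean(list(per_pair.values())))
    return DistanceResult(per_pair=per_pair, mean=mean, n_lines=n_lines)


# ---------------------------------------------------------------------- #
# classical metrics
# ---------------------------------------------------------------------- #

def height(tree: Tree) -> float:
    """Highest point of the tree (max z over all cylinder endpoints), m."""
    return float(max(tree.start[:, 2].max(), tree.end[:, 2].max()))


def girth(tree: Tree) -> float:
    """Diameter of the ground segment, m.

    Breast-height diameter is ill-defined for shrubby multi-stem forms,
    so the root cylinder's diameter stands in.
    """
    return float(2.0 * tree.radius[tree.root])


def crown_spread(tree: Tree, sep_deg: float = 10.0) -> float:
    """Spoke-method crown spread, m.

    Spokes at ``sep_deg`` azimuthal separation emanate from the ground
    segment's XY position; each spoke extends to the most distant cylinder
    endpoint whose azimuth falls in its half-open sector (empty sector:
    length 0).  The crown spread is twice the mean spoke length.
    """
    if not float(360.0 / sep_deg).is_integer():
        raise ValueError("sep_deg must divide 360")
    n_spokes = int(round(360.0 / sep_deg))
    center = tree.start[tree.root, :2]
    pts = np.concatenate([tree.start[:, :2], tree.end[:, :2]], axis=0) - center
    r = np.linalg.norm(pts, axis=1)
    az = np.degrees(np.arctan2(pts[:, 1], pts[:, 0])) % 360.0
    sector = np.floor(az / sep_deg).astype(int) % n_spokes
    spokes = np.zeros(n_spokes)
    np.maximum.at(spokes, sector, r)
    return float(2.0 * spokes.mean())


def classical_metrics(tree: Tree, sep_deg: float = 10.0) -> ClassicalMetrics:
    """Height, girth and crown spread of one tree."""
    return ClassicalMetrics(h=height(tree), g=girth(tree), c=crown_spread(tree, sep_deg))


def classical_distances(
    model: ClassicalMetrics, data: ClassicalMetrics
) -> tuple[float, float, float]:
    """Relative errors (d_h, d_g, d_c) of model metrics vs reference data.

    d_h = |h_d - h_m| / h_d and likewise for girth and crown spread; the
    reference (data/QSM) metrics must be strictly positive.
    """
    for name, v in (("height", data.h), ("girth", data.g), ("crown spread", data.c)):
        if v <= 0:
            raise ValueError(f"reference {name} must be > 0")
    return (
        abs(data.h - model.h) / data.h,
        abs(data.g - model.g) / data.g,
        abs(data.c - model.c) / data.c,
    )
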