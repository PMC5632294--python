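"""Structural data sets: branch tables B^w and segment tables S^w.

Tree morphology is summarized as empirical feature tables.  A *segment* is
one elementary cylinder; a *branch* is the maximal chain of segments of one
Gravelius order.  Branch rows carry the inclination angle beta (deg), the
azimuth alpha around the parent axis (deg), the total branch length L_t (m),
the first-segment radius R_f (m) and the along-parent attachment distance
L_a (m).  Segment rows carry the radius R (m), the along-branch distance L
(m) to the segment base, and two relative orientation angles: gamma, the
angle between the horizontal (XY) projections of the segment axis and its
parent's axis, and zeta, the absolute difference of their elevation angles.

Tables of different orders of the same kind may be merged (rows
concatenated) into joint data sets such as S^{0,1} or B^{2,3,4}; branch and
segment tables differ in dimension and are never merged together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .qsm import Tree

__all__ = [
    "FeatureTable",
    "BRANCH_COLUMNS",
    "SEGMENT_COLUMNS",
    "branch_table",
    "segment_table",
    "merge_tables",
    "read_table",
    "write_table",
]

BRANCH_COLUMNS = ["beta_deg", "alpha_deg", "total_length_m", "first_radius_m", "attach_length_m"]
SEGMENT_COLUMNS = ["radius_m", "along_branch_m", "gamma_deg", "zeta_deg"]

_EPS_HORIZ = 1e-9


@dataclass
class FeatureTable:
    """Rows-by-named-columns matrix of one feature kind over a set of orders."""

    kind: str                      # "branch" | "segment"
    orders: frozenset
    data: pd.DataFrame

    def __post_init__(self):
        if self.kind not in ("branch", "segment"):
            raise ValueError(f"unknown table kind {self.kind!r}")
        expect = BRANCH_COLUMNS if self.kind == "branch" else SEGMENT_COLUMNS
        if list(self.data.columns) != expect:
            raise ValueError(f"{self.kind} table must have columns {expect}")
        self.orders = frozenset(int(w) for w in self.orders)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def label(self) -> str:
        w = ",".join(str(x) for x in sorted(self.orders))
        return f"{'B' if self.kind == 'branch' else 'S'}^{{{w}}}"


# ---------------------------------------------------------------------- #
# geometry helpers
# ---------------------------------------------------------------------- #

def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two vectors, degrees in [0, 180]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS_HORIZ or nv < _EPS_HORIZ:
        return 0.0
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _azimuth_about(axis: np.ndarray, vec: np.ndarray) -> float:
    """Azimuth of ``vec`` around ``axis``, degrees in [0, 360).

    Measured from the projection of global +x onto the plane normal to
    ``axis`` (or +y when the axis is within 1e-6 of +x).  The absolute
    reference is immaterial to the distance — fits hold up to a rotation
    about z — but must be fixed for determinism.
    """
    a = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if np.linalg.norm(ref - a * np.dot(ref, a)) < 1e-6:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - a * np.dot(ref, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    w = vec - a * np.dot(vec, a)
    if np.linalg.norm(w) < _EPS_HORIZ:
        return 0.0
    ang = float(np.degrees(np.arctan2(np.dot(w, e2), np.dot(w, e1))) % 360.0)
    return 0.0 if ang >= 360.0 else ang  # fp wrap: tiny negatives round to 360


def _elevation_deg(v: np.ndarray) -> float:
    """Angle from the XY plane, degrees in [-90, 90]."""
    h = float(np.hypot(v[0], v[1]))
    return float(np.degrees(np.arctan2(v[2], h)))


def _require_orders(tree: Tree) -> None:
    if not tree.has_orders():
        raise RuntimeError("tree has no order annotations; run assign_orders first")


def _branch_rows(tree: Tree) -> dict[int, np.ndarray]:
    """branch_id -> row indices sorted by pos_in_branch."""
    out: dict[int, np.ndarray] = {}
    order_by = np.lexsort((tree.pos_in_branch, tree.branch_id))
    bids = tree.branch_id[order_by]
    bounds = np.flatnonzero(np.diff(bids)) + 1
    for grp in np.split(order_by, bounds):
        out[int(tree.branch_id[grp[0]])] = grp
    return out


# ---------------------------------------------------------------------- #
# extraction
# ---------------------------------------------------------------------- #

def branch_table(tree: Tree, orders: Iterable[int]) -> FeatureTable:
    """One row per branch whose Gravelius order is in ``orders``.

    The trunk has no parent segment, so its beta is measured against
    global +z and its alpha around +z from +x; its attachment distance
    L_a is 0.
    """
    _require_orders(tree)
    orders = frozenset(int(w) for w in orders)
    by_branch = _branch_rows(tree)
    z = np.array([0.0, 0.0, 1.0])

    rows = []
    for bid, idx in sorted(by_branch.items()):
        first = int(idx[0])
        w = int(tree.order[first])
        if w not in orders:
            continue
        p = int(tree.parent[first])
        if p < 0:
            beta = _angle_deg(tree.axis[first], z)
            alpha = _azimuth_about(z, tree.axis[first])
            l_a = 0.0
        else:
            beta = _angle_deg(tree.axis[first], tree.axis[p])
            alpha = _azimuth_about(tree.axis[p], tree.axis[first])
            # distance along the parent branch from its start to the
            # attachment point (the parent segment's tip)
            pb = by_branch[int(tree.branch_id[p])]
            ppos = int(tree.pos_in_branch[p])
            l_a = float(tree.length[pb[: ppos + 1]].sum())
        rows.append(
            (beta, alpha, float(tree.length[idx].sum()), float(tree.radius[first]), l_a)
        )
    df = pd.DataFrame(rows, columns=BRANCH_COLUMNS)
    return FeatureTable(kind="branch", orders=orders, data=df)


def segment_table(tree: Tree, orders: Iterable[int]) -> FeatureTable:
    """One row per segment of a branch whose order is in ``orders``.

    For the root segment — which has no parent — the reference axis is
    global +z, the degenerate limit of a vertical parent; its gamma is
    therefore 0 by the zero-horizontal-projection convention.
    """
    _require_orders(tree)
    orders = frozenset(int(w) for w in orders)
    by_branch = _branch_rows(tree)
    z = np.array([0.0, 0.0, 1.0])

    rows = []
    for bid, idx in sorted(by_branch.items()):
        if int(tree.order[idx[0]]) not in orders:
            continue
        prefix = 0.0
        for i in idx:
            i = int(i)
            p = int(tree.parent[i])
            pax = z if p < 0 else tree.axis[p]
            gamma = _angle_deg(
                np.array([tree.axis[i][0], tree.axis[i][1], 0.0]),
                np.array([pax[0], pax[1], 0.0]),
            )
            zeta = abs(_elevation_deg(tree.axis[i]) - _elevation_deg(pax))
            rows.append((float(tree.radius[i]), prefix, gamma, zeta))
            prefix += float(tree.length[i])
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return FeatureTable(kind="segment", orders=orders, data=df)


def merge_tables(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Row-concatenate same-kind tables into a joint multi-order data set."""
    if not tables:
        raise ValueError("nothing to merge")
    kinds = {t.kind for t in tables}
    if len(kinds) > 1:
        raise TypeError("branch and segment tables differ in dimension and cannot be merged")
    data = pd.concat([t.data for t in tables], ignore_index=True)
    orders = frozenset().union(*(t.orders for t in tables))
    return FeatureTable(kind=tables[0].kind, orders=orders, data=data)


# ---------------------------------------------------------------------- #
# serialization (2-line comment header: kind, orders)
# ---------------------------------------------------------------------- #

def write_table(table: FeatureTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind={table.kind}\n")
        fh.write(f"# orders={','.join(str(w) for w in sorted(table.orders))}\n")
        table.data.to_csv(fh, index=False, float_format="%.9g")


def read_table(path) -> FeatureTable:
    with open(path) as fh:
        kind_line = fh.readline().strip()
        orders_line = fh.readline().strip()
        df = pd.read_csv(fh)
    if not kind_line.startswith("# kind=") or not orders_line.startswith("# orders="):
        raise ValueError("feature table file lacks the 2-line kind/orders header")
    kind = kind_line.split("=", 1)[1]
    raw = orders_line.split("=", 1)[1]
    orders = frozenset(int(w) for w in raw.split(",") if w != "")
    return FeatureTable(kind=kind, orders=orders, data=df)
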