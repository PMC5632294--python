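"""Cylinder-table tree model: I/O, validation, and Gravelius order assignment.

A tree — whether reconstructed from laser scans (a quantitative structure
model, QSM) or emitted by a growth simulator — is an ordered table of
circular cylinders.  Each cylinder knows its start point, unit axis, length,
radius and the row index of its parent cylinder.  Topological annotations
(branch id, Gravelius order, position within branch) are derived from the
geometry by :func:`assign_orders` using the thickest-branch rule: at a
junction the child with the largest first-segment radius continues its
parent's branch and order, thinner children start lateral branches of
order ``w + 1``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Cylinder",
    "Tree",
    "TreeFormatError",
    "TreeTopologyError",
    "TreeValidationError",
    "read_tree",
    "write_tree",
    "assign_orders",
]

#: Canonical CSV column order for cylinder tables.
CSV_COLUMNS = [
    "radius",
    "length",
    "start_x",
    "start_y",
    "start_z",
    "axis_x",
    "axis_y",
    "axis_z",
    "parent",
    "extension",
    "branch_id",
    "branch_order",
    "pos_in_branch",
]

_AXIS_TOL = 1e-9


class TreeFormatError(ValueError):
    """Raised when a cylinder table file is malformed."""


class TreeTopologyError(ValueError):
    """Raised when parent links do not form a single rooted tree."""


class TreeValidationError(ValueError):
    """Raised when cylinder geometry violates the data model invariants."""


@dataclass
class Cylinder:
    """A single elementary unit of a branch.

    Angles and positions are in meters, z up.  ``parent`` is the row index
    of the parent cylinder, or ``None`` for the root.  ``order`` is the
    Gravelius order (0 = trunk); ``-1`` marks an unset annotation.
    """

    start: np.ndarray
    axis: np.ndarray
    length: float
    radius: float
    parent: Optional[int] = None
    is_extension: bool = False
    branch_id: int = -1
    order: int = -1
    pos_in_branch: int = -1

    @property
    def end(self) -> np.ndarray:
        return np.asarray(self.start, float) + float(self.length) * np.asarray(self.axis, float)


@dataclass
class Tree:
    """Ordered collection of cylinders with parent/branch/order topology.

    Stored column-wise as numpy arrays for vectorized feature extraction;
    row order is significant and preserved through I/O.
    """

    start: np.ndarray        # (n, 3) m
    axis: np.ndarray         # (n, 3) unit
    length: np.ndarray       # (n,) m
    radius: np.ndarray       # (n,) m
    parent: np.ndarray       # (n,) int, -1 for root
    extension: np.ndarray    # (n,) bool
    branch_id: np.ndarray    # (n,) int, -1 unset
    order: np.ndarray        # (n,) int, -1 unset
    pos_in_branch: np.ndarray  # (n,) int, -1 unset
    meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ #

    def __len__(self) -> int:
        return int(self.length.shape[0])

    @property
    def n(self) -> int:
        return len(self)

    @property
    def end(self) -> np.ndarray:
        """(n, 3) cylinder tip positions."""
        return self.start + self.axis * self.length[:, None]

    @property
    def root(self) -> int:
        """Row index of the root cylinder."""
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeTopologyError(f"expected exactly one root, found {roots.size}")
        return int(roots[0])

    def cylinders(self) -> Iterable[Cylinder]:
        """Iterate rows as :class:`Cylinder` objects (copies)."""
        for i in range(len(self)):
            yield Cylinder(
                start=self.start[i].copy(),
                axis=self.axis[i].copy(),
                length=float(self.length[i]),
                radius=float(self.radius[i]),
                parent=None if self.parent[i] < 0 else int(self.parent[i]),
                is_extension=bool(self.extension[i]),
                branch_id=int(self.branch_id[i]),
                order=int(self.order[i]),
                pos_in_branch=int(self.pos_in_branch[i]),
            )

    @classmethod
    def from_cylinders(cls, cylinders: Iterable[Cylinder], meta: Optional[dict] = None) -> "Tree":
        cyls = list(cylinders)
        if not cyls:
            raise TreeValidationError("a tree must have at least one cylinder")
        return cls(
            start=np.array([c.start for c in cyls], float).reshape(-1, 3),
            axis=np.array([c.axis for c in cyls], float).reshape(-1, 3),
            length=np.array([c.length for c in cyls], float),
            radius=np.array([c.radius for c in cyls], float),
            parent=np.array([-1 if c.parent is None else c.parent for c in cyls], int),
            extension=np.array([c.is_extension for c in cyls], bool),
            branch_id=np.array([c.branch_id for c in cyls], int),
            order=np.array([c.order for c in cyls], int),
            pos_in_branch=np.array([c.pos_in_branch for c in cyls], int),
            meta=dict(meta or {}),
        )

    def copy(self) -> "Tree":
        return Tree(
            start=self.start.copy(), axis=self.axis.copy(),
            length=self.length.copy(), radius=self.radius.copy(),
            parent=self.parent.copy(), extension=self.extension.copy(),
            branch_id=self.branch_id.copy(), order=self.order.copy(),
            pos_in_branch=self.pos_in_branch.copy(), meta=dict(self.meta),
        )

    def children(self) -> list[list[int]]:
        """Child row indices per cylinder."""
        kids: list[list[int]] = [[] for _ in range(len(self))]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[int(p)].append(i)
        return kids

    def has_orders(self) -> bool:
        return bool(np.all(self.order >= 0) and np.all(self.branch_id >= 0))

    # ------------------------------------------------------------------ #

    def validate(self, check_attachment: bool = False, attach_tol: float = 1e-6) -> None:
        """Check all data-model invariants; raise on the first violation.

        Attachment (child start on parent's tip) is only enforced when
        ``check_attachment`` is set: simulated trees satisfy it by
        construction while imported QSMs carry reconstruction noise.
        """
        n = len(self)
        if n == 0:
            raise TreeValidationError("a tree must have at least one cylinder")
        norms = np.linalg.norm(self.axis, axis=1)
        bad = np.flatnonzero(np.abs(norms - 1.0) > _AXIS_TOL)
        if bad.size:
            raise TreeValidationError(f"non-unit axis at rows {bad[:10].tolist()}")
        bad = np.flatnonzero(~(self.length > 0))
        if bad.size:
            raise TreeValidationError(f"nonpositive length at rows {bad[:10].tolist()}")
        bad = np.flatnonzero(~(self.radius > 0))
        if bad.size:
            raise TreeValidationError(f"nonpositive radius at rows {bad[:10].tolist()}")
        if np.any(self.parent >= n) or np.any(self.parent < -1):
            raise TreeTopologyError("parent index out of range")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeTopologyError(f"expected exactly one root, found {roots.size}")
        self._check_acyclic()
        if check_attachment:
            p = self.parent
            has_parent = p >= 0
            gap = np.linalg.norm(self.start[has_parent] - self.end[p[has_parent]], axis=1)
            bad = np.flatnonzero(gap > attach_tol)
            if bad.size:
                rows = np.flatnonzero(has_parent)[bad]
                raise TreeValidationError(
                    f"child start detached from parent tip at rows {rows[:10].tolist()}"
                )

    def _check_acyclic(self) -> None:
        n = len(self)
        seen_root = np.zeros(n, bool)
        for i in range(n):
            if seen_root[i]:
                continue
            path = []
            j = i
            on_path = set()
            while j >= 0 and not seen_root[j]:
                if j in on_path:
                    raise TreeTopologyError(f"cyclic parent links through row {j}")
                on_path.add(j)
                path.append(j)
                j = int(self.parent[j])
            for k in path:
                seen_root[k] = True


# ---------------------------------------------------------------------- #
# I/O
# ---------------------------------------------------------------------- #

def _frame_from_tree(tree: Tree) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "radius": tree.radius,
            "length": tree.length,
            "start_x": tree.start[:, 0],
            "start_y": tree.start[:, 1],
            "start_z": tree.start[:, 2],
            "axis_x": tree.axis[:, 0],
            "axis_y": tree.axis[:, 1],
            "axis_z": tree.axis[:, 2],
            "parent": tree.parent,
            "extension": tree.extension.astype(int),
            "branch_id": tree.branch_id,
            "branch_order": tree.order,
            "pos_in_branch": tree.pos_in_branch,
        },
        columns=CSV_COLUMNS,
    )


def _tree_from_frame(df: pd.DataFrame, meta: Optional[dict] = None) -> Tree:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TreeFormatError(f"missing required column(s): {', '.join(missing)}")
    return Tree(
        start=df[["start_x", "start_y", "start_z"]].to_numpy(float),
        axis=df[["axis_x", "axis_y", "axis_z"]].to_numpy(float),
        length=df["length"].to_numpy(float),
        radius=df["radius"].to_numpy(float),
        parent=df["parent"].to_numpy(int),
        extension=df["extension"].to_numpy(int).astype(bool),
        branch_id=df["branch_id"].to_numpy(int),
        order=df["branch_order"].to_numpy(int),
        pos_in_branch=df["pos_in_branch"].to_numpy(int),
        meta=dict(meta or {}),
    )


def read_tree(path, column_map: Optional[dict] = None) -> Tree:
    """Read a cylinder table CSV into a validated :class:`Tree`.

    Parameters
    ----------
    path:
        CSV file with the canonical header (meters, z up, 0-based parent
        index with ``-1`` for the root).
    column_map:
        Optional mapping from canonical column names to the names used in
        the file, for converting foreign QSM exports.
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    self_ref = [i for i in range(len(df)) if int(df["parent"].iloc[i]) == i] if "parent" in df else []
    if self_ref:
        raise TreeTopologyError(f"self-referencing parent at rows {self_ref[:10]}")
    tree = _tree_from_frame(df, meta={"source": str(path)})
    tree.validate()
    return tree


def write_tree(tree: Tree, path) -> None:
    """Write a tree as canonical-order CSV, floats at 9 significant digits."""
    if len(tree) == 0:
        raise TreeValidationError("refusing to write an empty tree")
    df = _frame_from_tree(tree)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.9g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------- #
# Gravelius orders
# ---------------------------------------------------------------------- #

def assign_orders(tree: Tree, force: bool = False, w_max: int = 10) -> Tree:
    """Assign Gravelius orders, branch ids and in-branch positions.

    The trunk (root chain) is order 0.  At every junction the child with
    the largest first-segment radius continues its parent's branch and
    order; at equal radii the lowest row index wins.  Other children start
    fresh lateral branches of order ``w + 1``, capped at ``w_max``.

    Returns a new tree; idempotent.  Existing annotations are recomputed
    only when ``force`` is true or any annotation is unset.
    """
    out = tree.copy()
    if out.has_orders() and not force:
        return out
    kids = out.children()
    root = out.root

    order = np.full(len(out), -1, int)
    branch = np.full(len(out), -1, int)
    pos = np.full(len(out), -1, int)
    next_branch = 0
    extension = np.zeros(len(out), bool)

    # Iterative DFS; each stack entry is (row, order, branch_id, pos).
    stack = [(root, 0, 0, 0)]
    next_branch = 1
    while stack:
        i, w, b, p = stack.pop()
        order[i] = w
        branch[i] = b
        pos[i] = p
        ch = kids[i]
        if not ch:
            continue
        radii = out.radius[ch]
        cont = ch[int(np.argmax(radii))]  # argmax takes the lowest index on ties
        for c in ch:
            if c == cont:
                extension[c] = True
                stack.append((c, w, b, p + 1))
            else:
                extension[c] = False
                stack.append((c, min(w + 1, w_max), next_branch, 0))
                next_branch += 1

    out.order = order
    out.branch_id = branch
    out.pos_in_branch = pos
    out.extension = extension
    return out
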