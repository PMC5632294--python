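"""Morphological clone generation and summary statistics.

A best-fit parameter set defines a stochastic growth process; running it
with different random seeds yields *morphological clones* — trees sharing
the coarse structure the fit captured while differing in fine-scale
branching.  This module generates clone sets and summarizes each clone's
classical metrics (height, girth, crown spread) and relative errors
against a target tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distance import ClassicalMetrics, classical_distances, classical_metrics
from .qsm import Tree
from .sot import SOTParams, simulate

__all__ = ["CloneSet", "generate_clones", "clone_summary", "plot_clone_summary"]


@dataclass
class CloneSet:
    """Clones simulated from one parameter set with distinct seeds."""

    params: SOTParams
    seeds: list
    trees: list

    def __post_init__(self):
        if len(self.seeds) != len(self.trees):
            raise ValueError("one tree per seed required")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("clone seeds must be distinct")

    def __len__(self) -> int:
        return len(self.trees)


def generate_clones(params: SOTParams, n: int = 100, seed_base: int = 0) -> CloneSet:
    """Simulate ``n`` clones with seeds ``seed_base .. seed_base+n-1``.

    Deterministic given (params, n, seed_base); clones are independent
    realizations, so generation order is immaterial.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = [int(seed_base) + k for k in range(int(n))]
    trees = [simulate(params, s) for s in seeds]
    return CloneSet(params=params, seeds=seeds, trees=trees)


def clone_summary(clone_set: CloneSet, target: Tree) -> pd.DataFrame:
    """Per-clone classical metrics and relative errors against the target.

    Returns one row per clone with columns seed, h, g, c (meters) and
    d_h, d_g, d_c (relative errors vs the target tree).  Quantiles of any
    column are available via ``DataFrame.quantile``.
    """
    ref = classical_metrics(target)
    rows = []
    for seed, tree in zip(clone_set.seeds, clone_set.trees):
        m = classical_metrics(tree)
        dh, dg, dc = classical_distances(m, ref)
        rows.append((seed, m.h, m.g, m.c, dh, dg, dc))
    return pd.DataFrame(rows, columns=["seed", "h", "g", "c", "d_h", "d_g", "d_c"])


def plot_clone_summary(summary: pd.DataFrame, target: Tree, path=None):
    """Box plots of clone metric distributions with the target as a line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = classical_metrics(target)
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    axes[0].boxplot([summary["h"], summary["g"], summary["c"]], tick_labels=["h", "g", "c"])
    for i, v in enumerate((ref.h, ref.g, ref.c)):
        axes[0].hlines(v, i + 0.75, i + 1.25, colors="k")
    axes[0].set_ylabel("meters")
    axes[0].set_title("clone metrics (target in black)")
    axes[1].boxplot(
        [summary["d_h"], summary["d_g"], summary["d_c"]],
        tick_labels=["d_h", "d_g", "d_c"],
    )
    axes[1].set_title("relative errors vs target")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
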