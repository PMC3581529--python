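"""Tree-shape diagnostics of ancient rapid radiations.

Two signals are quantified: (i) terminal branches much longer than
internodal branches (Welch's unequal-variance t-test on the two length
partitions) and (ii) nodal support decaying with node depth (Pearson
correlation between relative node height and support). A radiation
leaves short, poorly supported internal branches and long terminal
branches, so a radiation-consistent tree shows a significant positive
terminal-internodal contrast together with a significant negative
height-support correlation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import RadsigError
from .tree import Node, Tree


@dataclass
class BranchPartition:
    terminal_lengths: list[float]
    internodal_lengths: list[float]
    flagged: bool = False  # no internodal edges (star-like tree)

    @property
    def terminal_mean(self) -> float:
        return float(np.mean(self.terminal_lengths))

    @property
    def internodal_mean(self) -> float:
        if not self.internodal_lengths:
            return float("nan")
        return float(np.mean(self.internodal_lengths))


def partition_branches(tree: Tree) -> BranchPartition:
    """Split edges into terminal (leaf to node) and internodal (node to node).

    A degree-2 root is an artifact of rooted newick serialization: its two
    edges are merged into one edge first, classified by its endpoints. A
    degree-3 root's edges count by their child's type.
    """
    terminal: list[float] = []
    internodal: list[float] = []
    root = tree.root
    merged: set[int] = set()
    if len(root.children) == 2:
        a, b = root.children
        merged = {id(a), id(b)}
        length = (a.length or 0.0) + (b.length or 0.0)
        if a.is_leaf or b.is_leaf:
            terminal.append(length)
        else:
            internodal.append(length)
    for node in tree.postorder():
        if node is root or id(node) in merged:
            continue
        (terminal if node.is_leaf else internodal).append(node.length)
    return BranchPartition(terminal, internodal, flagged=not internodal)


@dataclass
class WelchResult:
    t: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float


def welch_test(a, b) -> WelchResult:
    """Welch's two-sample t-test with Satterthwaite fractional df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise RadsigError("each sample needs at least two observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise RadsigError("both samples have zero variance; t is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def _node_heights(tree: Tree, mode: str = "max") -> dict[int, float]:
    if mode not in ("max", "mean"):
        raise RadsigError(f"height mode must be 'max' or 'mean', got {mode!r}")
    heights: dict[int, float] = {}
    tipdists: dict[int, list[float]] = {}  # path lengths to descendant leaves
    for node in tree.postorder():
        if node.is_leaf:
            tipdists[id(node)] = [0.0]
        else:
            dists = [d + c.length for c in node.children for d in tipdists[id(c)]]
            tipdists[id(node)] = dists
        dists = tipdists[id(node)]
        heights[id(node)] = max(dists) if mode == "max" else float(np.mean(dists))
    return heights


@dataclass
class HeightSupportTable:
    frame: pd.DataFrame  # columns: height, relative_height, support

    def __len__(self) -> int:
        return len(self.frame)


def relative_node_heights(tree: Tree, mode: str = "max") -> HeightSupportTable:
    """Relative node height (height / total tree length) versus support.

    Height is the maximum (default) or mean path length from the node to
    its descendant leaves. Rows cover internal, non-root nodes that carry
    a support value.
    """
    total = tree.total_length()
    if total <= 0:
        raise RadsigError("total branch length is zero")
    heights = _node_heights(tree, mode)
    rows = []
    for node in tree.internal_nodes(include_root=False):
        if node.support is None:
            continue
        h = heights[id(node)]
        rows.append({"height": h, "relative_height": h / total, "support": node.support})
    return HeightSupportTable(pd.DataFrame(rows, columns=["height", "relative_height", "support"]))


@dataclass
class PearsonResult:
    r: float
    p_value: float
    n: int


def height_support_correlation(table: HeightSupportTable) -> PearsonResult:
    df = table.frame
    if len(df) < 3:
        raise RadsigError("need at least 3 supported internal nodes")
    if df["support"].nunique() == 1 or df["relative_height"].nunique() == 1:
        raise RadsigError("constant column; correlation undefined")
    res = stats.pearsonr(df["relative_height"], df["support"])
    return PearsonResult(float(res.statistic), float(res.pvalue), len(df))


# -- model / results ---------------------------------------------------------

class RadiationDiagnostic:
    """Radiation diagnostic for a tree with branch lengths and supports."""

    def __init__(self, tree: Tree):
        self.tree = tree

    def fit(self, alpha: float = 0.05, height_mode: str = "max") -> "RadiationResult":
        partition = partition_branches(self.tree)
        if partition.flagged or len(partition.internodal_lengths) < 2:
            raise RadsigError("too few internodal branches for the radiation test")
        welch = welch_test(partition.terminal_lengths, partition.internodal_lengths)
        table = relative_node_heights(self.tree, mode=height_mode)
        pearson = height_support_correlation(table)
        verdict = welch.p_value < alpha and pearson.r < 0 and pearson.p_value < alpha
        return RadiationResult(self.tree, partition, welch, table, pearson, alpha, verdict)


@dataclass
class RadiationResult:
    tree: Tree
    partition: BranchPartition
    welch: WelchResult
    height_support: HeightSupportTable
    pearson: PearsonResult
    alpha: float
    radiation_consistent: bool

    def summary(self) -> str:
        w, r = self.welch, self.pearson
        lines = [
            "Radiation diagnostic",
            f"  terminal branches:   n={len(self.partition.terminal_lengths)}, "
            f"mean={self.partition.terminal_mean:.4g}",
            f"  internodal branches: n={len(self.partition.internodal_lengths)}, "
            f"mean={self.partition.internodal_mean:.4g}",
            f"  Welch t = {w.t:.3f} (d.f. = {w.df:.1f}), p = {w.p_value:.3g}",
            f"  height/support Pearson r = {r.r:.3f} (n = {r.n}), p = {r.p_value:.3g}",
            f"  verdict (alpha={self.alpha}): "
            + ("radiation-consistent" if self.radiation_consistent else "not radiation-consistent"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_terminal": len(self.partition.terminal_lengths),
            "n_internodal": len(self.partition.internodal_lengths),
            "terminal_mean": self.partition.terminal_mean,
            "internodal_mean": self.partition.internodal_mean,
            "welch_t": self.welch.t,
            "welch_df": self.welch.df,
            "welch_p": self.welch.p_value,
            "pearson_r": self.pearson.r,
            "pearson_p": self.pearson.p_value,
            "n_supported_nodes": self.pearson.n,
            "alpha": self.alpha,
            "radiation_consistent": self.radiation_consistent,
        }


def radiation_report(tree: Tree, alpha: float = 0.05, height_mode: str = "max") -> RadiationResult:
    """Functional wrapper around :class:`RadiationDiagnostic`."""
    return RadiationDiagnostic(tree).fit(alpha=alpha, height_mode=height_mode)
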