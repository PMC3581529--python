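"""A permutation test of the 'library' pattern of coexisting lineages.

Genomes often host several retroelement lineages at once. Under a
library scenario — an ancestral collection of element lineages whose
divergence predates the host species splits — conspecific lineages
should never be each other's closest relatives on the element tree.
The observed statistic S counts conspecific lineage pairs whose MRCA
clade contains no leaf from any other species; the null shuffles
species labels across lineages (optionally within clades, preserving
the species-by-clade margins), and the one-sided p-value asks whether
conspecific lineages cluster *less* than chance.

The statistic, null and sidedness are this package's formalisation of a
pattern usually argued qualitatively from co-occurrence tables.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LineageTable, RadsigError
from .tree import Tree


@dataclass
class CooccurrenceMatrix:
    frame: pd.DataFrame  # species x clade counts
    multiple_species: list[str]  # species carrying >= 2 lineages

    def summary(self) -> str:
        lines = ["Species x clade lineage counts:"]
        lines.append(self.frame.to_string())
        lines.append(f"species with multiple lineages: {', '.join(self.multiple_species) or 'none'}")
        return "\n".join(lines)


def build_cooccurrence(table: LineageTable) -> CooccurrenceMatrix:
    df = table.to_frame()
    if df.empty:
        return CooccurrenceMatrix(pd.DataFrame(), [])
    counts = pd.crosstab(df["species"], df["clade"])
    multiple = sorted(counts.index[counts.sum(axis=1) >= 2])
    return CooccurrenceMatrix(counts, multiple)


def _leafsets(tree: Tree) -> list[tuple[object, frozenset[str]]]:
    below: dict[int, frozenset[str]] = {}
    out = []
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        out.append((node, below[id(node)]))
    return out


def _sister_statistic(leafsets, species_of: dict[str, str]) -> int:
    """Count conspecific pairs whose MRCA clade holds only that species."""
    by_species: dict[str, list[str]] = {}
    for lid, sp in species_of.items():
        by_species.setdefault(sp, []).append(lid)
    s = 0
    for sp, lineages in by_species.items():
        if len(lineages) < 2:
            continue
        own = set(lineages)
        for x, y in itertools.combinations(sorted(lineages), 2):
            # postorder: the first leafset containing both is the MRCA clade
            for _node, ls in leafsets:
                if x in ls and y in ls:
                    if ls <= own:
                        s += 1
                    break
    return s


def sister_pair_statistic(tree: Tree, table: LineageTable) -> int:
    leaves = set(tree.leaf_labels())
    missing = [lid for lid in table.lineage_ids if lid not in leaves]
    if missing:
        raise RadsigError(f"lineage ids not found as tree leaves: {missing}")
    return _sister_statistic(_leafsets(tree), table.species_of())


def n_conspecific_pairs(table: LineageTable) -> int:
    counts = pd.Series(list(table.species_of().values())).value_counts()
    return int(sum(c * (c - 1) // 2 for c in counts))


# -- permutation null --------------------------------------------------------

def _shuffled_species(
    records, rng: np.random.Generator, stratify_by_clade: bool
) -> dict[str, str]:
    lids = [r[0] for r in records]
    species = [r[1] for r in records]
    clades = [r[2] for r in records]
    new = list(species)
    groups = {}
    for i, cl in enumerate(clades):
        groups.setdefault(cl if stratify_by_clade else "all", []).append(i)
    for idxs in groups.values():
        vals = [species[i] for i in idxs]
        perm = rng.permutation(len(vals))
        for slot, i in enumerate(idxs):
            new[i] = vals[perm[slot]]
    return dict(zip(lids, new))


def _distinct_assignments(records, stratify_by_clade: bool, limit: int = 50000):
    """All distinct species assignments (exhaustive null for small cases)."""
    groups: dict[str, list[int]] = {}
    for i, (_lid, _sp, cl) in enumerate(records):
        groups.setdefault(cl if stratify_by_clade else "all", []).append(i)
    per_group = []
    for idxs in groups.values():
        vals = [records[i][1] for i in idxs]
        perms = {p for p in itertools.permutations(vals)}
        per_group.append((idxs, sorted(perms)))
    out = []
    for combo in itertools.product(*(perms for _idxs, perms in per_group)):
        assign = [None] * len(records)
        for (idxs, _), perm in zip(per_group, combo):
            for slot, i in enumerate(idxs):
                assign[i] = perm[slot]
        out.append({records[i][0]: assign[i] for i in range(len(records))})
        if len(out) > limit:
            raise RadsigError("exhaustive null too large; use permutations")
    return out


@dataclass
class LibraryTestResult:
    statistic: int
    n_conspecific_pairs: int
    p_value: float
    null_mean: float
    null_distribution: np.ndarray
    n_perm: int
    seed: int | None
    stratified: bool
    exhaustive: bool
    per_species: dict[str, int]
    cooccurrence: CooccurrenceMatrix

    def summary(self) -> str:
        lines = [
            "Library-pattern permutation test",
            f"  conspecific pairs: {self.n_conspecific_pairs}; "
            f"observed clustered pairs S = {self.statistic}",
            f"  null mean S = {self.null_mean:.3f} "
            f"({'exhaustive, ' + str(len(self.null_distribution)) + ' assignments' if self.exhaustive else str(self.n_perm) + ' permutations'}"
            f"{', stratified by clade' if self.stratified else ''})",
            f"  one-sided p (less clustering than chance) = {self.p_value:.4g}",
        ]
        return "\n".join(lines)


class LibraryTest:
    """Permutation test that conspecific lineages cluster less than chance."""

    def __init__(self, tree: Tree, table: LineageTable):
        self.tree = tree
        self.table = table
        leaves = set(tree.leaf_labels())
        missing = [lid for lid in table.lineage_ids if lid not in leaves]
        if missing:
            raise RadsigError(f"lineage ids not found as tree leaves: {missing}")

    def fit(
        self,
        n_perm: int = 10000,
        seed: int | None = 0,
        stratify_by_clade: bool = False,
        exhaustive: bool = False,
    ) -> LibraryTestResult:
        if not exhaustive and n_perm < 100:
            raise RadsigError("need at least 100 permutations")
        npairs = n_conspecific_pairs(self.table)
        if npairs < 1:
            raise RadsigError("no species has two or more lineages")
        leafsets = _leafsets(self.tree)
        species_of = self.table.species_of()
        s_obs = _sister_statistic(leafsets, species_of)

        per_species: dict[str, int] = {}
        by_species: dict[str, list[str]] = {}
        for lid, sp in species_of.items():
            by_species.setdefault(sp, []).append(lid)
        for sp, lineages in by_species.items():
            if len(lineages) >= 2:
                sub = {lid: sp for lid in lineages}
                per_species[sp] = _sister_statistic(leafsets, sub)

        records = self.table.records
        if exhaustive:
            assignments = _distinct_assignments(records, stratify_by_clade)
            distinct = {tuple(sorted(a.items())) for a in assignments}
            if len(distinct) <= 1:
                raise RadsigError("degenerate shuffle space: one distinct assignment")
            null = np.array([_sister_statistic(leafsets, a) for a in assignments])
            p = float((1 + int((null <= s_obs).sum())) / (len(null) + 1))
        else:
            rng = np.random.default_rng(seed)
            draws = []
            seen = set()
            for _ in range(n_perm):
                assign = _shuffled_species(records, rng, stratify_by_clade)
                seen.add(tuple(sorted(assign.items())))
                draws.append(_sister_statistic(leafsets, assign))
            if len(seen) <= 1 and tuple(sorted(species_of.items())) in seen:
                raise RadsigError("degenerate shuffle space: one distinct assignment")
            null = np.array(draws)
            p = float((1 + int((null <= s_obs).sum())) / (n_perm + 1))

        return LibraryTestResult(
            statistic=s_obs,
            n_conspecific_pairs=npairs,
            p_value=p,
            null_mean=float(null.mean()),
            null_distribution=null,
            n_perm=len(null),
            seed=seed,
            stratified=stratify_by_clade,
            exhaustive=exhaustive,
            per_species=per_species,
            cooccurrence=build_cooccurrence(self.table),
        )


def permutation_test(
    tree: Tree,
    table: LineageTable,
    n_perm: int = 10000,
    seed: int | None = 0,
    stratify_by_clade: bool = False,
    **kwargs,
) -> LibraryTestResult:
    """Functional wrapper around :class:`LibraryTest`."""
    return LibraryTest(tree, table).fit(
        n_perm=n_perm, seed=seed, stratify_by_clade=stratify_by_clade, **kwargs
    )
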