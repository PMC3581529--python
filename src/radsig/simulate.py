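"""Synthetic-data generators with retained ground truth.

Every generator is a pure function of its seed: the same configuration
gives bit-identical output. Defaults mirror the radiation regime the
diagnostics target — 87 tips, mean terminal branch length 0.225 and mean
internodal length 0.042 expected substitutions per site, rtREV+G
sequence evolution — so a default simulation reproduces the study
conditions the statistics were designed for.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import (
    DOWNSTREAM_HALF,
    TARGET_MOTIF,
    UPSTREAM_HALF,
    ZincFingerGrammar,
)
from .core import AA_LETTERS, LineageTable, NucSequence, ProteinAlignment, RadsigError
from .substitution import N_STATES, SubstitutionModel, get_model
from .tree import Node, Tree


@dataclass
class SimConfig:
    seed: int
    n_tips: int = 87
    terminal_scale: float = 0.225  # expected terminal branch length
    internode_scale: float = 0.042  # expected internodal branch length
    n_sites: int = 542
    model: str = "rtrev"
    alpha: float = 1.0
    k: int = 4

    def __post_init__(self) -> None:
        if self.seed is None:
            raise RadsigError("seed is mandatory")
        if self.terminal_scale <= 0 or self.internode_scale < 0:
            raise RadsigError("branch-length scales must be positive (internode may be 0)")
        if self.n_tips < 4:
            raise RadsigError("need at least 4 tips")
        if self.n_sites < 1:
            raise RadsigError("need at least one site")

    def substitution_model(self) -> SubstitutionModel:
        return get_model(self.model, self.alpha, self.k)


@dataclass
class TreeTruth:
    terminal_lengths: list[float]
    internodal_lengths: list[float]


def simulate_tree(cfg: SimConfig) -> tuple[Tree, TreeTruth]:
    """Random-join (coalescent-style) topology with exponential branch
    lengths: internodal ~ Exp(mean=internode_scale), terminal ~
    Exp(mean=terminal_scale). Unrooted style: degree-3 root; an n-tip
    tree has n terminal and n-3 internodal edges."""
    rng = np.random.default_rng(cfg.seed)
    nodes = [Node(label=f"t{i + 1}") for i in range(cfg.n_tips)]
    terminal = rng.exponential(cfg.terminal_scale, size=cfg.n_tips)
    for node, bl in zip(nodes, terminal):
        node.length = float(bl)
    internodal: list[float] = []
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        bl = float(rng.exponential(cfg.internode_scale)) if cfg.internode_scale > 0 else 0.0
        parent.length = bl
        internodal.append(bl)
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for x, n in enumerate(nodes) if x not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add(n)
    return Tree(root), TreeTruth([float(x) for x in terminal], internodal)


def evolve_alignment(tree: Tree, cfg: SimConfig) -> ProteinAlignment:
    """Forward simulation along the tree: root states from the model's
    equilibrium frequencies; one gamma category per site, fixed across
    the whole tree; child states via the transition matrices."""
    model = cfg.substitution_model()
    rng = np.random.default_rng(cfg.seed + 1)
    L = cfg.n_sites
    cats = rng.integers(0, model.k, size=L)
    root_states = rng.choice(N_STATES, size=L, p=model.freqs)

    rows: dict[str, np.ndarray] = {}

    def descend(node, states):
        for child in node.children:
            P = model.transition_matrices(child.length)  # (k,20,20)
            child_states = np.empty(L, dtype=np.int64)
            u = rng.random(L)
            for c in range(model.k):
                mask = cats == c
                if not mask.any():
                    continue
                cum = np.cumsum(P[c][states[mask]], axis=1)
                child_states[mask] = (u[mask, None] > cum).sum(axis=1)
            if child.is_leaf:
                rows[child.label] = child_states
            else:
                descend(child, child_states)

    descend(tree.root, root_states)
    labels = tree.leaf_labels()
    return ProteinAlignment(
        list(labels),
        ["".join(AA_LETTERS[s] for s in rows[lb]) for lb in labels],
    )


def simulate_radiation_dataset(cfg: SimConfig) -> tuple[Tree, TreeTruth, ProteinAlignment]:
    tree, truth = simulate_tree(cfg)
    return tree, truth, evolve_alignment(tree, cfg)


# -- R2-like proteins ----------------------------------------------------------

ZF_PATTERNS: dict[str, tuple[str, ...]] = {
    "A": ("CCHH", "CCHC", "CCHH"),
    "B": ("CCHC", "CCHH"),
    "C": ("CCHH", "CCHH"),
    "D": ("CCHH",),
}

# spacer alphabet excludes the coordinating residues so planted motifs are
# the only grammar matches
_SPACER_AA = "".join(a for a in AA_LETTERS if a not in "CH")


def _spacer(rng, lo, hi) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(_SPACER_AA[i] for i in rng.integers(0, len(_SPACER_AA), size=n))


@dataclass
class PlantedMotif:
    type: str
    span: tuple[int, int]


def make_r2_protein(
    pattern: str,
    seed: int,
    grammar: ZincFingerGrammar | None = None,
    tail_length: tuple[int, int] = (60, 160),
) -> tuple[str, list[PlantedMotif]]:
    """Protein with the clade's ZF motifs planted in order, plus ground truth."""
    if pattern not in ZF_PATTERNS:
        raise RadsigError(f"pattern must be one of {sorted(ZF_PATTERNS)}, got {pattern!r}")
    grammar = grammar or ZincFingerGrammar()
    rng = np.random.default_rng(seed)
    parts = [_spacer(rng, 5, 30)]
    truth: list[PlantedMotif] = []
    pos = len(parts[0])
    for i, kind in enumerate(ZF_PATTERNS[pattern]):
        if i:
            gap = _spacer(rng, 10, 40)
            parts.append(gap)
            pos += len(gap)
        motif = (
            "C" + _spacer(rng, *grammar.c_c)
            + "C" + _spacer(rng, *grammar.c_h)
            + "H" + _spacer(rng, *grammar.h_h)
            + kind[3]
        )
        parts.append(motif)
        truth.append(PlantedMotif(kind, (pos, pos + len(motif))))
        pos += len(motif)
    parts.append(_spacer(rng, *tail_length))
    return "".join(parts), truth


# -- rDNA loci -----------------------------------------------------------------

_NUC = "ACGT"
_FORBIDDEN = (UPSTREAM_HALF, DOWNSTREAM_HALF, TARGET_MOTIF)


def _random_nuc(rng, n: int) -> str:
    s = list(_NUC[i] for i in rng.integers(0, 4, size=n))
    text = "".join(s)
    # scrub accidental half-sites so detector hits are exactly the planted ones
    changed = True
    while changed:
        changed = False
        for bad in _FORBIDDEN:
            k = text.find(bad)
            while k != -1:
                pos = k + int(rng.integers(0, len(bad)))
                old = text[pos]
                new = _NUC[int(rng.integers(0, 4))]
                while new == old:
                    new = _NUC[int(rng.integers(0, 4))]
                text = text[:pos] + new + text[pos + 1 :]
                changed = True
                k = text.find(bad)
    return text


@dataclass
class PlantedJunction:
    cleavage: int
    interval: tuple[int, int]

    @property
    def inserted(self) -> bool:
        return self.interval[0] != self.interval[1]


def make_rdna_locus(
    n_units: int,
    insert_at: set[int],
    element_length: int = 1000,
    seed: int = 0,
    unit_flank: int = 120,
) -> tuple[NucSequence, list[PlantedJunction]]:
    """Tandem 28S-like units, each with the exact target motif; units in
    ``insert_at`` carry an element between the TTAAGG and TAGCCA
    half-sites. Ground-truth cleavage coordinates and inserted intervals
    are returned in locus coordinates."""
    if not insert_at <= set(range(n_units)):
        raise RadsigError(f"insert_at {sorted(insert_at)} outside unit range 0..{n_units - 1}")
    if n_units < 1:
        raise RadsigError("need at least one unit")
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    truth: list[PlantedJunction] = []
    pos = 0

    def push(s: str):
        nonlocal pos
        pieces.append(s)
        pos += len(s)

    for u in range(n_units):
        push(_random_nuc(rng, unit_flank))
        push("TTAAGG")
        cleavage = pos
        if u in insert_at:
            element = _random_nuc(rng, element_length)
            push(element)
            truth.append(PlantedJunction(cleavage, (cleavage, pos)))
        else:
            truth.append(PlantedJunction(cleavage, (cleavage, cleavage)))
        push("TAGCCA")
        push(_random_nuc(rng, unit_flank))
    return NucSequence(f"locus_{seed}", "".join(pieces)), truth


# -- library-model trees ---------------------------------------------------------

def _random_species_topology(n_species: int, rng) -> Node:
    nodes = [Node(label=f"sp{i + 1}") for i in range(n_species)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for x, n in enumerate(nodes) if x not in (i, j)] + [parent]
    return nodes[0]


def _clone_renamed(node: Node, suffix: str, rng, scale: float) -> Node:
    out = Node(
        label=f"{node.label}_{suffix}" if node.is_leaf else None,
        length=float(rng.exponential(scale)),
    )
    for c in node.children:
        out.add(_clone_renamed(c, suffix, rng, scale))
    return out


def simulate_library(
    n_species: int,
    n_classes: int,
    cfg: SimConfig,
    mode: str = "library",
    class_clades: list[str] | None = None,
) -> tuple[Tree, LineageTable]:
    """Element tree plus lineage table under two scenarios.

    ``library``: lineage classes diverge on a deep star predating the
    species splits; within each class the lineages track a shared species
    topology, so conspecific lineages are never sisters. ``duplication``:
    lineages duplicate after speciation, so each species' lineages form a
    cherry/clade and conspecific clustering is maximal.
    """
    if n_species < 2 or n_classes < 2:
        raise RadsigError("need at least 2 species and 2 classes")
    if mode not in ("library", "duplication"):
        raise RadsigError(f"mode must be 'library' or 'duplication', got {mode!r}")
    rng = np.random.default_rng(cfg.seed)
    classes = [chr(ord("x") + i) if i < 3 else f"c{i + 1}" for i in range(n_classes)]
    clades = class_clades or [("A", "B", "C", "D")[i % 4] for i in range(n_classes)]
    if len(clades) != n_classes:
        raise RadsigError("class_clades must have one clade per class")
    species_top = _random_species_topology(n_species, rng)
    root = Node()
    scale = cfg.terminal_scale
    if mode == "library":
        for cls in classes:
            sub = _clone_renamed(species_top, cls, rng, scale)
            sub.length = 2.0 + float(rng.exponential(scale))  # deep class stems
            root.add(sub)
    else:
        def clone_dup(node: Node) -> Node:
            if node.is_leaf:
                holder = Node(length=float(rng.exponential(scale)))
                for cls in classes:
                    holder.add(
                        Node(label=f"{node.label}_{cls}", length=float(rng.exponential(scale)))
                    )
                return holder
            out = Node(length=float(rng.exponential(scale)))
            for c in node.children:
                out.add(clone_dup(c))
            return out

        root = clone_dup(species_top)
    root.length = None
    records = [
        (f"sp{i + 1}_{cls}", f"sp{i + 1}", clades[c])
        for c, cls in enumerate(classes)
        for i in range(n_species)
    ]
    return Tree(root), LineageTable(records)
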