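"""Amino-acid substitution models and Felsenstein-pruning likelihoods.

Implements time-reversible 20-state CTMC models (Poisson and rtREV),
discrete-gamma rate heterogeneity with mean-of-bin category rates, and
vectorised pruning log-likelihoods over site patterns.

The rate matrix is built as Q = S diag(pi), its diagonal set so rows sum
to zero, then scaled so that the expected substitution rate at
equilibrium is one (-sum_i pi_i Q_ii = 1); branch lengths are therefore
expected substitutions per site.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from ._rtrev_data import RTREV_FREQS, RTREV_LOWER
from .core import AA_LETTERS, ProteinAlignment, RadsigError
from .tree import Tree

N_STATES = 20
_AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rate of each of k equal-probability bins of Gamma(alpha, 1/alpha).

    The weighted mean of the category rates is exactly 1.
    """
    if alpha <= 0:
        raise RadsigError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise RadsigError(f"need at least one rate category, got {k}")
    if k == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
    # mean over a bin: k * [F_{alpha+1}(b) - F_{alpha+1}(a)] for Gamma(alpha, 1/alpha)
    cdf_up = gamma_dist.cdf(edges, a=alpha + 1.0, scale=1.0 / alpha)
    rates = k * np.diff(cdf_up)
    return rates


@dataclass
class SubstitutionModel:
    """A reversible amino-acid model with discrete-gamma rate categories."""

    name: str
    exchangeabilities: np.ndarray  # 20x20 symmetric, zero diagonal
    freqs: np.ndarray  # equilibrium frequencies, simplex
    alpha: float = 1.0
    k: int = 1

    _eig: tuple = field(init=False, repr=False)
    rates: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.freqs, dtype=float)
        if S.shape != (N_STATES, N_STATES):
            raise RadsigError("exchangeability matrix must be 20x20")
        if not np.allclose(S, S.T):
            raise RadsigError("exchangeability matrix must be symmetric")
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise RadsigError("frequencies must be positive and sum to 1")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        Q /= mu
        self.Q = Q
        self.freqs = pi
        # symmetrise: B = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        lam, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eig = (lam, U / d[:, None], (U * d[:, None]).T)
        self.rates = discrete_gamma_rates(self.alpha, self.k)

    def with_alpha(self, alpha: float, k: int | None = None) -> "SubstitutionModel":
        return SubstitutionModel(
            self.name, self.exchangeabilities, self.freqs, alpha, self.k if k is None else k
        )

    def transition_matrix(self, t: float, category: int = 0) -> np.ndarray:
        """P(t) for the given rate category; rows sum to 1."""
        if t < 0:
            raise RadsigError(f"branch length must be non-negative, got {t}")
        r = self.rates[category]
        lam, left, right = self._eig
        P = (left * np.exp(lam * (r * t))) @ right
        return np.maximum(P, 0.0)

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t) over all rate categories, shape (k, 20, 20)."""
        if t < 0:
            raise RadsigError(f"branch length must be non-negative, got {t}")
        lam, left, right = self._eig
        expo = np.exp(lam[None, :] * (self.rates[:, None] * t))
        P = np.einsum("il,cl,lj->cij", left, expo, right)
        return np.maximum(P, 0.0)


def poisson_model(alpha: float = 1.0, k: int = 1) -> SubstitutionModel:
    """Equal-rates 20-state model (the amino-acid Jukes-Cantor analogue)."""
    S = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
    pi = np.full(N_STATES, 1.0 / N_STATES)
    return SubstitutionModel("poisson", S, pi, alpha, k)


def rtrev_model(alpha: float = 1.0, k: int = 4) -> SubstitutionModel:
    """rtREV: the retrovirus-derived reverse-transcriptase matrix."""
    S = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(RTREV_LOWER, start=1):
        for j, v in enumerate(row):
            S[i, j] = S[j, i] = v
    pi = np.array(RTREV_FREQS)
    return SubstitutionModel("rtrev", S, pi, alpha, k)


def get_model(name: str, alpha: float = 1.0, k: int = 4) -> SubstitutionModel:
    if name == "poisson":
        return poisson_model(alpha, k)
    if name == "rtrev":
        return rtrev_model(alpha, k)
    raise RadsigError(f"unknown model {name!r}; expected 'poisson' or 'rtrev'")


# -- alignment encoding ------------------------------------------------------

def encode_alignment(aln: ProteinAlignment, ids: list[str] | None = None):
    """Encode rows as integer codes; 20 marks gap/X (fully ambiguous).

    Returns (codes array of shape (n, L), row ids).
    """
    ids = list(aln.ids) if ids is None else ids
    n, L = len(ids), aln.length
    codes = np.empty((n, L), dtype=np.int8)
    for i, sid in enumerate(ids):
        row = aln.row(sid)
        codes[i] = [_AA_INDEX.get(c, N_STATES) for c in row]
    return codes, ids


def compress_patterns(codes: np.ndarray):
    """Collapse identical columns; returns (patterns (n, npat), counts)."""
    cols = codes.T
    uniq, counts = np.unique(cols, axis=0, return_counts=True)
    return uniq.T, counts.astype(float)


_LEAF_ONEHOT = np.vstack([np.eye(N_STATES), np.ones((1, N_STATES))])


def leaf_conditionals(codes_row: np.ndarray) -> np.ndarray:
    """Per-site conditional likelihood vectors for a leaf (npat, 20)."""
    return _LEAF_ONEHOT[codes_row]


# -- pruning -----------------------------------------------------------------

def tree_loglik(tree: Tree, aln: ProteinAlignment, model: SubstitutionModel) -> float:
    """Pruning log-likelihood of the alignment on the tree.

    Sites are summed; rate categories averaged with equal weights. Gaps
    and X contribute a factor of one for every state. The root placement
    does not affect the value (reversible models; pulley principle).
    """
    labels = tree.leaf_labels()
    missing = [lb for lb in labels if lb not in aln.ids]
    if missing:
        raise RadsigError(f"leaf labels not in alignment: {missing}")
    codes, ids = encode_alignment(aln, labels)
    patterns, counts = compress_patterns(codes)
    idx = {lb: i for i, lb in enumerate(ids)}
    k = model.k
    npat = patterns.shape[1]

    conds: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leaf = leaf_conditionals(patterns[idx[node.label]])
            conds[id(node)] = np.broadcast_to(leaf, (k, npat, N_STATES))
        else:
            acc = np.ones((k, npat, N_STATES))
            for child in node.children:
                P = model.transition_matrices(child.length)  # (k,20,20)
                acc = acc * np.einsum("cps,cxs->cpx", conds.pop(id(child)), P)
            conds[id(node)] = acc
    root_cond = conds[id(tree.root)]
    site_lik = (root_cond @ model.freqs).mean(axis=0)  # average over categories
    if np.any(site_lik <= 0):
        raise RadsigError("zero site likelihood encountered")
    return float(np.dot(counts, np.log(site_lik)))


def estimate_alpha(
    tree: Tree,
    aln: ProteinAlignment,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (0.05, 50.0),
) -> float:
    """ML estimate of the gamma shape on a fixed tree (1-D bounded search)."""

    def neg(a: float) -> float:
        return -tree_loglik(tree, aln, model.with_alpha(a))

    res = minimize_scalar(neg, bounds=bounds, method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)
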