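"""Quartet likelihood mapping.

For each sampled four-taxon subset, the ML log-likelihoods of the three
unrooted quartet topologies are turned into barycentric posterior
weights (a softmax with equal topology priors) and classified into the
seven regions of the likelihood-mapping simplex: three corners (resolved
topology), three edges (conflicting signal) and a center (unresolved,
star-like signal).

The seven-region geometry follows an explicit, configurable rule:
center when the largest weight is below ``center_threshold`` (default
1/2); otherwise a corner when the second-largest weight is below
``corner_threshold`` (default 1/3); otherwise the edge between the two
largest weights.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chi2_contingency

from .core import ProteinAlignment, RadsigError
from .substitution import (
    N_STATES,
    SubstitutionModel,
    compress_patterns,
    encode_alignment,
    leaf_conditionals,
)

REGIONS = ("corner1", "corner2", "corner3", "edge12", "edge13", "edge23", "center")
CORNERS = ("corner1", "corner2", "corner3")
EDGES = ("edge12", "edge13", "edge23")

# topology T1=(ab|cd), T2=(ac|bd), T3=(ad|bc): index pairs into (a,b,c,d)
_TOPOLOGY_PAIRS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


@dataclass(frozen=True)
class Quartet:
    taxa: tuple[str, str, str, str]
    clusters: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != 4:
            raise RadsigError(f"quartet taxa must be distinct: {self.taxa}")


@dataclass
class QuartetWeights:
    quartet: Quartet
    logliks: tuple[float, float, float]
    weights: tuple[float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        ll = np.asarray(self.logliks, dtype=float)
        w = np.exp(ll - logsumexp(ll))
        self.weights = tuple(w / w.sum())


# -- sampling ----------------------------------------------------------------

def sample_quartets_random(taxa: list[str], n: int, seed: int) -> list[Quartet]:
    """n quartets drawn uniformly, no repetition within a quartet."""
    if len(taxa) < 4:
        raise RadsigError(f"need at least 4 taxa, got {len(taxa)}")
    if n < 1:
        raise RadsigError("need at least one quartet")
    rng = np.random.default_rng(seed)
    taxa = list(taxa)
    return [
        Quartet(tuple(taxa[i] for i in rng.choice(len(taxa), size=4, replace=False)))
        for _ in range(n)
    ]


def sample_quartets_clustered(
    cluster_map: dict[str, int], n: int, seed: int
) -> list[Quartet]:
    """One taxon per cluster, so T1 corresponds to (cluster1,cluster2 | cluster3,cluster4)."""
    groups = {c: sorted(t for t, g in cluster_map.items() if g == c) for c in (1, 2, 3, 4)}
    empty = [c for c, members in groups.items() if not members]
    if empty:
        raise RadsigError(f"empty cluster(s): {empty}")
    if n < 1:
        raise RadsigError("need at least one quartet")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        taxa = tuple(groups[c][rng.integers(len(groups[c]))] for c in (1, 2, 3, 4))
        out.append(Quartet(taxa, clusters=(1, 2, 3, 4)))
    return out


# -- quartet ML --------------------------------------------------------------

class _QuartetLikelihood:
    """Pruning likelihood of one pairing ((x1,x2),(x3,x4)) as a function of
    the five branch lengths (four terminal, internal last).

    Conditionals are propagated in the eigenbasis of the symmetrised rate
    matrix, so evaluating the likelihood after changing a single branch
    costs one small matrix product; the coordinate-descent driver exploits
    this by freezing the parts a 1-D move does not touch.
    """

    def __init__(self, leaves, counts, model: SubstitutionModel):
        self.counts = counts
        self.model = model
        lam, left, right = model._eig
        self.lam = lam
        self.leftT = left.T
        self.rightT = right.T
        self.rates = model.rates
        self.pi = model.freqs
        self.k = model.k
        # leaf conditionals projected onto the right eigenvectors
        self.proj = [leaf @ self.rightT for leaf in leaves]  # (npat, 20) each

    def _expf(self, t: float) -> np.ndarray:
        return np.exp(self.lam[None, :] * (self.rates[:, None] * t))  # (k, 20)

    def leaf_cond(self, i: int, t: float) -> np.ndarray:
        """Conditional at the internal node through terminal branch i, (k,npat,20)."""
        e = self._expf(t)
        return (self.proj[i][None, :, :] * e[:, None, :]) @ self.leftT

    def propagate(self, cond: np.ndarray, t: float) -> np.ndarray:
        """Push a node conditional across the internal branch."""
        e = self._expf(t)
        return ((cond @ self.rightT) * e[:, None, :]) @ self.leftT

    def _ll_from_site(self, site: np.ndarray) -> float:
        if np.any(site <= 0):
            return -np.inf
        return float(self.counts @ np.log(site))

    def loglik(self, lengths) -> float:
        c = [self.leaf_cond(i, lengths[i]) for i in range(4)]
        u = c[0] * c[1]
        v = c[2] * c[3]
        site = ((u * self.propagate(v, lengths[4])) @ self.pi).mean(axis=0)
        return self._ll_from_site(site)

    __call__ = loglik

    def optimize(self, cfg: "OptimizerConfig") -> float:
        x = [cfg.init] * 5
        conds = [self.leaf_cond(i, x[i]) for i in range(4)]
        best = -np.inf
        for _ in range(cfg.max_sweeps):
            # terminal branches of the first pair: site = ((c_i * fixed) @ pi)
            v = conds[2] * conds[3]
            w = self.propagate(v, x[4])
            for i, j in ((0, 1), (1, 0)):
                fixed = conds[j] * w
                x[i] = self._opt1d(lambda t: ((self.leaf_cond(i, t) * fixed) @ self.pi).mean(0), cfg)
                conds[i] = self.leaf_cond(i, x[i])
            # by reversibility the root can sit on the other side of the
            # internal branch, so the second pair is symmetric
            u = conds[0] * conds[1]
            wu = self.propagate(u, x[4])
            for i, j in ((2, 3), (3, 2)):
                fixed = conds[j] * wu
                x[i] = self._opt1d(lambda t: ((self.leaf_cond(i, t) * fixed) @ self.pi).mean(0), cfg)
                conds[i] = self.leaf_cond(i, x[i])
            # internal branch last: site = sum_l (v-proj * e) * ((u*pi) @ left)
            u = conds[0] * conds[1]
            v = conds[2] * conds[3]
            H = (u * self.pi[None, None, :]) @ self.leftT.T
            RB = v @ self.rightT

            def site_internal(t: float) -> np.ndarray:
                e = self._expf(t)
                return ((RB * e[:, None, :]) * H).sum(axis=2).mean(axis=0)

            x[4] = self._opt1d(site_internal, cfg)
            new = self.loglik(x)
            if new - best < cfg.sweep_tol:
                best = max(new, best)
                break
            best = new
        return best

    def _opt1d(self, site_fn, cfg: "OptimizerConfig") -> float:
        def neg(t: float) -> float:
            site = site_fn(t)
            if np.any(site <= 0):
                return np.inf
            return -float(self.counts @ np.log(site))

        res = minimize_scalar(
            neg, bounds=(cfg.lower, cfg.upper), method="bounded",
            options={"xatol": cfg.xatol},
        )
        return float(res.x)


@dataclass
class OptimizerConfig:
    lower: float = 1e-6
    upper: float = 10.0
    xatol: float = 1e-6
    max_sweeps: int = 50
    sweep_tol: float = 1e-6
    init: float = 0.1


def _optimize_branches(lik: _QuartetLikelihood, cfg: OptimizerConfig) -> float:
    return lik.optimize(cfg)


def quartet_ml(
    aln: ProteinAlignment,
    quartet: Quartet,
    model: SubstitutionModel,
    optimizer: OptimizerConfig | None = None,
) -> QuartetWeights:
    """ML branch lengths for each of the three topologies; softmax weights.

    Sites that are gap/X across all four taxa are dropped; fewer than one
    usable site is an error.
    """
    optimizer = optimizer or OptimizerConfig()
    codes, ids = encode_alignment(aln, list(quartet.taxa))
    usable = (codes < N_STATES).any(axis=0)
    if not usable.any():
        raise RadsigError("no usable sites for quartet (all gap/unknown)")
    patterns, counts = compress_patterns(codes[:, usable])
    leaves = [leaf_conditionals(patterns[i]) for i in range(4)]
    lls = []
    for (p1, p2), (p3, p4) in _TOPOLOGY_PAIRS:
        lik = _QuartetLikelihood([leaves[p1], leaves[p2], leaves[p3], leaves[p4]], counts, model)
        lls.append(_optimize_branches(lik, optimizer))
    return QuartetWeights(quartet, tuple(lls))


# -- region classification ---------------------------------------------------

def classify_region(
    w: QuartetWeights | tuple[float, float, float],
    center_threshold: float = 0.5,
    corner_threshold: float = 1.0 / 3.0,
) -> str:
    weights = w.weights if isinstance(w, QuartetWeights) else tuple(w)
    order = sorted(range(3), key=lambda i: (-weights[i], i))  # ties toward lower index
    q, s = weights[order[0]], weights[order[1]]
    if q < center_threshold:
        return "center"
    if s < corner_threshold:
        return f"corner{order[0] + 1}"
    i, j = sorted((order[0], order[1]))
    return f"edge{i + 1}{j + 1}"


@dataclass
class RegionCounts:
    counts: dict[str, int]
    n_quartets: int

    def __post_init__(self) -> None:
        missing = set(REGIONS) - set(self.counts)
        if missing:
            self.counts = {**{r: 0 for r in REGIONS}, **self.counts}
        if any(v < 0 for v in self.counts.values()):
            raise RadsigError("negative region count")
        if sum(self.counts.values()) != self.n_quartets:
            raise RadsigError("region counts do not sum to n_quartets")

    @property
    def resolved(self) -> int:
        return sum(self.counts[c] for c in CORNERS)

    @property
    def conflicting(self) -> int:
        return sum(self.counts[e] for e in EDGES)

    @property
    def unresolved(self) -> int:
        return self.counts["center"]

    def percentages(self) -> dict[str, float]:
        n = self.n_quartets
        return {
            "resolved": 100.0 * self.resolved / n,
            "conflicting": 100.0 * self.conflicting / n,
            "unresolved": 100.0 * self.unresolved / n,
        }

    def summary(self) -> str:
        p = self.percentages()
        return (
            f"{self.n_quartets} quartets: resolved {p['resolved']:.1f}%, "
            f"conflicting {p['conflicting']:.1f}%, unresolved {p['unresolved']:.1f}%"
        )


def summarize_run(labels: list[str]) -> RegionCounts:
    if not labels:
        raise RadsigError("no region labels to summarise")
    counts = {r: 0 for r in REGIONS}
    for lb in labels:
        if lb not in counts:
            raise RadsigError(f"unknown region label {lb!r}")
        counts[lb] += 1
    return RegionCounts(counts, len(labels))


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    infinite: bool = False


def compare_runs_chi2(
    reference: RegionCounts, test: RegionCounts, mode: str = "goodness_of_fit"
) -> Chi2Result:
    """Compare two likelihood-mapping runs on the 3-category summary
    (resolved / conflicting / unresolved).

    The primary mode tests the second run's counts against expected
    counts given by the reference run's proportions (goodness of fit,
    df=2); a 2x3 contingency test is available as an option.
    """
    ref = np.array([reference.resolved, reference.conflicting, reference.unresolved], float)
    obs = np.array([test.resolved, test.conflicting, test.unresolved], float)
    if ref.sum() == 0 or obs.sum() == 0:
        raise RadsigError("empty run")
    if mode == "contingency":
        stat, p, df, _ = chi2_contingency(np.vstack([ref, obs]))
        return Chi2Result(float(stat), int(df), float(p))
    if mode != "goodness_of_fit":
        raise RadsigError(f"unknown chi2 mode {mode!r}")
    props = ref / ref.sum()
    if np.any((props == 0) & (obs > 0)):
        return Chi2Result(np.inf, 2, 0.0, infinite=True)
    keep = props > 0
    expected = obs.sum() * props
    stat = float(((obs[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    return Chi2Result(stat, 2, float(chi2_dist.sf(stat, 2)))


# -- model / results objects -------------------------------------------------

class QuartetMapping:
    """Likelihood-mapping analysis of a protein alignment.

    Parameters
    ----------
    alignment : ProteinAlignment
    model : SubstitutionModel
    clusters : optional dict taxon -> {1..4} enabling clustered sampling.
    """

    def __init__(
        self,
        alignment: ProteinAlignment,
        model: SubstitutionModel,
        clusters: dict[str, int] | None = None,
    ):
        self.alignment = alignment
        self.model = model
        self.clusters = clusters

    def fit(
        self,
        n: int = 5000,
        seed: int = 0,
        sampling: str = "random",
        optimizer: OptimizerConfig | None = None,
        center_threshold: float = 0.5,
        corner_threshold: float = 1.0 / 3.0,
    ) -> "QuartetMappingResults":
        if sampling == "random":
            quartets = sample_quartets_random(self.alignment.ids, n, seed)
        elif sampling == "clustered":
            if self.clusters is None:
                raise RadsigError("clustered sampling requires a cluster map")
            quartets = sample_quartets_clustered(self.clusters, n, seed)
        else:
            raise RadsigError(f"unknown sampling {sampling!r}")
        results = [quartet_ml(self.alignment, q, self.model, optimizer) for q in quartets]
        labels = [classify_region(w, center_threshold, corner_threshold) for w in results]
        return QuartetMappingResults(self, results, labels, sampling, seed)


class QuartetMappingResults:
    def __init__(self, mapping, weights, labels, sampling, seed):
        self.model_spec = mapping
        self.weights = weights
        self.labels = labels
        self.sampling = sampling
        self.seed = seed
        self.region_counts = summarize_run(labels)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w, lb in zip(self.weights, self.labels):
            rows.append(
                dict(
                    zip(("taxon_a", "taxon_b", "taxon_c", "taxon_d"), w.quartet.taxa),
                    ll1=w.logliks[0], ll2=w.logliks[1], ll3=w.logliks[2],
                    p1=w.weights[0], p2=w.weights[1], p3=w.weights[2],
                    region=lb,
                )
            )
        return pd.DataFrame(rows)

    def compare_to(self, other: "QuartetMappingResults", mode: str = "goodness_of_fit") -> Chi2Result:
        return compare_runs_chi2(self.region_counts, other.region_counts, mode)

    def summary(self) -> str:
        lines = [
            "Quartet likelihood mapping",
            f"  sampling: {self.sampling} (seed {self.seed})",
            f"  model: {self.model_spec.model.name} "
            f"(alpha={self.model_spec.model.alpha}, k={self.model_spec.model.k})",
            "  " + self.region_counts.summary(),
            "  region counts: "
            + ", ".join(f"{r}={self.region_counts.counts[r]}" for r in REGIONS),
        ]
        return "\n".join(lines)
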