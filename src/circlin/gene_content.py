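"""Phyletic-pattern analysis and gene gain/loss reconstruction under a
two-state birth-death model on a fixed guide tree.

Each gene family is a binary character (present/absent) evolving along
the branches of a rooted species tree as a continuous-time Markov chain
with gain rate g (0 -> 1) and loss rate l (1 -> 0) per unit branch
length. Branch transition probabilities follow the standard two-state
solution,

    P01(t) = (g / (g + l)) (1 - exp(-(g + l) t))
    P10(t) = (l / (g + l)) (1 - exp(-(g + l) t)),

with P00 = 1 - P01 and P11 = 1 - P10. Likelihoods are computed by
Felsenstein pruning; ancestral presence posteriors by the up-down
(inside-outside) recursion; rates by bounded maximum likelihood,
optionally conditioned on a family being observed in at least one
genome (the ascertainment correction appropriate for ortholog-cluster
matrices, which never contain all-absent families).

This is a presence/absence simplification: gene duplications and family
sizes are not modelled, only gain and loss of families.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

RATE_LOWER = 1e-6
RATE_UPPER = 50.0
PRESENCE_CUTOFF = 0.5

# deterministic multi-start points for (gain, loss)
_STARTS = [(0.1, 0.1), (0.05, 0.2), (0.5, 0.5), (1.0, 1.0), (0.01, 0.01)]


@dataclass
class PhyleticMatrix:
    """Gene-family copy counts (families x genomes); presence = count >= 1."""

    families: list[str]
    genomes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.families), len(self.genomes)):
            raise ValueError("counts shape does not match family/genome lists")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.families)) != len(self.families):
            raise ValueError("duplicate family ids")
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("duplicate genome ids")

    @property
    def presence(self) -> np.ndarray:
        return (self.counts >= 1).astype(np.int8)

    @classmethod
    def from_tsv(cls, path) -> "PhyleticMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            families=[str(f) for f in df.index],
            genomes=[str(g) for g in df.columns],
            counts=df.to_numpy(dtype=np.int64),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.families, columns=self.genomes).to_csv(
            path, sep="\t", index_label="family"
        )


@dataclass(frozen=True)
class BirthDeathRates:
    gain_rate: float
    loss_rate: float
    root_presence_prior: float | None = None  # None -> stationary g/(g+l)

    def __post_init__(self) -> None:
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.root_presence_prior is not None and not (
            0 <= self.root_presence_prior <= 1
        ):
            raise ValueError("root prior must be in [0, 1]")

    @property
    def root_prior(self) -> float:
        if self.root_presence_prior is not None:
            return self.root_presence_prior
        total = self.gain_rate + self.loss_rate
        return self.gain_rate / total if total > 0 else 0.5


class GuideTree:
    """A rooted guide tree indexed for vectorized pruning.

    Nodes are numbered in postorder (leaves and internals interleaved,
    root last). Branch lengths missing from the newick are replaced by
    unit lengths with a warning. Polytomies are supported directly.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        nodes = list(tree.postorder_node_iter())
        self._index = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.blen = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.labels: list[str] = []
        self.leaf_indices: list[int] = []
        missing_blen = False
        n_internal = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self._index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                if nd.edge.length is None:
                    missing_blen = True
                    self.blen[i] = 1.0
                else:
                    if nd.edge.length < 0:
                        raise ValueError("negative branch length")
                    self.blen[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("leaf without a label")
                self.labels.append(nd.taxon.label)
                self.leaf_indices.append(i)
            else:
                n_internal += 1
                label = nd.taxon.label if nd.taxon else (nd.label or f"node{n_internal}")
                self.labels.append(label)
        if missing_blen:
            logger.warning("guide tree lacks some branch lengths; using 1.0")
        self.root = self.n_nodes - 1
        self.leaf_labels = [self.labels[i] for i in self.leaf_indices]
        if len(set(self.leaf_labels)) != len(self.leaf_labels):
            raise ValueError("duplicate leaf labels")

    @classmethod
    def from_newick(cls, newick: str) -> "GuideTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "GuideTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    def branches(self) -> list[tuple[int, int]]:
        """(parent, child) index pairs, postorder by child."""
        return [(int(self.parent[i]), i) for i in range(self.n_nodes) if self.parent[i] >= 0]


@dataclass
class AncestralReconstruction:
    tree: GuideTree
    families: list[str]
    posterior: np.ndarray  # (n_nodes, n_families) presence probabilities
    calls: np.ndarray  # bool, posterior > cutoff
    branch_gains: np.ndarray  # (n_nodes,) counts on the branch above each node
    branch_losses: np.ndarray
    rates: BirthDeathRates

    def node_posterior(self, label: str) -> dict[str, float]:
        i = self.tree.labels.index(label)
        return dict(zip(self.families, self.posterior[i]))


def _transition_matrices(tree: GuideTree, rates: BirthDeathRates) -> np.ndarray:
    """P[i] is the 2x2 transition matrix on the branch above node i."""
    g, l = rates.gain_rate, rates.loss_rate
    total = g + l
    t = tree.blen
    P = np.zeros((tree.n_nodes, 2, 2))
    if total == 0:
        P[:] = np.eye(2)
        return P
    decay = np.exp(-total * t)
    p01 = (g / total) * (1 - decay)
    p10 = (l / total) * (1 - decay)
    P[:, 0, 0] = 1 - p01
    P[:, 0, 1] = p01
    P[:, 1, 0] = p10
    P[:, 1, 1] = 1 - p10
    return P


def _leaf_pattern_matrix(
    matrix: PhyleticMatrix, tree: GuideTree
) -> np.ndarray:
    """Presence patterns aligned to the tree's leaf order: (F, n_leaves)."""
    missing = [lab for lab in tree.leaf_labels if lab not in matrix.genomes]
    if missing:
        raise ValueError(f"tree leaves absent from matrix: {missing}")
    cols = [matrix.genomes.index(lab) for lab in tree.leaf_labels]
    return matrix.presence[:, cols]


def _inside(
    patterns: np.ndarray, tree: GuideTree, P: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pruning pass. Returns (partials, log_scale).

    partials[i, f, s] is proportional to P(data below node i | state s),
    rescaled per node/family; log_scale[f] accumulates the rescaling.
    """
    F = patterns.shape[0]
    partials = np.ones((tree.n_nodes, F, 2))
    log_scale = np.zeros(F)
    for leaf_pos, i in enumerate(tree.leaf_indices):
        obs = patterns[:, leaf_pos]
        partials[i, :, 0] = obs == 0
        partials[i, :, 1] = obs == 1
    for i in range(tree.n_nodes):
        kids = tree.children[i]
        if not kids:
            continue
        acc = np.ones((F, 2))
        for c in kids:
            # message from child c to parent: sum_sc P[c][sp, sc] * partial_c[sc]
            acc *= partials[c] @ P[c].T
        mx = acc.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        partials[i] = acc / mx[:, None]
        log_scale += np.log(mx)
    return partials, log_scale


def _pattern_loglik(
    patterns: np.ndarray, tree: GuideTree, rates: BirthDeathRates
) -> np.ndarray:
    P = _transition_matrices(tree, rates)
    partials, log_scale = _inside(patterns, tree, P)
    pi = np.array([1 - rates.root_prior, rates.root_prior])
    lik = partials[tree.root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(lik) + log_scale


def likelihood(
    pattern: dict[str, int], tree: GuideTree, rates: BirthDeathRates
) -> float:
    """Log-likelihood of one presence/absence pattern (leaf label -> 0/1)."""
    missing = [lab for lab in tree.leaf_labels if lab not in pattern]
    if missing:
        raise ValueError(f"pattern missing leaves: {missing}")
    arr = np.array([[pattern[lab] for lab in tree.leaf_labels]], dtype=np.int8)
    return float(_pattern_loglik(arr, tree, rates)[0])


def _aggregate_patterns(patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, counts = np.unique(patterns, axis=0, return_counts=True)
    return uniq, counts.astype(np.float64)


def fit_rates(
    matrix: PhyleticMatrix,
    tree: GuideTree,
    correction_for_unobservable: bool = False,
    root_presence_prior: float | None = None,
) -> BirthDeathRates:
    """Maximum-likelihood global gain/loss rates.

    With ``correction_for_unobservable`` the likelihood of each family is
    conditioned on presence in at least one genome, the appropriate model
    when all-absent families can never enter the matrix. Unique phyletic
    patterns are aggregated, so cost is independent of family count.
    Deterministic: a fixed set of multi-starts feeds a bounded L-BFGS-B
    search over log-rates.
    """
    if len(matrix.families) < 1:
        raise ValueError("need at least one family")
    patterns = _leaf_pattern_matrix(matrix, tree)
    uniq, weights = _aggregate_patterns(patterns)
    all_absent = np.zeros((1, tree.n_leaves), dtype=np.int8)
    n_total = weights.sum()

    def neg_ll(log_rates: np.ndarray) -> float:
        g, l = np.exp(log_rates)
        rates = BirthDeathRates(g, l, root_presence_prior)
        ll = float(weights @ _pattern_loglik(uniq, tree, rates))
        if correction_for_unobservable:
            ll_absent = float(_pattern_loglik(all_absent, tree, rates)[0])
            denom = -np.expm1(ll_absent)  # 1 - P(all absent)
            if denom <= 0:
                return np.inf
            ll -= n_total * np.log(denom)
        return -ll if np.isfinite(ll) else np.inf

    bounds = [(np.log(RATE_LOWER), np.log(RATE_UPPER))] * 2
    best = None
    for g0, l0 in _STARTS:
        res = minimize(
            neg_ll,
            x0=np.log([g0, l0]),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("rate optimization failed to find a finite likelihood")
    g, l = np.exp(best.x)
    return BirthDeathRates(float(g), float(l), root_presence_prior)


def ancestral_states(
    matrix: PhyleticMatrix,
    tree: GuideTree,
    rates: BirthDeathRates,
    cutoff: float = PRESENCE_CUTOFF,
) -> AncestralReconstruction:
    """Marginal presence posteriors per node and family, with gain/loss calls.

    Uses the up-down recursion: the inside (pruning) pass conditions on
    data below each node, the outside pass on data elsewhere; their
    product gives the marginal posterior. Presence is called where the
    posterior exceeds ``cutoff``; a gain on a branch is a family called
    absent at the parent and present at the child, a loss the reverse.
    """
    patterns = _leaf_pattern_matrix(matrix, tree)
    F = patterns.shape[0]
    P = _transition_matrices(tree, rates)
    partials, _ = _inside(patterns, tree, P)
    pi = np.array([1 - rates.root_prior, rates.root_prior])

    outside = np.ones((tree.n_nodes, F, 2))
    outside[tree.root] = pi
    for i in range(tree.n_nodes - 1, -1, -1):
        kids = tree.children[i]
        if not kids:
            continue
        msgs = [partials[c] @ P[c].T for c in kids]  # (F, 2) indexed by parent state
        for idx, c in enumerate(kids):
            sib = outside[i].copy()
            for jdx, m in enumerate(msgs):
                if jdx != idx:
                    sib *= m
            # propagate through c's own branch: sum over parent state
            outside[c] = sib @ P[c]
            mx = outside[c].max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            outside[c] /= mx[:, None]

    joint = partials * outside
    denom = joint.sum(axis=2)
    denom = np.where(denom > 0, denom, 1.0)
    posterior = joint[:, :, 1] / denom

    calls = posterior > cutoff
    gains = np.zeros(tree.n_nodes, dtype=np.int64)
    losses = np.zeros(tree.n_nodes, dtype=np.int64)
    for p, c in tree.branches():
        gains[c] = int((~calls[p] & calls[c]).sum())
        losses[c] = int((calls[p] & ~calls[c]).sum())

    return AncestralReconstruction(
        tree=tree,
        families=list(matrix.families),
        posterior=posterior,
        calls=calls,
        branch_gains=gains,
        branch_losses=losses,
        rates=rates,
    )


def simulate_gene_content(
    tree: GuideTree,
    rates: BirthDeathRates,
    n_families: int,
    seed: int = 0,
) -> PhyleticMatrix:
    """Evolve binary family states down the tree; returns a presence matrix."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    P = _transition_matrices(tree, rates)
    states = np.zeros((tree.n_nodes, n_families), dtype=np.int8)
    states[tree.root] = rng.random(n_families) < rates.root_prior
    for i in range(tree.n_nodes - 1, -1, -1):
        for c in tree.children[i]:
            p_present = np.where(states[i] == 1, P[c, 1, 1], P[c, 0, 1])
            states[c] = rng.random(n_families) < p_present
    leaf_states = states[tree.leaf_indices].T  # (F, n_leaves)
    return PhyleticMatrix(
        families=[f"fam{i + 1}" for i in range(n_families)],
        genomes=list(tree.leaf_labels),
        counts=leaf_states.astype(np.int64),
    )


def group_core(matrix: PhyleticMatrix, group: set[str] | list[str]) -> set[str]:
    """Families present (count >= 1) in every genome of the group."""
    group = list(group)
    if not group:
        raise ValueError("group must be non-empty")
    unknown = [g for g in group if g not in matrix.genomes]
    if unknown:
        raise ValueError(f"unknown genome ids: {unknown}")
    cols = [matrix.genomes.index(g) for g in group]
    mask = (matrix.counts[:, cols] >= 1).all(axis=1)
    return {f for f, m in zip(matrix.families, mask) if m}


def lineage_specific(
    matrix: PhyleticMatrix,
    in_group: set[str] | list[str],
    out_group: set[str] | list[str],
) -> set[str]:
    """Families present in all of ``in_group`` and absent from all of ``out_group``."""
    in_group, out_group = list(in_group), list(out_group)
    if not in_group or not out_group:
        raise ValueError("both groups must be non-empty")
    if set(in_group) & set(out_group):
        raise ValueError("in_group and out_group overlap")
    unknown = [g for g in in_group + out_group if g not in matrix.genomes]
    if unknown:
        raise ValueError(f"unknown genome ids: {unknown}")
    in_cols = [matrix.genomes.index(g) for g in in_group]
    out_cols = [matrix.genomes.index(g) for g in out_group]
    mask = (matrix.counts[:, in_cols] >= 1).all(axis=1) & (
        matrix.counts[:, out_cols] == 0
    ).all(axis=1)
    return {f for f, m in zip(matrix.families, mask) if m}
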