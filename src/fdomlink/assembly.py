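"""Phylogenetic null-model analysis of community assembly: βMNTD and βNTI.

βMNTD is the abundance-weighted mean phylogenetic distance from each taxon to
its nearest relative in the other community. βNTI standardizes the observed
βMNTD against a null distribution generated by shuffling taxon labels across
the tips of the phylogeny; |βNTI| > 2 is conventionally read as deterministic
assembly and |βNTI| < 2 as stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .community import FeatureTable
from .errors import TreeError, UndefinedDistanceError

__all__ = [
    "Phylogeny",
    "BetaNTIResult",
    "cophenetic_distances",
    "beta_mntd",
    "beta_mntd_matrix",
    "beta_nti",
    "assembly_fractions",
]


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths whose tips are ASV ids."""

    tree: dendropy.Tree

    def __post_init__(self):
        labels = self.tip_labels
        if any(lbl is None for lbl in labels):
            raise TreeError("all tips must be named")
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label if leaf.taxon else None
                for leaf in self.tree.leaf_node_iter()]

    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=source, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", unquoted_underscores=True).strip()


def cophenetic_distances(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Patristic (path-sum) distances between all tip pairs.

    Computed as depth(i) + depth(j) − 2·depth(lca(i, j)) by a single pass over
    internal nodes, crossing the leaf sets of their child subtrees.
    """
    leaves = list(tree.tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)

    depth: dict[int, float] = {}
    for node in tree.tree.preorder_node_iter():
        parent_depth = depth.get(id(node.parent_node), 0.0)
        depth[id(node)] = parent_depth + (node.edge.length or 0.0)

    leaf_depth = np.array([depth[id(lf)] for lf in leaves])
    under: dict[int, list[int]] = {}
    d = np.zeros((n, n))
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            under[id(node)] = [index[id(node)]]
            continue
        child_sets = [under.pop(id(ch)) for ch in node.child_nodes()]
        node_depth = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia = np.asarray(child_sets[a])
                ib = np.asarray(child_sets[b])
                dist = leaf_depth[ia][:, None] + leaf_depth[ib][None, :] - 2.0 * node_depth
                d[np.ix_(ia, ib)] = dist
                d[np.ix_(ib, ia)] = dist.T
        under[id(node)] = [i for s in child_sets for i in s]
    return labels, d


def beta_mntd(x, y, d: np.ndarray, weighted: bool = True) -> float:
    """Between-community mean nearest taxon distance.

    ``x`` and ``y`` are relative-abundance vectors aligned with the taxa of
    distance matrix ``d``. For every taxon in one community the distance to
    its nearest taxon in the other community is taken (0 for shared taxa);
    the two directed means are averaged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x > 0
    sy = y > 0
    if not sx.any() or not sy.any():
        raise UndefinedDistanceError("βMNTD undefined for an empty community")
    min_to_y = d[:, sy].min(axis=1)
    min_to_x = d[:, sx].min(axis=1)
    if weighted:
        wx = x[sx] / x[sx].sum()
        wy = y[sy] / y[sy].sum()
    else:
        wx = np.full(sx.sum(), 1.0 / sx.sum())
        wy = np.full(sy.sum(), 1.0 / sy.sum())
    return float(0.5 * ((wx * min_to_y[sx]).sum() + (wy * min_to_x[sy]).sum()))


def beta_mntd_matrix(rel: np.ndarray, d: np.ndarray, weighted: bool = True) -> np.ndarray:
    """All-pairs βMNTD for a (taxa × samples) relative-abundance matrix."""
    n_taxa, n_samples = rel.shape
    present = rel > 0
    if not present.any(axis=0).all():
        raise UndefinedDistanceError("βMNTD undefined: empty sample present")
    m = np.empty((n_taxa, n_samples))
    for s in range(n_samples):
        m[:, s] = d[:, present[:, s]].min(axis=1)
    if weighted:
        w = rel / rel.sum(axis=0)
    else:
        w = present / present.sum(axis=0)
    t = w.T @ m  # t[x, y] = Σ_i w_x(i) · min-dist(i → community y)
    return 0.5 * (t + t.T)


@dataclass
class BetaNTIResult:
    sample_ids: list[str]
    bmntd_obs: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    bnti: np.ndarray       # NaN where null_sd == 0
    n_null: int
    seed: int | None

    def values(self) -> np.ndarray:
        """Finite upper-triangle βNTI values."""
        iu = np.triu_indices(len(self.sample_ids), 1)
        v = self.bnti[iu]
        return v[np.isfinite(v)]

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "sample_i": self.sample_ids[i],
                    "sample_j": self.sample_ids[j],
                    "bmntd": self.bmntd_obs[i, j],
                    "null_mean": self.null_mean[i, j],
                    "null_sd": self.null_sd[i, j],
                    "bnti": self.bnti[i, j],
                })
        return pd.DataFrame(rows)


def beta_nti(table: FeatureTable, tree: Phylogeny, n_null: int = 999,
             weighted: bool = True, seed: int = 0) -> BetaNTIResult:
    """βNTI for all sample pairs via the taxa-shuffle null model.

    Each null draw permutes taxon labels across the phylogeny's tips
    (equivalently, jointly permutes the rows of the abundance matrix against
    the fixed distance matrix) and recomputes βMNTD for all pairs. Pairs with
    zero null standard deviation are returned as NaN rather than fabricated.
    """
    if table.n_samples < 2:
        raise UndefinedDistanceError("βNTI needs at least 2 samples")
    labels, d = cophenetic_distances(tree)
    pos = {lbl: i for i, lbl in enumerate(labels)}
    missing = [a for a in table.asv_ids if a not in pos]
    if missing:
        raise TreeError(f"ASVs absent from the tree: {missing[:5]}"
                        + ("..." if len(missing) > 5 else ""))
    order = [pos[a] for a in table.asv_ids]
    d = d[np.ix_(order, order)]
    rel = table.relative_abundance()

    obs = beta_mntd_matrix(rel, d, weighted=weighted)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = table.n_samples
    mean_acc = np.zeros((n, n))
    m2_acc = np.zeros((n, n))
    for draw in range(1, n_null + 1):
        perm = rng.permutation(table.n_asvs)
        null = beta_mntd_matrix(rel[perm], d, weighted=weighted)
        delta = null - mean_acc
        mean_acc += delta / draw
        m2_acc += delta * (null - mean_acc)
    null_sd = np.sqrt(m2_acc / max(n_null - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(null_sd > 0, (obs - mean_acc) / null_sd, np.nan)
    # degenerate null exactly at the observed value: z-score is 0, not undefined
    degenerate = (null_sd == 0) & (np.abs(obs - mean_acc) < 1e-12)
    bnti[degenerate] = 0.0
    np.fill_diagonal(bnti, 0.0)
    return BetaNTIResult(
        sample_ids=list(table.sample_ids),
        bmntd_obs=obs,
        null_mean=mean_acc,
        null_sd=null_sd,
        bnti=bnti,
        n_null=n_null,
        seed=seed,
    )


def assembly_fractions(bnti_values, threshold: float = 2.0) -> tuple[float, float]:
    """Percent of pairs assembled stochastically (|βNTI| < threshold) vs not."""
    v = np.asarray(bnti_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise UndefinedDistanceError("no finite βNTI values")
    pct_stochastic = 100.0 * np.sum(np.abs(v) < threshold) / v.size
    return float(pct_stochastic), float(100.0 - pct_stochastic)
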