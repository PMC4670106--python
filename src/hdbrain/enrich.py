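"""Ranked nested-subset geneset enrichment sweep with integrated clustering.

A single over-representation test on a long DE list hides *where* in the
ranking a geneset's signal lives. The sweep instead tests every nested
prefix of a significance-ranked gene list — the top 25, top 50, and so on
in steps of 25 up to the whole list — against each geneset with the
one-sided hypergeometric tail (equivalently Fisher's exact test), giving a
geneset-by-subset-size profile of -log10 p. Sets driven by the most
extreme genes peak early; sets spread through the list peak late.

Per collection, sets are ranked by their single best p anywhere in the
sweep and the top 15 profiles kept. Profiles from all collections are then
concatenated (insignificant cells, p >= 0.05, contribute 0), each row is
divided by its row sum, and rows are clustered by Ward linkage on
Euclidean distance and cut into a small number of functional groups
(default 5, labeled A, B, C, ...).

GO-style collections may carry an acyclic term hierarchy; annotations are
propagated from descendant terms to ancestors (the true-path rule) before
testing, so a parent term is tested on the union of its own and its
descendants' genes.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .dge import bh_adjust
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

MASK_ALPHA = 0.05
TOP_K = 15
SUBSET_STEP = 25
N_GROUPS = 5


@dataclass
class GeneSetCollection:
    """A named collection of genesets with an optional term hierarchy.

    ``hierarchy`` holds (child, parent) edges and must be acyclic. Members
    need not lie in any particular universe; the intersection with the
    analysis universe is taken at test time.
    """

    name: str
    sets: dict[str, list[str]]
    hierarchy: list[tuple[str, str]] = field(default_factory=list)

    def propagated(self) -> dict[str, set[str]]:
        """Memberships after true-path propagation (descendants -> ancestors)."""
        members = {name: set(genes) for name, genes in self.sets.items()}
        if not self.hierarchy:
            return members
        g = nx.DiGraph()
        g.add_nodes_from(members)
        g.add_edges_from(self.hierarchy)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            raise InputError(f"collection {self.name}: term hierarchy is cyclic")
        for node in nx.topological_sort(g):
            node_members = members.get(node, set())
            for parent in g.successors(node):
                members.setdefault(parent, set()).update(node_members)
        return members


@dataclass
class EnrichmentProfile:
    """Geneset x subset-size sweep result for one collection.

    ``neglog10p`` stores -log10 of the raw one-sided p per cell; ``mask``
    flags cells with p < mask_alpha; ``padj`` holds BH-adjusted p per
    subset-size column; ``best_p`` is each set's minimum raw p over the
    sweep.
    """

    collection: str
    pvalues: pd.DataFrame
    mask_alpha: float = MASK_ALPHA

    @property
    def neglog10p(self) -> pd.DataFrame:
        return -np.log10(self.pvalues.clip(lower=1e-300))

    @property
    def mask(self) -> pd.DataFrame:
        return self.pvalues < self.mask_alpha

    @property
    def best_p(self) -> pd.Series:
        return self.pvalues.min(axis=1)

    @property
    def best_size(self) -> pd.Series:
        """Subset size at which each set attains its best p (first on ties)."""
        return self.pvalues.idxmin(axis=1)

    @property
    def padj(self) -> pd.DataFrame:
        adj = {c: bh_adjust(self.pvalues[c].to_numpy())
               for c in self.pvalues.columns}
        return pd.DataFrame(adj, index=self.pvalues.index)


@dataclass
class ClusterGram:
    """Concatenated, row-normalized enrichment matrix with Ward grouping."""

    matrix: pd.DataFrame          # row-normalized, rows ordered as input
    linkage_matrix: np.ndarray    # scipy linkage (Ward, Euclidean)
    groups: pd.Series             # group label (A, B, ...) per row
    row_order: list[str]          # dendrogram leaf order


def nested_subsets(ranked: list[str], step: int = SUBSET_STEP) -> list[int]:
    """Prefix sizes step, 2*step, ..., plus the full length if not a multiple."""
    if step < 1:
        raise ConfigurationError(f"nested_subsets: step must be >= 1, got {step}")
    n = len(ranked)
    if n == 0:
        raise InputError("nested_subsets: ranked list is empty")
    sizes = list(range(step, n + 1, step))
    if not sizes or sizes[-1] != n:
        sizes.append(n)
    return sizes


def hypergeom_enrich(subset: set, geneset: set, universe: set) -> float:
    """One-sided over-representation p: P(X >= |subset & geneset|).

    X ~ Hypergeometric(N=|universe|, K=|geneset & universe|, n=|subset|).
    The geneset is intersected with the universe before testing; an empty
    effective geneset returns p = 1 with a warning.
    """
    universe = set(universe)
    subset = set(subset)
    if not universe:
        raise InputError("hypergeom_enrich: empty universe")
    if not subset <= universe:
        raise InputError("hypergeom_enrich: subset must be contained in universe")
    eff = set(geneset) & universe
    if not eff:
        logger.warning("hypergeom_enrich: geneset has no members in universe")
        return 1.0
    k = len(subset & eff)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(eff), len(subset)))


def go_enrich(subset: set, collection: GeneSetCollection, universe: set
              ) -> pd.Series:
    """Per-term enrichment after true-path annotation propagation."""
    members = collection.propagated()
    return pd.Series({term: hypergeom_enrich(subset, genes, universe)
                      for term, genes in members.items()}).sort_index()


def enrichment_profile(collection: GeneSetCollection, ranked: list[str],
                       universe: set, step: int = SUBSET_STEP,
                       mask_alpha: float = MASK_ALPHA) -> EnrichmentProfile:
    """Sweep every nested prefix of `ranked` against every set.

    Vectorized: per set, member positions in the ranked list give the
    overlap at every prefix size via a single sort, then the hypergeometric
    tail is evaluated across all sizes at once.
    """
    if len(ranked) != len(set(ranked)):
        raise InputError("enrichment_profile: ranked list contains duplicates")
    universe = set(universe)
    if not set(ranked) <= universe:
        raise InputError("enrichment_profile: ranked list must lie in universe")
    sizes = nested_subsets(ranked, step=step)
    n_univ = len(universe)
    rank_of = {g: i for i, g in enumerate(ranked)}
    members = collection.propagated()

    rows = {}
    sizes_arr = np.asarray(sizes)
    for name in sorted(members):
        eff = members[name] & universe
        if not eff:
            logger.warning("enrichment_profile: set %r empty in universe, p=1",
                           name)
            rows[name] = np.ones(len(sizes))
            continue
        positions = np.sort([rank_of[g] for g in eff if g in rank_of])
        overlap = np.searchsorted(positions, sizes_arr, side="left")
        rows[name] = stats.hypergeom.sf(overlap - 1, n_univ, len(eff), sizes_arr)
    pvalues = pd.DataFrame.from_dict(rows, orient="index", columns=sizes)
    pvalues.index.name = "set_name"
    return EnrichmentProfile(collection.name, pvalues, mask_alpha=mask_alpha)


def rank_genesets(profile: EnrichmentProfile, top_k: int = TOP_K) -> list[str]:
    """Sets ordered by best (minimum) sweep p, ties by name; first top_k."""
    if top_k < 1:
        raise ConfigurationError(f"rank_genesets: top_k must be >= 1, got {top_k}")
    if profile.pvalues.empty:
        raise InputError("rank_genesets: profile is empty")
    best = profile.best_p
    order = best.reset_index()
    order.columns = ["set_name", "best_p"]
    order = order.sort_values(["best_p", "set_name"], kind="stable")
    return order["set_name"].head(top_k).tolist()


def integrate_and_cluster(profiles: list[EnrichmentProfile],
                          top_k: int = TOP_K, n_groups: int = N_GROUPS,
                          masked: bool = True) -> ClusterGram:
    """Concatenate top-k profiles per collection, normalize, Ward-cluster.

    Insignificant cells (p >= mask_alpha) contribute 0 when ``masked``
    (the default, mirroring a significance-masked display); rows are
    divided by their sum (all-zero rows dropped with a warning), then
    clustered by Ward linkage on Euclidean distance and cut into
    ``n_groups`` groups labeled A, B, ... in dendrogram leaf order.
    """
    if not profiles:
        raise InputError("integrate_and_cluster: no profiles given")
    columns = list(profiles[0].pvalues.columns)
    blocks = []
    for prof in profiles:
        if list(prof.pvalues.columns) != columns:
            raise InputError(
                "integrate_and_cluster: profiles have mismatched subset-size "
                f"columns ({prof.collection} vs {profiles[0].collection})")
        top = rank_genesets(prof, top_k=min(top_k, len(prof.pvalues)))
        block = prof.neglog10p.loc[top]
        if masked:
            block = block.where(prof.mask.loc[top], 0.0)
        block = block.copy()
        block.index = [f"{prof.collection}:{s}" for s in top]
        blocks.append(block)
    mat = pd.concat(blocks, axis=0)

    rowsum = mat.sum(axis=1)
    zero = rowsum <= 0
    if zero.any():
        logger.warning("integrate_and_cluster: dropping %d all-zero rows: %s",
                       int(zero.sum()), list(mat.index[zero])[:5])
        mat = mat.loc[~zero]
        rowsum = rowsum[~zero]
    if mat.shape[0] < 2:
        raise InputError("integrate_and_cluster: need at least 2 nonzero rows")
    normed = mat.div(rowsum, axis=0)

    Z = linkage(normed.to_numpy(), method="ward", metric="euclidean")
    n_groups = min(n_groups, normed.shape[0])
    raw_labels = fcluster(Z, t=n_groups, criterion="maxclust")
    leaf_order = leaves_list(Z)
    row_order = [normed.index[i] for i in leaf_order]
    # relabel groups A, B, ... in order of first appearance along the leaves
    seen: dict[int, str] = {}
    letters = string.ascii_uppercase
    for i in leaf_order:
        lab = raw_labels[i]
        if lab not in seen:
            seen[lab] = letters[len(seen) % 26]
    groups = pd.Series([seen[l] for l in raw_labels], index=normed.index,
                       name="group")
    return ClusterGram(matrix=normed, linkage_matrix=Z, groups=groups,
                       row_order=row_order)
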