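"""Phylogenetic diversity and structure.

Trees are handled as :class:`dendropy.Tree` objects (Newick in, Newick out).
The module provides BLADJ-style age calibration for trees whose internal
nodes carry a partial set of divergence-time estimates, Faith's PD, mean
pairwise distance (MPD), and the net relatedness index (NRI) under the
phylogeny-shuffle null model: each null iteration permutes all tip labels of
the pool tree uniformly at random — preserving tree shape and per-cell
richness — and recomputes MPD for every cell under that same permutation.

NRI = −(MPD_obs − mean(MPD_null)) / sd(MPD_null); positive values indicate
phylogenetic clustering (co-occurring taxa more related than expected),
negative values overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .gridding import CommunityMatrix

__all__ = [
    "parse_newick",
    "write_newick",
    "read_age_table",
    "bladj_calibrate",
    "patristic_matrix",
    "faith_pd",
    "pd_table",
    "mpd",
    "nri",
    "NRIRecord",
]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse one rooted Newick tree; tip labels must be unique."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_age_table(path) -> dict[str, float]:
    """Two-column whitespace text: internal-node label, age (time before present)."""
    ages = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, age = line.split()
            ages[label] = float(age)
    return ages


# ---------------------------------------------------------------------------
# BLADJ age calibration

def bladj_calibrate(tree: dendropy.Tree, ages: Mapping[str, float]) -> dendropy.Tree:
    """Assign branch lengths from a partial set of internal-node ages.

    Nodes whose label appears in ``ages`` are fixed at that age; tips sit at
    age 0.  Every undated internal node is placed, working root-ward to
    tip-ward, at the age that divides the span between its (already dated)
    parent and its nearest dated descendant evenly by edge count — so a chain
    of k undated nodes between two dated ones is spaced uniformly.  Branch
    length = parent age − child age; with all tips at age 0 the result is
    ultrametric.

    The root must be dated, and no dated descendant may be older than a dated
    ancestor.
    """
    tree = tree.clone(depth=1)
    node_age: dict[int, float] = {}

    def label_of(node) -> str | None:
        if node.is_leaf():
            return node.taxon.label if node.taxon else None
        return node.label

    # fixed ages: tips at 0, dated internals from the table
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node_age[id(node)] = float(ages.get(label_of(node), 0.0))
        else:
            lab = label_of(node)
            if lab is not None and lab in ages:
                node_age[id(node)] = float(ages[lab])

    root = tree.seed_node
    if id(root) not in node_age:
        raise ValueError("root node must have an age")

    def nearest_dated_below(node) -> tuple[float, int]:
        """(age, edge distance) of the closest fixed-age descendant.

        Ties in edge distance resolve to the oldest age (the binding
        constraint when spacing the chain).
        """
        found: list[tuple[int, float]] = []
        stack = [(child, 1) for child in node.child_nodes()]
        while stack:
            n, d = stack.pop()
            if id(n) in node_age and (n.is_leaf() or label_of(n) in ages):
                found.append((d, node_age[id(n)]))
                continue
            stack.extend((c, d + 1) for c in n.child_nodes())
        best_d = min(d for d, _ in found)  # every path ends in a tip, which is dated
        best_age = max(a for d, a in found if d == best_d)
        return best_age, best_d

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_age = node_age[id(node.parent_node)]
        if id(node) in node_age:
            if node_age[id(node)] > parent_age + 1e-12:
                raise ValueError(
                    f"inconsistent calibration: node {label_of(node)!r} age "
                    f"{node_age[id(node)]} exceeds its ancestor's age {parent_age}"
                )
        else:
            below_age, below_d = nearest_dated_below(node)
            if below_age > parent_age + 1e-12:
                raise ValueError(
                    "inconsistent calibration: dated descendant older than ancestor"
                )
            node_age[id(node)] = parent_age - (parent_age - below_age) / (below_d + 1)
        node.edge.length = parent_age - node_age[id(node)]
    root.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# Distances and diversity

def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip labels (sorted) and the symmetric matrix of path-length distances."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    taxa = {leaf.taxon.label: leaf.taxon for leaf in tree.leaf_node_iter()}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return labels, d


def faith_pd(tree: dendropy.Tree, taxa: Iterable[str], include_stem: bool = False) -> float:
    """Total branch length of the minimal subtree spanning ``taxa``.

    Rooted at the taxa's MRCA; the stem above the MRCA is excluded unless
    ``include_stem``.  Zero or one taxon gives PD = 0 (no stem either way for
    an empty set).
    """
    wanted = set(taxa)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = wanted - tips
    if missing:
        raise KeyError(f"taxa not in tree: {sorted(missing)}")
    k = len(wanted)
    if k == 0:
        return 0.0

    total = 0.0
    counts: dict[int, int] = {}
    mrca_edge = None
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = 1 if node.taxon.label in wanted else 0
        else:
            c = sum(counts[id(ch)] for ch in node.child_nodes())
        counts[id(node)] = c
        bl = node.edge.length or 0.0
        if 1 <= c < k:
            total += bl
        elif c == k and mrca_edge is None:
            mrca_edge = bl  # first full-count node in postorder = the MRCA
    if include_stem and mrca_edge is not None:
        total += mrca_edge
    return total


def pd_table(tree: dendropy.Tree, matrix: CommunityMatrix,
             include_stem: bool = False) -> pd.DataFrame:
    """Faith's PD per cell, for all species and per life form."""
    out = {}
    for subset, col in (("all", "pd_all"), ("woody", "pd_woody"), ("herbaceous", "pd_herb")):
        sub = matrix.subset_species(subset)
        vals = []
        for cell in matrix.cells:
            present = sub.columns[sub.loc[cell].to_numpy() == 1]
            vals.append(faith_pd(tree, present, include_stem=include_stem))
        out[col] = vals
    return pd.DataFrame(out, index=pd.Index(matrix.cells, name="cell"))


def mpd(dist: np.ndarray, labels: list[str], taxa: Iterable[str]) -> float:
    """Mean patristic distance over unordered pairs of distinct taxa."""
    idx = [labels.index(t) if isinstance(labels, list) else labels.get_loc(t) for t in taxa]
    k = len(idx)
    if k < 2:
        raise ValueError("MPD requires at least two taxa")
    sub = dist[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


# ---------------------------------------------------------------------------
# NRI under the phylogeny-shuffle null

@dataclass(frozen=True)
class NRIRecord:
    cell_id: str
    n_taxa: int
    mpd_obs: float
    null_mean: float
    null_sd: float
    nri: float
    n_iterations: int


def nri(
    matrix: CommunityMatrix,
    tree: dendropy.Tree,
    n_iter: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Net relatedness index per cell under the tip-shuffle null model.

    One label permutation per iteration is shared across all cells, so every
    cell sees the identical marginal null while the pool tree is shuffled
    only once per iteration.  Cells with fewer than two species, or whose
    null MPD is shuffle-invariant (null SD = 0, e.g. the full pool), get
    ``nri = NaN``.

    Returns a DataFrame with columns n_taxa, mpd_obs, null_mean, null_sd,
    nri, n_iterations indexed by cell.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    labels, dist = patristic_matrix(tree)
    pos = {lab: i for i, lab in enumerate(labels)}
    missing = [s for s in matrix.species if s not in pos]
    if missing:
        raise KeyError(f"species not in tree: {missing}")

    n = len(labels)
    # cells x pool-tips indicator, columns ordered as `labels`
    m = np.zeros((len(matrix.cells), n), dtype=float)
    for j, s in enumerate(matrix.species):
        m[:, pos[s]] = matrix.data.iloc[:, j].to_numpy()
    k = m.sum(axis=1)
    pairs = k * (k - 1)

    def all_mpd(indicator: np.ndarray) -> np.ndarray:
        quad = ((indicator @ dist) * indicator).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(pairs > 0, quad / np.where(pairs > 0, pairs, 1), np.nan)

    obs = all_mpd(m)
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_iter, len(matrix.cells)))
    for it in range(n_iter):
        perm = rng.permutation(n)
        nulls[it] = all_mpd(m[:, perm])
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1) if n_iter > 1 else np.zeros(len(matrix.cells))

    with np.errstate(invalid="ignore", divide="ignore"):
        values = -(obs - null_mean) / null_sd
    # shuffle-invariant communities (e.g. the full pool) have an exactly
    # degenerate null; tolerance absorbs matrix-product rounding noise
    degenerate = null_sd <= 1e-9 * np.maximum(1.0, np.abs(null_mean))
    bad = (k < 2) | degenerate | ~np.isfinite(values)
    values = np.where(bad, np.nan, values)

    return pd.DataFrame(
        {
            "n_taxa": k.astype(int),
            "mpd_obs": np.where(k >= 2, obs, np.nan),
            "null_mean": np.where(k >= 2, null_mean, np.nan),
            "null_sd": np.where(k >= 2, null_sd, np.nan),
            "nri": values,
            "n_iterations": n_iter,
        },
        index=pd.Index(matrix.cells, name="cell"),
    )
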