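"""Phylogeny utilities: Newick I/O, Yule simulation, pruning, Brownian covariance.

Trees are represented as :class:`dendropy.Tree` objects throughout the
package.  All functions here require rooted trees with branch lengths in
time-proportional units and unique tip labels.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np


class TreeError(ValueError):
    """Raised for malformed or unusable phylogenies."""


def read_newick(source: str, *, from_string: bool = False) -> dendropy.Tree:
    """Read a single rooted Newick tree from a file path or string.

    Parameters
    ----------
    source
        Path to a Newick file, or a Newick string if ``from_string``.
    from_string
        Interpret ``source`` as Newick data rather than a path.

    Returns
    -------
    dendropy.Tree
        Rooted tree with unlabeled internal nodes auto-named ``nd0``,
        ``nd1``, ... in postorder.

    Raises
    ------
    TreeError
        If the string does not parse, contains more than one tree, or has
        duplicate tip labels.
    """
    kwargs = dict(schema="newick", preserve_underscores=True,
                  suppress_internal_node_taxa=True)
    try:
        if from_string:
            tree = dendropy.Tree.get(data=source, **kwargs)
        else:
            tree = dendropy.Tree.get(path=source, **kwargs)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick input: {exc}") from exc
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {lb for lb in labels if labels.count(lb) > 1}
    if dupes:
        raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
    if len(labels) < 2:
        raise TreeError("tree must have at least 2 tips")
    name_internal_nodes(tree)
    return tree


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    """Serialize a tree to Newick; write to ``path`` if given.

    Branch lengths are written with full float precision so that
    ``read_newick(write_newick(t))`` round-trips exactly.
    """
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True,
                       real_value_format_specifier="0.17g").strip()
    if not s.endswith(";"):
        s += ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def name_internal_nodes(tree: dendropy.Tree) -> None:
    """Assign deterministic labels nd0, nd1, ... to unlabeled internal nodes."""
    i = 0
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            continue
        if nd.label is None:
            nd.label = f"nd{i}"
        i += 1


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` extant tips.

    Starting from a root with two lineages, each of the ``k`` concurrent
    lineages splits at rate ``birth_rate``; after the tree reaches
    ``n_tips`` lineages a final exponential waiting time at rate
    ``n_tips * birth_rate`` is appended so that the expected root-to-tip
    depth is ``sum_{k=2..n} 1/(k * birth_rate)``.

    Tips are labelled ``t1 .. tN``.  The same seed yields a byte-identical
    Newick string.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = dendropy.Node(edge_length=0.0)
        root.add_child(child)
        active.append(child)
    k = 2
    while True:
        wait = rng.exponential(1.0 / (k * birth_rate))
        for nd in active:
            nd.edge.length += wait
        if k == n_tips:
            break
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node(edge_length=0.0)
            parent.add_child(child)
            active.append(child)
        k += 1
    # deterministic labelling: order of `active` is simulation order; sort by
    # a traversal so equal seeds give equal files regardless of pop order
    for i, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon = taxon_ns.new_taxon(label=f"t{i + 1}")
    name_internal_nodes(tree)
    return tree


def scale_to_depth(tree: dendropy.Tree, depth: float) -> dendropy.Tree:
    """Rescale branch lengths so the mean root-to-tip depth equals ``depth``.

    Published time trees are commonly standardized to relative depth before
    rate estimation; a unit-depth tree puts a rate of ~1 in the regime of
    about one expected change per root-to-tip path.
    """
    if depth <= 0:
        raise TreeError("target depth must be > 0")
    d = node_depths(tree)
    mean_depth = float(np.mean([d[lf] for lf in tree.leaf_node_iter()]))
    if mean_depth <= 0:
        raise TreeError("tree has zero depth")
    factor = depth / mean_depth
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= factor
    return tree


def prune_to_data(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Tree:
    """Return the induced subtree on ``labels``.

    Unary internal nodes created by pruning are suppressed with their branch
    lengths summed; the root is retained.  Raises :class:`TreeError` listing
    any requested label absent from the tree, and if fewer than 2 labels are
    requested (a one-tip tree is degenerate).
    """
    labels = list(labels)
    present = set(tip_labels(tree))
    missing = sorted(set(labels) - present)
    if missing:
        raise TreeError(f"tips not in tree: {missing}")
    if len(set(labels)) < 2:
        raise TreeError("pruning to fewer than 2 tips yields a degenerate tree")
    pruned = tree.extract_tree_with_taxa_labels(
        labels=set(labels), suppress_unifurcations=True)
    pruned.is_rooted = True
    # extract_tree keeps the old root even if unifurcating; collapse it
    seed = pruned.seed_node
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        child.parent_node = None
        pruned.seed_node = child
        child.edge.length = None
        seed = child
    name_internal_nodes(pruned)
    return pruned


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Root-to-node path lengths (root depth 0)."""
    depths: dict[dendropy.Node, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depths[nd] = 0.0
        else:
            bl = nd.edge.length or 0.0
            depths[nd] = depths[nd.parent_node] + bl
    return depths


def brownian_vcv(tree: dendropy.Tree,
                 labels: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix implied by the tree.

    Entry (i, j) is the root-to-MRCA path length of tips i and j; the
    diagonal holds root-to-tip depths.  Returns the matrix together with
    the tip-label ordering of its rows.
    """
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise TreeError("negative branch length")
    if labels is None:
        labels = tip_labels(tree)
    idx = {lb: i for i, lb in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    depths = node_depths(tree)
    # accumulate: for each node, pairs of tips whose MRCA is that node
    tipsets: dict[dendropy.Node, list[int]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            lb = nd.taxon.label
            if lb not in idx:
                tipsets[nd] = []
                continue
            i = idx[lb]
            V[i, i] = depths[nd]
            tipsets[nd] = [i]
        else:
            kids = [tipsets[c] for c in nd.child_nodes()]
            d = depths[nd]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            V[i, j] = V[j, i] = d
            merged = [i for k in kids for i in k]
            tipsets[nd] = merged
    return V, list(labels)


def simulate_brownian(tree: dendropy.Tree, sigma2: float, seed_or_rng,
                      root_value: float = 0.0) -> dict[str, float]:
    """Evolve a continuous trait by Brownian motion; returns tip values."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    values: dict[dendropy.Node, float] = {}
    out: dict[str, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            values[nd] = root_value
        else:
            bl = nd.edge.length or 0.0
            values[nd] = values[nd.parent_node] + rng.normal(0.0, np.sqrt(sigma2 * bl))
        if nd.is_leaf():
            out[nd.taxon.label] = values[nd]
    return out
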