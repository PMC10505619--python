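"""Root-to-tip divergence and the high-rate-of-evolution call.

Per-orthogroup maximum-likelihood gene trees are unrooted, so a rooting
step precedes the root-to-tip distance: midpoint rooting by default (the
species panel has no designated outgroup), or rooting on a configured
outgroup tip.  A focal species is called "high divergence" when its
root-to-tip distance exceeds every other species' distance (``strict_max``,
the parameter-free default) or exceeds the background mean by ``k``
standard deviations (``zscore``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy

from .io_formats import ConfigurationError


class TreeError(ValueError):
    pass


@dataclass
class DivergenceResult:
    orthogroup_id: str
    distances: dict[str, float]
    focal: str
    high_divergence: bool
    rule: str
    params: dict = field(default_factory=dict)


def _require_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            head = edge.head_node
            label = (
                head.taxon.label if head.taxon else f"internal node {id(head)}"
            )
            raise TreeError(f"branch length absent on edge above {label}")


def total_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.edges())


def root_tree(
    tree: dendropy.Tree, method: str = "midpoint", outgroup: str | None = None
) -> dendropy.Tree:
    """Root a tree by midpoint or on an outgroup tip's branch (split 50/50).

    Total tree length is conserved.  Operates on (and returns) the input
    tree object.
    """
    _require_lengths(tree)
    if method == "input":
        # trust the rooting the tree came with (e.g. gene trees derived
        # from a rooted species tree); midpoint rooting would force the
        # two most divergent tips to tie at the root-to-tip maximum
        root_children = tree.seed_node.child_nodes()
        if len(root_children) != 2:
            raise TreeError(
                "rooting method 'input' needs a rooted (bifurcating-root) tree; "
                f"root has {len(root_children)} children"
            )
        tree.is_rooted = True
        return tree
    if method == "midpoint":
        if total_length(tree) <= 0:
            raise TreeError("midpoint rooting undefined on a zero-length tree")
        tree.reroot_at_midpoint(update_bipartitions=False)
    elif method == "outgroup":
        if not outgroup:
            raise ConfigurationError("outgroup rooting requires an outgroup label")
        node = tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise TreeError(f"outgroup tip {outgroup!r} not found in tree")
        half = (node.edge.length or 0.0) / 2.0
        tree.reroot_at_edge(
            node.edge, length1=half, length2=half, update_bipartitions=False
        )
    else:
        raise ConfigurationError(f"unknown rooting method {method!r}")
    tree.is_rooted = True
    return tree


def root_to_tip(tree: dendropy.Tree) -> dict[str, float]:
    """Sum of branch lengths from the root to each tip."""
    if not tree.is_rooted:
        raise TreeError("root_to_tip requires a rooted tree")
    _require_lengths(tree)
    out: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = d
    return out


def call_high_divergence(
    distances: dict[str, float],
    focal: str,
    rule: str = "strict_max",
    k: float = 2.0,
    orthogroup_id: str = "",
) -> DivergenceResult:
    """Decide whether the focal tip's root-to-tip distance is elevated.

    ``strict_max``: focal strictly exceeds every background distance (ties
    do not count).  ``zscore``: focal > mean(background) + k * sd(background),
    with the sample (n-1) standard deviation.
    """
    if focal not in distances:
        raise ConfigurationError(f"focal species {focal!r} absent from distances")
    if len(distances) < 3:
        raise ConfigurationError(
            f"high-divergence call needs >=3 species, got {len(distances)}"
        )
    others = [v for sp, v in distances.items() if sp != focal]
    focal_d = distances[focal]
    if rule == "strict_max":
        flag = all(focal_d > v for v in others)
        params = {}
    elif rule == "zscore":
        mean = sum(others) / len(others)
        var = sum((v - mean) ** 2 for v in others) / (len(others) - 1)
        sd = math.sqrt(var)
        flag = focal_d > mean + k * sd
        params = {"k": k, "background_mean": mean, "background_sd": sd}
    else:
        raise ConfigurationError(f"unknown divergence rule {rule!r}")
    return DivergenceResult(
        orthogroup_id=orthogroup_id,
        distances=dict(distances),
        focal=focal,
        high_divergence=bool(flag),
        rule=rule,
        params=params,
    )
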