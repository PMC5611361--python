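"""Rooted-tree handling and phylogenetically independent contrasts (PICs).

Newick parsing is delegated to dendropy; the validated tree is held in a
small immutable node structure that the contrast algorithm walks directly.
Contrasts follow the classic pruning recursion: at each internal node the
standardized difference of the two daughter values is recorded, the node is
assigned the precision-weighted average of its daughters, and its parent
branch is lengthened by the harmonic contribution of the daughter branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats


class NewickError(ValueError):
    """Raised for structurally invalid trees."""


class PolytomyError(NewickError):
    """Raised when a node has more than two children."""


@dataclass
class _Node:
    name: str | None = None
    length: float = 0.0
    children: list["_Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """A validated rooted, binary tree with strictly positive branch lengths."""

    def __init__(self, root: _Node):
        self.root = root
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    # -- traversal ----------------------------------------------------

    def postorder(self) -> Iterator[_Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[_Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def tip_labels(self) -> list[str]:
        return [n.name for n in self.postorder() if n.is_leaf]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(node: _Node, acc: float) -> None:
            acc += node.length
            if node.is_leaf:
                depths[node.name] = acc
            for child in node.children:
                walk(child, acc)

        walk(self.root, 0.0)
        return depths

    # -- serialization ------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: _Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            if node is self.root:
                return f"({inner})"
            return f"({inner}):{node.length:.10g}"

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        tips = []
        for node in self.postorder():
            if node.is_leaf:
                if not node.name:
                    raise NewickError("unnamed tip in tree")
                tips.append(node.name)
            elif len(node.children) != 2:
                if node is self.root and len(node.children) > 2:
                    raise NewickError(
                        f"root has {len(node.children)} children: tree appears "
                        "unrooted; provide a rooted binary tree"
                    )
                raise PolytomyError(
                    f"node with {len(node.children)} children: polytomies are "
                    "not supported; resolve the tree before analysis"
                )
            if node is not self.root:
                if not np.isfinite(node.length):
                    raise NewickError(f"non-finite branch length near {node.name!r}")
                if node.length <= 0:
                    raise NewickError(
                        f"missing or non-positive branch length near {node.name!r}"
                    )
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")
        if len(tips) < 2:
            raise NewickError("tree must have at least 2 tips")


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string (or file content) into a validated Phylogeny."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise NewickError(f"could not parse newick: {exc}") from exc

    def convert(dnode) -> _Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        length = dnode.edge.length if dnode.edge.length is not None else np.nan
        node = _Node(name=label, length=float(length))
        for child in dnode.child_nodes():
            node.children.append(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    return Phylogeny(root)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


@dataclass(frozen=True)
class ContrastSet:
    """Standardized independent contrasts for one trait on one tree."""

    trait: str
    contrasts: np.ndarray
    node_order: tuple[str, ...]

    def __post_init__(self):
        if len(self.contrasts) != len(self.node_order):
            raise ValueError("contrasts and node_order length mismatch")
        if not np.all(np.isfinite(self.contrasts)):
            raise ValueError("non-finite contrast encountered")

    @property
    def n(self) -> int:
        return len(self.contrasts)


def pic_contrasts(
    tree: Phylogeny, trait: Mapping[str, float], name: str = "trait"
) -> ContrastSet:
    """Compute n_tips - 1 standardized contrasts for one trait.

    Contrast direction is left-child minus right-child in input tree order;
    only direction-invariant statistics should be computed from the result.
    """
    values = dict(trait)
    missing = [t for t in tree.tip_labels if t not in values]
    if missing:
        raise ValueError(f"missing trait value for tip(s): {missing}")

    # per-node state: (value, effective branch length, tip signature)
    state: dict[int, tuple[float, float, tuple[str, ...]]] = {}
    contrasts: list[float] = []
    order: list[str] = []

    for node in tree.postorder():
        if node.is_leaf:
            state[id(node)] = (float(values[node.name]), node.length, (node.name,))
            continue
        (x1, v1, t1), (x2, v2, t2) = (state[id(c)] for c in node.children)
        contrasts.append((x1 - x2) / np.sqrt(v1 + v2))
        order.append("|".join(sorted(t1 + t2)))
        xa = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        state[id(node)] = (xa, node.length + v1 * v2 / (v1 + v2), t1 + t2)

    return ContrastSet(name, np.asarray(contrasts), tuple(order))


def pic_correlation(cs1: ContrastSet, cs2: ContrastSet) -> tuple[float, float]:
    """Correlation through the origin between two contrast sets.

    Returns (r, two-sided p) with the t approximation on n_contrasts - 1
    degrees of freedom.
    """
    if cs1.node_order != cs2.node_order:
        raise ValueError("contrast sets come from different trees or node orders")
    u, w = cs1.contrasts, cs2.contrasts
    denom = np.sqrt(np.sum(u * u) * np.sum(w * w))
    if denom == 0:
        raise ValueError("zero-variance contrast set")
    r = float(np.sum(u * w) / denom)
    n = cs1.n
    df = n - 1
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)
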