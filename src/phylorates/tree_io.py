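"""Reading, validation and writing of time-calibrated trees.

Time convention: years before present (BP). The present is 0, the root age is
positive, and ages increase into the past. Branch lengths are in years.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, TextIO

import dendropy

__all__ = [
    "Node",
    "DatedTree",
    "TreeIOError",
    "NewickParseError",
    "TreeValidationError",
    "read_newick",
    "write_newick",
    "node_ages",
    "prune_to_extant",
    "prune_to_tips",
]


class TreeIOError(ValueError):
    """Base class for tree input/output failures."""


class NewickParseError(TreeIOError):
    """Malformed Newick text. Carries the character offset when known."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (character offset {offset})"
        super().__init__(message)


class TreeValidationError(TreeIOError):
    """Structurally valid Newick that violates a dated-tree invariant."""


@dataclass(eq=False)
class Node:
    """A node of a rooted tree; ``length`` is the subtending edge in years."""

    label: str | None = None
    length: float | None = None  # None at the root only
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> Iterator["Node"]:
        return (n for n in self.preorder() if n.is_leaf)


@dataclass(eq=False)
class DatedTree:
    """A rooted, dated tree with branch lengths in years.

    The root age (years BP) is defined as the maximum root-to-tip path
    length, so extant tips sit at age 0 and the invariant linking root age
    to branch lengths holds by construction.  Bifurcations and polytomies
    are both allowed; a unary root is tolerated only in the degenerate
    single-tip case.
    """

    root: Node
    family_name: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_tips = self.n_tips
        if n_tips < 1:
            raise TreeValidationError("tree has no tips")
        seen: set[str] = set()
        for node in self.root.preorder():
            if node is not self.root:
                if node.length is None:
                    name = node.label or "<unnamed internal node>"
                    raise TreeValidationError(f"missing branch length on node {name!r}")
                if node.length < 0:
                    name = node.label or "<unnamed internal node>"
                    raise TreeValidationError(
                        f"negative branch length {node.length} on node {name!r}"
                    )
            if node.is_leaf:
                if node.label is None:
                    raise TreeValidationError("unlabeled tip")
                if node.label in seen:
                    raise TreeValidationError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
            elif len(node.children) < 2 and n_tips > 1:
                raise TreeValidationError(
                    "internal node with a single child (unary nodes are only "
                    "accepted in single-tip trees)"
                )

    # -- basic accessors --------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.root.leaves())

    @property
    def root_age(self) -> float:
        """Maximum root-to-tip path length, in years BP."""
        best = 0.0
        stack: list[tuple[Node, float]] = [(self.root, 0.0)]
        while stack:
            node, depth = stack.pop()
            if node.is_leaf and depth > best:
                best = depth
            for child in node.children:
                stack.append((child, depth + (child.length or 0.0)))
        return best

    def copy(self) -> "DatedTree":
        def _clone(node: Node) -> Node:
            return Node(node.label, node.length, [_clone(c) for c in node.children])

        return DatedTree(_clone(self.root), family_name=self.family_name)


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------


def _check_parentheses(text: str) -> None:
    """Cheap pre-scan so malformed input reports a character offset."""
    depth = 0
    in_comment = 0
    in_quote = False
    for offset, ch in enumerate(text):
        if in_quote:
            if ch == "'":
                in_quote = False
            continue
        if ch == "'":
            in_quote = True
        elif ch == "[":
            in_comment += 1
        elif ch == "]":
            in_comment = max(0, in_comment - 1)
        elif in_comment:
            continue
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset)
    if depth != 0:
        raise NewickParseError(f"{depth} unclosed '('", len(text))


def _from_dendropy(dnode: dendropy.Node) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = Node(label=label, length=dnode.edge.length)
    node.children = [_from_dendropy(c) for c in dnode.child_nodes()]
    return node


def read_newick(source: str | os.PathLike | TextIO) -> list[DatedTree]:
    """Read one :class:`DatedTree` per tree in a Newick file or stream.

    ``source`` may be a path, a Newick string, or an open text stream.
    Input order is preserved.  Comments in square brackets are ignored.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        source = os.fspath(source)
        # Heuristic: anything containing a semicolon or parenthesis is data.
        if any(c in str(source) for c in ";()") or "\n" in str(source):
            text = str(source)
        else:
            with open(source) as fh:
                text = fh.read()
    _check_parentheses(text)
    try:
        tree_list = dendropy.TreeList.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(str(exc)) from exc
    trees = []
    for dtree in tree_list:
        root = _from_dendropy(dtree.seed_node)
        root.length = None  # a stem edge on the root carries no information here
        trees.append(DatedTree(root))
    if not trees:
        raise NewickParseError("no trees found in input")
    return trees


def _node_to_newick(node: Node, out: io.StringIO) -> None:
    if node.children:
        out.write("(")
        for i, child in enumerate(node.children):
            if i:
                out.write(",")
            _node_to_newick(child, out)
        out.write(")")
    if node.label is not None:
        label = node.label
        if any(c in label for c in " ,();:[]"):
            label = "'" + label.replace("'", "''") + "'"
        out.write(label)
    if node.length is not None:
        out.write(f":{node.length:.17g}")


def tree_to_newick(tree: DatedTree) -> str:
    """Serialize a single tree to a Newick string (17 significant digits)."""
    out = io.StringIO()
    _node_to_newick(tree.root, out)
    out.write(";")
    return out.getvalue()


def write_newick(trees: DatedTree | Iterable[DatedTree], dest: str | os.PathLike | TextIO) -> None:
    """Write trees to ``dest``, one Newick string per line."""
    if isinstance(trees, DatedTree):
        trees = [trees]
    lines = [tree_to_newick(t) + "\n" for t in trees]
    if hasattr(dest, "write"):
        dest.writelines(lines)
    else:
        with open(dest, "w") as fh:
            fh.writelines(lines)


# ---------------------------------------------------------------------------
# ages and pruning
# ---------------------------------------------------------------------------


def node_ages(tree: DatedTree) -> Mapping[Node, float]:
    """Map each node to its age in years BP (root age minus root-to-node path)."""
    root_age = tree.root_age
    ages: dict[Node, float] = {}
    stack: list[tuple[Node, float]] = [(tree.root, 0.0)]
    while stack:
        node, depth = stack.pop()
        ages[node] = root_age - depth
        for child in node.children:
            stack.append((child, depth + (child.length or 0.0)))
    return ages


def _prune(node: Node, keep: set[Node]) -> Node | None:
    """Drop tips not in ``keep``; suppress unary nodes, merging edge lengths."""
    if node.is_leaf:
        return node if node in keep else None
    kept = [c for c in (_prune(c, keep) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        if node.length is not None:
            child.length = (child.length or 0.0) + node.length
        return child
    node.children = kept
    return node


def prune_to_tips(tree: DatedTree, labels: Iterable[str]) -> DatedTree:
    """Return a copy of ``tree`` restricted to the tips named in ``labels``.

    Unary nodes created by the pruning are suppressed (edge lengths merged);
    if the old root ends up with a single surviving child subtree, that
    subtree's root becomes the new root, so the result is the crown tree of
    the retained tips.
    """
    wanted = set(labels)
    missing = wanted - set(tree.tip_labels)
    if missing:
        raise TreeValidationError(f"tips not in tree: {sorted(missing)}")
    if not wanted:
        raise TreeValidationError("cannot prune to an empty tip set")
    work = tree.copy()
    keep = {n for n in work.root.leaves() if n.label in wanted}
    new_root = _prune(work.root, keep)
    assert new_root is not None
    new_root.length = None
    return DatedTree(new_root, family_name=tree.family_name)


def prune_to_extant(tree: DatedTree, tol: float = 1e-6) -> DatedTree:
    """Remove non-extant tips (age greater than ``tol`` x root age).

    The default tolerance absorbs the rounding error of near-ultrametric
    consensus trees.  Raises :class:`TreeValidationError` when no tip
    survives (an all-extinct tree).
    """
    ages = node_ages(tree)
    cutoff = tol * tree.root_age
    extant = [n.label for n in tree.root.leaves() if ages[n] <= cutoff]
    if not extant:
        raise TreeValidationError("tree has no extant tips (all lineages extinct)")
    if len(extant) == tree.n_tips:
        return tree
    return prune_to_tips(tree, extant)
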