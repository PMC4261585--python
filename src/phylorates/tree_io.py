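"""Phylogenetic trees: Newick I/O, the ``$``-labelled rate-category dialect,
rerooting and midpoint rooting.

Trees are stored as linked :class:`Node` objects.  Every non-root node carries
the length and the integer rate category of the branch *above* it (the branch
leading to it from its parent).  A tree is considered *rooted* iff its root has
exactly two children.
"""

from __future__ import annotations

import logging
import math
from typing import Iterator, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "Tree",
    "NewickParseError",
    "parse_newick",
    "parse_rate_newick",
    "write_newick",
    "midpoint_root",
    "reroot_at_edge",
]


class NewickParseError(ValueError):
    """Malformed Newick input; carries the offending character position."""

    def __init__(self, message: str, position: Optional[int] = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class Node:
    """A tree node.  ``length`` and ``category`` describe the branch above."""

    __slots__ = ("name", "length", "category", "children", "parent", "_raw_category")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None,
                 category: int = 1):
        self.name = name
        self.length = length
        self.category = category
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self._raw_category: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name or '?'} {kind} len={self.length} cat={self.category}>"


class Tree:
    """A phylogeny with branch lengths and integer branch rate categories."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node is not self.root:
                if node.length is None or not math.isfinite(node.length):
                    raise ValueError("branch lengths required: every non-root branch "
                                     "must carry a finite length")
                if node.length < 0:
                    raise ValueError(f"negative branch length {node.length!r}")
                if node.category < 1:
                    raise ValueError("branch categories must be positive integers")
            if node.is_leaf:
                if not node.name:
                    raise ValueError("leaf labels must be nonempty")
                if node.name in seen:
                    raise ValueError(f"duplicate leaf label {node.name!r}")
                seen.add(node.name)

    # ------------------------------------------------------------------
    # traversal / introspection
    # ------------------------------------------------------------------
    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def categories(self) -> list[int]:
        """Sorted distinct branch categories present on non-root branches."""
        return sorted({n.category for n in self.postorder() if n is not self.root})

    def find(self, name: str) -> Node:
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(name)

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.category)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path length between every unordered leaf pair (brute force)."""
        paths: dict[str, list[Node]] = {}
        for leaf in self.leaves():
            chain = []
            node: Optional[Node] = leaf
            while node is not None:
                chain.append(node)
                node = node.parent
            paths[leaf.name] = chain
        out: dict[tuple[str, str], float] = {}
        names = sorted(paths)
        for i, x in enumerate(names):
            for y in names[i + 1:]:
                ax = paths[x]
                ancestors_y = set(map(id, paths[y]))
                lca_idx = next(k for k, n in enumerate(ax) if id(n) in ancestors_y)
                lca = ax[lca_idx]
                d = sum(n.length for n in ax[:lca_idx])
                node = paths[y][0]
                while node is not lca:
                    d += node.length
                    node = node.parent
                out[(x, y)] = d
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {len(self.leaves())} leaves, rooted={self.is_rooted}>"


# ----------------------------------------------------------------------
# parsing
# ----------------------------------------------------------------------

_SPECIAL = set("():,;")


class _Parser:
    def __init__(self, text: str, rate_dialect: bool):
        self.text = text
        self.i = 0
        self.rate_dialect = rate_dialect

    def error(self, msg: str) -> NewickParseError:
        return NewickParseError(msg, position=self.i)

    def skip_ws(self) -> None:
        while self.i < len(self.text) and self.text[self.i].isspace():
            self.i += 1

    def peek(self) -> str:
        self.skip_ws()
        if self.i >= len(self.text):
            raise self.error("unexpected end of input")
        return self.text[self.i]

    def parse(self) -> Node:
        root = self.parse_clade()
        self.skip_ws()
        if self.i >= len(self.text) or self.text[self.i] != ";":
            raise self.error("expected ';' terminating the tree")
        self.i += 1
        self.skip_ws()
        if self.i != len(self.text):
            raise self.error("trailing characters after ';'")
        return root

    def parse_clade(self) -> Node:
        if self.peek() == "(":
            self.i += 1
            node = Node()
            node.add_child(self.parse_clade())
            while self.peek() == ",":
                self.i += 1
                node.add_child(self.parse_clade())
            if self.peek() != ")":
                raise self.error("expected ')' or ','")
            self.i += 1
        else:
            node = Node()
        self.parse_label(node)
        return node

    def parse_label(self, node: Node) -> None:
        self.skip_ws()
        name = self.parse_name()
        if name:
            node.name = name
        self.skip_ws()
        if self.rate_dialect and self.i < len(self.text) and self.text[self.i] == "$":
            self.i += 1
            node._raw_category = self.parse_category()
        self.skip_ws()
        if self.i < len(self.text) and self.text[self.i] == ":":
            self.i += 1
            node.length = self.parse_number()

    def parse_name(self) -> str:
        start = self.i
        stop = _SPECIAL | ({"$"} if self.rate_dialect else set())
        while self.i < len(self.text):
            c = self.text[self.i]
            if c in stop or c.isspace():
                break
            self.i += 1
        return self.text[start:self.i]

    def parse_category(self) -> int:
        self.skip_ws()
        start = self.i
        while self.i < len(self.text) and self.text[self.i].isdigit():
            self.i += 1
        token = self.text[start:self.i]
        nxt = self.text[self.i] if self.i < len(self.text) else ""
        if not token or (nxt and nxt not in _SPECIAL and not nxt.isspace()):
            raise self.error("expected a positive integer after '$'")
        value = int(token)
        if value < 1:
            raise self.error("rate category must be a positive integer")
        return value

    def parse_number(self) -> float:
        self.skip_ws()
        start = self.i
        while self.i < len(self.text) and (self.text[self.i] not in _SPECIAL
                                           and not self.text[self.i].isspace()):
            self.i += 1
        token = self.text[start:self.i]
        try:
            return float(token)
        except ValueError:
            self.i = start
            raise self.error(f"expected a number, found {token!r}")


def parse_newick(text: str) -> Tree:
    """Parse a conventional Newick tree (branch lengths required).

    All branch categories default to 1.  ``$`` is treated as an ordinary
    label character.
    """
    root = _Parser(text, rate_dialect=False).parse()
    return Tree(root)


def parse_rate_newick(text: str) -> Tree:
    """Parse the ``$``-labelled dialect assigning branch rate categories.

    A label suffix ``$k`` (k a positive integer) puts the branch above the
    labelled node into rate category ``k``.  The distinct input categories are
    relabelled to contiguous ``1..C`` preserving their numeric order; branches
    without a label default to category 1 (merged with explicit ``$1`` labels
    if both occur, with a logged warning).  A ``$`` on the root is ignored
    (the root has no branch).
    """
    root = _Parser(text, rate_dialect=True).parse()
    if root._raw_category is not None:
        logger.warning("ignoring '$%d' on the root node: the root has no branch",
                       root._raw_category)
        root._raw_category = None

    tree = Tree(root)
    nonroot = [n for n in tree.postorder() if n is not root]
    any_labelled = any(n._raw_category is not None for n in nonroot)
    unlabelled = [n for n in nonroot if n._raw_category is None]
    if any_labelled and unlabelled:
        logger.warning("%d branch(es) without a '$' label default to category 1",
                       len(unlabelled))
    raw = {n._raw_category if n._raw_category is not None else 1 for n in nonroot}
    relabel = {old: new for new, old in enumerate(sorted(raw), start=1)}
    for n in nonroot:
        n.category = relabel[n._raw_category if n._raw_category is not None else 1]
        n._raw_category = None
    return tree


# ----------------------------------------------------------------------
# writing
# ----------------------------------------------------------------------

def write_newick(tree: Tree, categories: bool = False) -> str:
    """Serialize a tree to Newick; ``categories=True`` emits ``$k`` suffixes."""

    def fmt(node: Node, is_root: bool) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            s = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if node.name:
                s += node.name
        if not is_root:
            if categories:
                s += f"${node.category}"
            s += f":{node.length!r}"
        return s

    return fmt(tree.root, True) + ";"


# ----------------------------------------------------------------------
# rerooting
# ----------------------------------------------------------------------

def _invert_path_to_root(node: Node) -> None:
    """Make ``node`` topmost by reversing parent links up to the old root.

    The branch attributes between a former (child, parent) pair move from the
    child onto the parent.  If the old root is left with a single child it is
    spliced out (its branch merges into that child's branch).
    """
    path: list[Node] = []
    cur: Optional[Node] = node
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    old_root = path[-1]

    # stash edge attributes keyed by the lower node of each edge
    edge = {id(c): (c.length, c.category) for c in path[:-1]}

    for child, parent in zip(path, path[1:]):
        parent.children.remove(child)
        child.children.append(parent)
        parent.parent = child
        parent.length, parent.category = edge[id(child)]
    node.parent = None
    node.length = None
    node.category = 1

    if len(old_root.children) == 1 and old_root.parent is not None:
        lone = old_root.children[0]
        if lone.category != old_root.category:
            logger.warning("merging branches with differing rate categories "
                           "(%d vs %d) while rerooting; keeping %d",
                           lone.category, old_root.category, lone.category)
        lone.length += old_root.length
        holder = old_root.parent
        holder.children[holder.children.index(old_root)] = lone
        lone.parent = holder
        old_root.children = []
        old_root.parent = None


def reroot_at_edge(tree: Tree, leaf_or_node: str | Node,
                   dist_from_child: float) -> Tree:
    """Return a copy rerooted on the branch above ``leaf_or_node``.

    The new root is placed ``dist_from_child`` above the named node; both
    halves of the split branch inherit its rate category.
    """
    original = tree
    tree = tree.copy()
    if isinstance(leaf_or_node, str):
        child = tree.find(leaf_or_node)
    else:
        # map a node of the original tree onto the copy by positional path
        path_idx: list[int] = []
        cur: Optional[Node] = leaf_or_node
        while cur.parent is not None:
            path_idx.append(cur.parent.children.index(cur))
            cur = cur.parent
        if cur is not original.root:
            raise ValueError("node does not belong to this tree")
        child = tree.root
        for idx in reversed(path_idx):
            child = child.children[idx]
    if child.parent is None:
        raise ValueError("cannot reroot on the root: it has no branch above it")
    if not 0.0 <= dist_from_child <= child.length + 1e-12:
        raise ValueError("split point outside the branch")
    parent = child.parent
    length, category = child.length, child.category

    parent.children.remove(child)
    child.parent = None
    _invert_path_to_root(parent)

    new_root = Node()
    child.length = dist_from_child
    child.category = category
    new_root.add_child(child)
    parent.length = length - dist_from_child
    parent.category = category
    new_root.add_child(parent)
    return Tree(new_root)


def _reroot_at_node(tree: Tree, target_name_path: Node) -> Tree:
    tree_copy = tree.copy()
    # locate the corresponding node in the copy by positional path
    path_idx: list[int] = []
    cur = target_name_path
    while cur.parent is not None:
        path_idx.append(cur.parent.children.index(cur))
        cur = cur.parent
    node = tree_copy.root
    for idx in reversed(path_idx):
        node = node.children[idx]
    _invert_path_to_root(node)
    return Tree(node)


def midpoint_root(tree: Tree) -> Tree:
    """Midpoint-root an unrooted tree; rooted input is returned unchanged.

    The root is placed halfway along the longest leaf-to-leaf path (ties are
    broken by the lexicographically smallest leaf-label pair).  If the midpoint
    falls exactly on an existing node, that node becomes the root.
    """
    if len(tree.leaves()) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    if tree.is_rooted:
        return tree.copy()

    dists = tree.leaf_distances()
    best = max(dists.values())
    if best <= 0.0:
        raise ValueError("midpoint undefined: all branch lengths are zero")
    pair = min(p for p, d in dists.items() if d == best)
    half = best / 2.0

    # node path from pair[0] to pair[1]
    a = tree.find(pair[0])
    b = tree.find(pair[1])
    chain_a: list[Node] = []
    cur: Optional[Node] = a
    while cur is not None:
        chain_a.append(cur)
        cur = cur.parent
    ids_a = {id(n): k for k, n in enumerate(chain_a)}
    chain_b: list[Node] = []
    cur = b
    while id(cur) not in ids_a:
        chain_b.append(cur)
        cur = cur.parent
    lca = cur
    path = chain_a[: ids_a[id(lca)] + 1] + list(reversed(chain_b))

    cum = 0.0
    eps = 1e-12
    for k in range(len(path) - 1):
        lo, hi = path[k], path[k + 1]
        # branch between lo and hi is stored on whichever is the child
        if lo.parent is hi:
            child, blen = lo, lo.length
        else:
            child, blen = hi, hi.length
        if abs(cum - half) <= eps:
            return _reroot_at_node(tree, lo)
        if cum + blen > half + eps:
            along = half - cum  # distance from `lo` end of the branch
            dist_from_child = along if child is lo else blen - along
            return reroot_at_edge(tree, child, dist_from_child)
        cum += blen
    return _reroot_at_node(tree, path[-1])
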