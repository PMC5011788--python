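"""Newick trees with PAML branch/clade labels and a text cladogram.

PAML marks branch partitions directly in the Newick string: ``#N`` after a
node assigns that single branch to foreground partition N, while ``$N``
assigns the whole subtree (clade) to it.  Partition 0 is the implicit
background; labeled partitions must form a contiguous 1..N set because
codeml expects dense numbering.

Parsing is delegated to dendropy; this module extracts the label dialect,
assigns stable integer node ids (post-order, so re-parsing a written tree
reproduces the ids), renders a numbered text cladogram for interactive
labeling, and validates a labeling against the requirements of each model
family (site models need an unlabeled tree; branch-site models exactly two
partitions; branch and clade models at least two).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy

from .errors import ParseError, ValidationError

_LABEL_RE = re.compile(r"^(.*?)([#$])(\d+)$")


@dataclass
class Node:
    name: str | None = None
    length: float | None = None
    support: float | None = None
    label_kind: str | None = None   # "branch" (#) | "clade" ($)
    partition: int | None = None
    children: list = field(default_factory=list)
    node_id: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def label_token(self) -> str:
        if self.label_kind is None:
            return ""
        mark = "#" if self.label_kind == "branch" else "$"
        return f"{mark}{self.partition}"


@dataclass
class Tree:
    root: Node

    def nodes(self):
        """Post-order traversal (children before parents)."""
        out = []

        def walk(n):
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def leaves(self):
        return [n for n in self.nodes() if n.is_leaf]

    def find(self, node_id: int) -> Node:
        for n in self.nodes():
            if n.node_id == node_id:
                return n
        raise KeyError(f"no node with id {node_id}")

    def parent_of(self, node: Node):
        for n in self.nodes():
            if node in n.children:
                return n
        return None


def _split_label(raw: str | None):
    """Separate a trailing #N/$N from a node's raw label text."""
    if raw is None:
        return None, None, None
    m = _LABEL_RE.match(raw)
    if m:
        base, mark, num = m.group(1), m.group(2), int(m.group(3))
        kind = "branch" if mark == "#" else "clade"
        return base or None, kind, num
    return raw, None, None


def _assign_ids(tree: Tree) -> Tree:
    for i, n in enumerate(tree.nodes(), 1):
        n.node_id = i
    return tree


def parse_newick(text: str) -> Tree:
    """Parse Newick text carrying optional PAML ``#N``/``$N`` labels."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as e:  # dendropy raises several parser error types
        raise ParseError(f"malformed Newick: {e}") from e
    if dtree.seed_node is None:
        raise ParseError("empty Newick string")

    def convert(dn) -> Node:
        raw = dn.taxon.label if dn.taxon is not None else dn.label
        base, kind, num = _split_label(raw)
        node = Node(length=dn.edge.length, label_kind=kind, partition=num)
        if dn.is_leaf():
            if base is None:
                raise ParseError("leaf without a name")
            node.name = base
        elif base is not None:
            try:
                node.support = float(base)
            except ValueError:
                node.name = base
        node.children = [convert(c) for c in dn.child_nodes()]
        return node

    tree = Tree(root=convert(dtree.seed_node))
    names = [n.name for n in tree.leaves()]
    dupes = {x for x in names if names.count(x) > 1}
    if dupes:
        raise ParseError(f"duplicate leaf names: {sorted(dupes)}")
    _check_contiguous(tree)
    return _assign_ids(tree)


def write_newick(tree: Tree, lengths: bool = True, support: bool = True,
                 labels: bool = True) -> str:
    """Serialize canonically (no whitespace); labels preserved verbatim."""

    def fmt_len(x: float) -> str:
        return f"{x:g}"

    def emit(n: Node) -> str:
        if n.is_leaf:
            s = n.name or ""
        else:
            s = "(" + ",".join(emit(c) for c in n.children) + ")"
            if n.name is not None:
                s += n.name
            elif support and n.support is not None:
                s += f"{n.support:g}"
        if labels:
            s += n.label_token()
        if lengths and n.length is not None:
            s += f":{fmt_len(n.length)}"
        return s

    return emit(tree.root) + ";"


def render_cladogram(tree: Tree, display_mode: str = "none") -> str:
    """Numbered text cladogram, one row per node, leaves carrying names.

    *display_mode* toggles optional per-node annotations: ``support``,
    ``lengths``, ``both`` or ``none``.  Labeled nodes are marked with their
    ``#N``/``$N`` token so the labeling state is visible at a glance.
    """
    if display_mode not in ("none", "support", "lengths", "both"):
        raise ValidationError(f"unknown display mode {display_mode!r}")
    buf = io.StringIO()

    def annot(n: Node) -> str:
        bits = []
        if display_mode in ("support", "both") and n.support is not None:
            bits.append(f"{n.support:g}")
        if display_mode in ("lengths", "both") and n.length is not None:
            bits.append(f":{n.length:g}")
        return (" " + " ".join(bits)) if bits else ""

    def walk(n: Node, prefix: str, is_last: bool, is_root: bool):
        branch = "" if is_root else ("`-- " if is_last else "|-- ")
        name = n.name if n.is_leaf else (n.name or "*")
        token = f" {n.label_token()}" if n.label_kind else ""
        buf.write(f"{prefix}{branch}[{n.node_id}] {name}{token}{annot(n)}\n")
        ext = "" if is_root else ("    " if is_last else "|   ")
        for i, c in enumerate(n.children):
            walk(c, prefix + ext, i == len(n.children) - 1, False)

    walk(tree.root, "", True, True)
    return buf.getvalue()


def _partitions(tree: Tree) -> set:
    return {n.partition for n in tree.nodes() if n.partition is not None}


def _check_contiguous(tree: Tree):
    parts = _partitions(tree)
    if parts and parts != set(range(1, max(parts) + 1)):
        raise ValidationError(
            f"partition numbers {sorted(parts)} are not contiguous from 1"
        )


def apply_label(tree: Tree, node_id: int, kind: str, partition: int) -> Tree:
    """Set a ``#N`` (branch) or ``$N`` (clade) label on one node.

    Relabeling replaces any existing label on the node.  The resulting set of
    partition numbers must stay contiguous 1..N.
    """
    if kind not in ("branch", "clade"):
        raise ValidationError(f"label kind must be branch or clade, got {kind!r}")
    if partition < 1:
        raise ValidationError("partition numbers start at 1")
    node = tree.find(node_id)
    if kind == "branch" and node is tree.root:
        raise ValidationError("the root has no branch; cannot apply a branch label")
    old = (node.label_kind, node.partition)
    node.label_kind, node.partition = kind, partition
    try:
        _check_contiguous(tree)
    except ValidationError:
        node.label_kind, node.partition = old
        raise
    return tree


def remove_label(tree: Tree, node_id: int) -> Tree:
    """Remove a node's label; remaining partitions are renumbered densely."""
    node = tree.find(node_id)
    node.label_kind, node.partition = None, None
    remap = {p: i for i, p in enumerate(sorted(_partitions(tree)), 1)}
    for n in tree.nodes():
        if n.partition is not None:
            n.partition = remap[n.partition]
    return tree


def count_partitions(tree: Tree) -> int:
    """Background plus the number of distinct labeled partitions."""
    return 1 + len(_partitions(tree))


@dataclass
class Diagnostics:
    ok: bool
    message: str


#: partition-count requirement per model-family letter
_REQUIREMENTS = {
    "s": ("== 1", lambda n: n == 1, "site models need an unlabeled tree"),
    "w": ("== 2", lambda n: n == 2,
          "branch-site models need exactly one foreground partition"),
    "b": (">= 2", lambda n: n >= 2, "branch models need a labeled foreground"),
    "c": (">= 2", lambda n: n >= 2, "clade models need labeled clades"),
}


def validate_labeling(tree: Tree, model_class: str) -> Diagnostics:
    """Check a tree's partition count against one model family's needs."""
    if model_class not in _REQUIREMENTS:
        raise ValidationError(f"unknown model class {model_class!r}")
    expect, pred, why = _REQUIREMENTS[model_class]
    n = count_partitions(tree)
    if pred(n):
        return Diagnostics(True, f"{n} partition(s): valid for {model_class!r}")
    return Diagnostics(
        False, f"{n} partition(s) but class {model_class!r} requires {expect}: {why}"
    )
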