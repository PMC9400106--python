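"""Hierarchical topology trees of atom types.

Atom types are arranged by purely topological descriptors, one per level:
central element, number of first neighbors, elements of the first neighbors,
number of second neighbors, elements of the second neighbors, and finally
the atom-type names.  Planarity and ring membership annotate nodes but never
act as dividing criteria.

Three layouts are supported: an *extended* tree uses all five descriptor
levels; a *general* tree stops before the second-neighbor levels; a
*concise* tree additionally drops the first-neighbor elements and the leaf
names, keeping only per-leaf counts.  Types that cannot have second
neighbors appear with second-neighbor fields "none".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .bank import AtomTypeEntry

TREE_KINDS = ("extended", "general", "concise")

#: overlay category -> suggested fill color for DOT export
CATEGORY_COLORS = {
    "main": "lightgrey",
    "unique": "red",
    "distinct": "lightpink",
    "outlier": "orange",
    "complex": "white",
}


class TopologyError(ValueError):
    pass


@dataclass
class TreeNode:
    level: str                      # descriptor this node's value belongs to
    value: str
    children: dict[str, "TreeNode"] = field(default_factory=dict)
    entries: list[str] = field(default_factory=list)   # leaf atom-type names
    planar: bool = False            # bold flag: any member is a planar type
    rings: set[int] = field(default_factory=set)
    category: str | None = None     # density-cluster overlay category

    def child(self, level: str, value: str) -> "TreeNode":
        node = self.children.get(value)
        if node is None:
            node = TreeNode(level=level, value=value)
            self.children[value] = node
        return node

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for key in sorted(self.children):
            out.extend(self.children[key].leaves())
        return out


@dataclass
class TopologyTree:
    kind: str
    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()


def _multiset_token(elements) -> str:
    counts = Counter(elements)
    # wildcard second neighbors sort after named elements
    named = sorted(k for k in counts if k != "X")
    keys = named + (["X"] if "X" in counts else [])
    return "+".join(f"{k}{counts[k]}" if counts[k] > 1 else k for k in keys) \
        or "none"


def entry_signature(entry: AtomTypeEntry, kind: str) -> tuple[tuple[str, str], ...]:
    """Ordered (level, value) path of one entry for a tree layout."""
    topo = entry.topology
    first = topo.first_shell
    second = topo.second_shell
    path = [("element", topo.central_element),
            ("n_first", str(len(first)))]
    if kind != "concise":
        path.append(("first_elements", _multiset_token(n.element for n in first)))
    if kind == "extended":
        path.append(("n_second", str(len(second)) if second else "none"))
        path.append(("second_elements",
                     _multiset_token(n.element for n in second)))
    return tuple(path)


def build_tree(entries, kind: str = "extended") -> TopologyTree:
    """Deterministic, entry-order-invariant construction of a topology tree."""
    if kind not in TREE_KINDS:
        raise TopologyError(f"unknown tree kind {kind!r}; use {TREE_KINDS}")
    root = TreeNode(level="root", value="bank")
    for entry in sorted(entries, key=lambda e: e.name):
        node = root
        for level, value in entry_signature(entry, kind):
            node = node.child(level, value)
        node.entries.append(entry.name)
        planar = entry.topology.group_label in ("1p", "2p", "3p")
        rings = set().union(*(n.rings for n in entry.topology.neighbors),
                            set())
        walk = root
        for level, value in entry_signature(entry, kind):
            walk = walk.children[value]
            walk.planar = walk.planar or planar
            walk.rings |= rings
    return TopologyTree(kind=kind, root=root)


def terminal_clusters(tree: TopologyTree) -> list[list[str]]:
    """Leaf clusters (atom-type name lists); a partition of the entries."""
    if tree.kind != "extended":
        raise TopologyError("terminal clusters are defined on extended trees")
    return [sorted(leaf.entries) for leaf in tree.leaves()]


def mean_cluster_size(tree: TopologyTree) -> float:
    clusters = terminal_clusters(tree)
    return sum(len(c) for c in clusters) / len(clusters)


def categorize_entries(labels_by_entry: dict[str, dict[str, str]],
                       cluster_sizes: dict[str, int]) -> dict[str, str]:
    """Assign overlay categories from per-frame density-cluster labels.

    ``labels_by_entry`` maps entry name -> {frame name -> label path};
    ``cluster_sizes`` maps label path -> number of rows in that cluster.
    The main cluster of each (group family) is the one holding the most
    rows; an entry sitting in main clusters for every frame is "main", for
    some frames "distinct"; entries never in a main cluster are "outlier"
    when all their rotations are noise, "unique" when all their clusters are
    singletons, else "complex".
    """
    main_labels = set()
    if cluster_sizes:
        best = max(v for k, v in cluster_sizes.items()
                   if not k.endswith("-1"))
        main_labels = {k for k, v in cluster_sizes.items()
                       if v == best and not k.endswith("-1")}
    out = {}
    for name, per_frame in labels_by_entry.items():
        labels = list(per_frame.values())
        if not labels:
            raise TopologyError(f"entry {name} has no density labels")
        in_main = [lab in main_labels for lab in labels]
        noise = [lab.split("_")[-1] == "-1" for lab in labels]
        if all(in_main):
            out[name] = "main"
        elif any(in_main):
            out[name] = "distinct"
        elif all(noise):
            out[name] = "outlier"
        elif all(cluster_sizes.get(lab, 1) <= 1 or n
                 for lab, n in zip(labels, noise)):
            out[name] = "unique"
        else:
            out[name] = "complex"
    return out


def overlay_density_clusters(tree: TopologyTree,
                             categories: dict[str, str]) -> TopologyTree:
    """Attach density-cluster categories to the leaves of a general or
    concise tree (every leaf entry must be categorized)."""
    if tree.kind == "extended":
        raise TopologyError("overlay is drawn on general or concise trees")
    rank = ["main", "distinct", "unique", "outlier", "complex"]
    for leaf in tree.leaves():
        cats = []
        for name in leaf.entries:
            if name not in categories:
                raise TopologyError(f"no density label for entry {name}")
            cats.append(categories[name])
        leaf.category = max(cats, key=rank.index) if cats else None
    return tree


def to_dot(tree: TopologyTree) -> str:
    """Graphviz DOT export; planar nodes bold, overlay categories colored."""
    lines = ["digraph topology {", '  node [shape=box];']
    counter = [0]

    def walk(node, parent_id):
        nid = f"n{counter[0]}"
        counter[0] += 1
        label = node.value
        if node.entries and tree.kind != "concise":
            label += "\\n" + ",".join(node.entries)
        elif node.entries:
            label += f"\\n({len(node.entries)} types)"
        attrs = [f'label="{label}"']
        if node.planar:
            attrs.append('fontname="bold"')
        if node.category:
            attrs.append(f'style=filled fillcolor="'
                         f'{CATEGORY_COLORS.get(node.category, "white")}"')
        lines.append(f"  {nid} [{' '.join(attrs)}];")
        if parent_id is not None:
            lines.append(f"  {parent_id} -> {nid};")
        for key in sorted(node.children):
            walk(node.children[key], nid)

    walk(tree.root, None)
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_json_dict(tree: TopologyTree) -> dict:
    def walk(node):
        d = {"level": node.level, "value": node.value}
        if node.entries:
            d["entries"] = list(node.entries)
        if node.planar:
            d["planar"] = True
        if node.rings:
            d["rings"] = sorted(node.rings)
        if node.category:
            d["category"] = node.category
        if node.children:
            d["children"] = [walk(node.children[k])
                             for k in sorted(node.children)]
        return d
    return {"kind": tree.kind, "tree": walk(tree.root)}
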