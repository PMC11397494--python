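"""Rooted phylogenies with branch lengths in expected substitutions per site.

The tree is stored as flat parent/length arrays indexed by node id, which is
the layout the pruning likelihood engine consumes directly.  Newick parsing is
delegated to dendropy; writing is a trivial recursive formatter so that a
write-then-parse round trip preserves topology, labels and branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "NewickError", "parse_newick"]


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclass
class Phylogeny:
    """A rooted tree over nodes ``0..n-1`` with the root last in no particular id.

    Attributes
    ----------
    parent : int array, ``parent[root] == -1``
    lengths : float array of branch lengths above each node; 0 for the root
    names : per-node label (leaf species name; internal labels optional)
    """

    parent: np.ndarray
    lengths: np.ndarray
    names: list
    children: list = field(init=False)
    root: int = field(init=False)
    postorder: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.parent)
        self.children = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise NewickError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise NewickError("branch lengths must be finite and non-negative")
        # iterative postorder
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.postorder = np.array(order[::-1], dtype=np.intp)
        labels = [self.names[i] for i in self.leaf_nodes()]
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickError(f"duplicate leaf labels: {dup}")

    # -- structure queries ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaf_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    def leaf_labels(self) -> list[str]:
        return [self.names[i] for i in self.leaf_nodes()]

    def node_by_name(self, name: str) -> int:
        for i, nm in enumerate(self.names):
            if nm == name:
                return i
        raise KeyError(f"no node named {name!r}")

    def total_length(self) -> float:
        return float(self.lengths.sum())

    # -- branch scale maps ---------------------------------------------------
    def scale_array(self, scales: dict | None = None) -> np.ndarray:
        """Resolve a {child-node-name: factor} map to a per-node array.

        Unlisted branches get scale 1.  A branch is identified by the node
        below it, so leaf labels address terminal branches.
        """
        arr = np.ones(self.n_nodes)
        if scales:
            for name, s in scales.items():
                s = float(s)
                if not np.isfinite(s) or s < 0:
                    raise ValueError(f"branch scale for {name!r} must be finite and >= 0")
                arr[self.node_by_name(name)] = s
        return arr

    # -- newick --------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"malformed Newick: {exc}") from exc
        nodes = list(dt.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.intp)
        lengths = np.zeros(len(nodes))
        names: list = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.taxon is not None:
                names[i] = nd.taxon.label
            elif nd.label:
                names[i] = nd.label
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise NewickError(
                        f"missing branch length above node {names[i] or i!r}"
                    )
                lengths[i] = float(nd.edge.length)
        return cls(parent=parent, lengths=lengths, names=names)

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if self.is_leaf(i):
                body = self.names[i] or ""
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[i]) + ")"
                if self.names[i]:
                    body += self.names[i]
            if i == self.root:
                return body
            return f"{body}:{float(self.lengths[i])!r}"

        return fmt(self.root) + ";"

    # -- rerooting (reversibility checks) ------------------------------------
    def reroot_above(self, node: int, fraction: float = 0.5) -> "Phylogeny":
        """Return a new tree rooted on the branch above ``node``.

        The branch is split at ``fraction`` of its length (measured from the
        child).  Used to assert likelihood invariance under re-rooting for
        reversible models.
        """
        if node == self.root:
            raise ValueError("cannot reroot above the root")
        # Build adjacency with edge lengths, then hang from a new root.
        adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(self.n_nodes)}
        for i, p in enumerate(self.parent):
            if p >= 0:
                adj[i].append((p, float(self.lengths[i])))
                adj[p].append((i, float(self.lengths[i])))
        new_root = self.n_nodes
        blen = float(self.lengths[node])
        adj[new_root] = [(node, blen * fraction), (int(self.parent[node]), blen * (1 - fraction))]
        adj[node].append((new_root, blen * fraction))
        adj[self.parent[node]].append((new_root, blen * (1 - fraction)))
        adj[node] = [(v, l) for v, l in adj[node] if v != self.parent[node]]
        adj[int(self.parent[node])] = [
            (v, l) for v, l in adj[int(self.parent[node])] if v != node
        ]
        parent = np.full(self.n_nodes + 1, -1, dtype=np.intp)
        lengths = np.zeros(self.n_nodes + 1)
        names = list(self.names) + [None]
        seen = {new_root}
        stack = [new_root]
        while stack:
            v = stack.pop()
            for w, l in adj[v]:
                if w not in seen:
                    seen.add(w)
                    parent[w] = v
                    lengths[w] = l
                    stack.append(w)
        # drop the old root if it became a degree-2 pass-through node
        t = Phylogeny(parent=parent, lengths=lengths, names=names)
        return t.suppress_unifurcations()

    def suppress_unifurcations(self) -> "Phylogeny":
        """Collapse single-child chains, summing branch lengths along them."""

        def descend(i: int) -> tuple[str, float]:
            acc = float(self.lengths[i])
            while len(self.children[i]) == 1:
                i = self.children[i][0]
                acc += float(self.lengths[i])
            if self.is_leaf(i):
                return self.names[i] or "", acc
            parts = []
            for c in self.children[i]:
                body, length = descend(c)
                parts.append(f"{body}:{float(length)!r}")
            return "(" + ",".join(parts) + ")", acc

        r = self.root
        while len(self.children[r]) == 1:
            r = self.children[r][0]
        if self.is_leaf(r):
            return Phylogeny.from_newick(f"({self.names[r]}:0.0);")
        parts = []
        for c in self.children[r]:
            body, length = descend(c)
            parts.append(f"{body}:{length!r}")
        return Phylogeny.from_newick("(" + ",".join(parts) + ");")


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string with branch lengths into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)
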