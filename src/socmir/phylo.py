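"""Species-tree handling and parsimony gain/loss reconstruction.

Presence/absence of a miRNA across the genome panel is a binary character on
the species tree. Three reconstruction modes are provided:

* ``fitch``  — minimum-change reconstruction (regain after loss allowed),
  generalized to polytomies by unit-cost dynamic programming;
* ``dollo``  — a single gain (on the branch entering the MRCA of all present
  leaves, or the root stem) with a minimal set of subsequent losses;
* ``sankoff(gain_cost, loss_cost)`` — weighted-parsimony dynamic programming
  with the root prior fixed to *absent*, used to count the minimum number of
  independent gain events over all minimum-cost reconstructions.

The root prior matters: the queries are lineage-annotated miRNAs, so
presence at the base of the panel is itself a gain worth counting. The
Dollo and gain-count modes therefore include a virtual "root stem" branch
from an absent ancestor; the Fitch mode follows the classical convention
(root state free, changes counted on tree branches only).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "TreeError",
    "TreeNode",
    "SpeciesTree",
    "BinaryCharacter",
    "GainLossReconstruction",
    "parse_newick",
    "fitch_min_changes",
    "dollo_reconstruct",
    "count_independent_gains",
    "ROOT_STEM",
]

ROOT_STEM = "root-stem"


class TreeError(ValueError):
    """Raised on malformed trees or tree/character inconsistencies."""


@dataclass
class TreeNode:
    node_id: str
    label: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted species tree (polytomies allowed) with named clade handles."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._postorder: list[TreeNode] = []
        self._collect(root)
        self.leaves = [n for n in self._postorder if n.is_leaf]
        labels = [n.label for n in self.leaves]
        dup = {x for x in labels if labels.count(x) > 1}
        if dup:
            raise TreeError(f"duplicate leaf labels: {sorted(dup)}")
        self._leaf_by_label = {n.label: n for n in self.leaves}
        self.clades: dict[str, TreeNode] = {}
        self._leafset: dict[str, frozenset[str]] = {}
        for n in self._postorder:
            if n.is_leaf:
                self._leafset[n.node_id] = frozenset([n.label])
            else:
                self._leafset[n.node_id] = frozenset().union(
                    *(self._leafset[c.node_id] for c in n.children)
                )

    def _collect(self, node: TreeNode) -> None:
        for c in node.children:
            c.parent = node
            self._collect(c)
        node.node_id = node.label if node.is_leaf and node.label else f"n{len(self._postorder)}"
        self._postorder.append(node)

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> list[TreeNode]:
        return list(self._postorder)

    def edges(self) -> list[tuple[TreeNode, TreeNode]]:
        return [(n.parent, n) for n in self._postorder if n.parent is not None]

    def leaf_order(self) -> list[str]:
        """Leaf labels in the tree's left-to-right (input Newick) order."""
        return [n.label for n in self.leaves]

    def leafset(self, node: TreeNode) -> frozenset[str]:
        return self._leafset[node.node_id]

    # -- clades ------------------------------------------------------------
    def mrca(self, labels: Iterable[str]) -> TreeNode:
        want = frozenset(labels)
        missing = want - set(self._leaf_by_label)
        if missing:
            raise TreeError(f"unknown leaves: {sorted(missing)}")
        best = self.root
        for n in self._postorder:  # postorder: smallest covering node first
            if want <= self._leafset[n.node_id]:
                return n
        return best  # pragma: no cover - root always covers

    def bind_clade(self, name: str, members: Iterable[str]) -> TreeNode:
        node = self.mrca(members)
        self.clades[name] = node
        return node

    def clade_leaves(self, name: str) -> frozenset[str]:
        if name not in self.clades:
            raise TreeError(f"clade handle {name!r} not bound")
        return self._leafset[self.clades[name].node_id]

    def branch_label(self, node: TreeNode) -> str:
        """Human-readable branch id: the child's leaf set."""
        if node.is_leaf:
            return node.label
        ls = sorted(self._leafset[node.node_id])
        return "+".join(ls)

    # -- I/O -----------------------------------------------------------------
    def to_newick(self) -> str:
        def render(n: TreeNode) -> str:
            if n.is_leaf:
                body = n.label
            else:
                body = "(" + ",".join(render(c) for c in n.children) + ")"
                if n.label:
                    body += n.label
            if n.length is not None:
                body += f":{n.length:g}"
            return body

        return render(self.root) + ";"


def parse_newick(text: str) -> SpeciesTree:
    """Parse a rooted Newick string, preserving child order.

    Raises :class:`TreeError` for malformed input or duplicate leaf labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy error messages carry the position
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = TreeNode(node_id="", label=label, length=dnode.edge.length)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    if root.is_leaf:
        raise TreeError("tree has a single node; need a rooted tree with leaves")
    return SpeciesTree(root)


def read_newick(path) -> SpeciesTree:
    with open(path) as fh:
        return parse_newick(fh.read())


# --- characters & reconstructions ----------------------------------------

@dataclass
class BinaryCharacter:
    """Presence (1) / absence (0) of one miRNA at every tree leaf."""

    mirna_name: str
    tip_states: Mapping[str, int]

    def validate(self, tree: SpeciesTree) -> None:
        missing = set(tree.leaf_order()) - set(self.tip_states)
        if missing:
            raise TreeError(
                f"{self.mirna_name}: no state for leaves {sorted(missing)}"
            )


@dataclass
class GainLossReconstruction:
    """Ancestral states plus the per-branch gain/loss event list.

    ``events`` holds ``(branch_id, kind)`` where branch_id is the child
    node's id (``ROOT_STEM`` for the virtual branch above the root) and kind
    is ``"gain"`` or ``"loss"``.
    """

    method: str
    mirna_name: str
    node_states: dict[str, int]
    events: list[tuple[str, str]]
    total_cost: float
    ambiguous_nodes: frozenset[str] = frozenset()

    @property
    def n_gains(self) -> int:
        return sum(1 for _, k in self.events if k == "gain")

    @property
    def n_losses(self) -> int:
        return sum(1 for _, k in self.events if k == "loss")


def _events_from_states(
    tree: SpeciesTree, states: Mapping[str, int], root_stem_from: int | None
) -> list[tuple[str, str]]:
    events: list[tuple[str, str]] = []
    if root_stem_from is not None:
        r = states[tree.root.node_id]
        if r != root_stem_from:
            events.append((ROOT_STEM, "gain" if r == 1 else "loss"))
    for parent, child in tree.edges():
        a, b = states[parent.node_id], states[child.node_id]
        if a != b:
            events.append((child.node_id, "gain" if b == 1 else "loss"))
    return events


def fitch_min_changes(
    tree: SpeciesTree, character: BinaryCharacter
) -> GainLossReconstruction:
    """Minimum-change reconstruction of a binary character (regains allowed).

    Computed by unit-cost dynamic programming over the rooted tree, which is
    exact for polytomies. Returns one minimizing assignment with ties broken
    toward later events (a child keeps its parent's state when both options
    are optimal); nodes whose state differs between minimum-cost
    reconstructions are flagged in ``ambiguous_nodes``.
    """
    character.validate(tree)
    INF = math.inf
    cost: dict[str, list[float]] = {}
    for n in tree.postorder():
        if n.is_leaf:
            s = int(character.tip_states[n.label])
            cost[n.node_id] = [0.0 if s == 0 else INF, 0.0 if s == 1 else INF]
        else:
            c0 = c1 = 0.0
            for ch in n.children:
                k0, k1 = cost[ch.node_id]
                c0 += min(k0, k1 + 1)
                c1 += min(k0 + 1, k1)
            cost[n.node_id] = [c0, c1]

    r0, r1 = cost[tree.root.node_id]
    total = min(r0, r1)

    # one MPR, DELTRAN-style: keep the parent's state on ties
    states: dict[str, int] = {}
    root_state = 0 if r0 <= r1 else 1
    states[tree.root.node_id] = root_state
    for n in reversed(tree.postorder()):  # preorder
        if n.parent is None:
            continue
        sp = states[n.parent.node_id]
        k0, k1 = cost[n.node_id]
        o0, o1 = k0 + (sp != 0), k1 + (sp != 1)
        if o0 < o1:
            states[n.node_id] = 0
        elif o1 < o0:
            states[n.node_id] = 1
        else:
            states[n.node_id] = sp

    # states achievable in at least one MPR (for ambiguity flags)
    achievable: dict[str, set[int]] = {
        tree.root.node_id: {s for s, c in ((0, r0), (1, r1)) if c == total}
    }
    for n in reversed(tree.postorder()):
        if n.parent is None:
            continue
        k = cost[n.node_id]
        opts: set[int] = set()
        for sp in achievable[n.parent.node_id]:
            best = min(k[0] + (sp != 0), k[1] + (sp != 1))
            opts |= {s for s in (0, 1) if k[s] + (sp != s) == best}
        achievable[n.node_id] = opts
    ambiguous = frozenset(nid for nid, s in achievable.items() if len(s) > 1)

    return GainLossReconstruction(
        method="fitch",
        mirna_name=character.mirna_name,
        node_states=states,
        events=_events_from_states(tree, states, root_stem_from=None),
        total_cost=total,
        ambiguous_nodes=ambiguous,
    )


def dollo_reconstruct(
    tree: SpeciesTree, character: BinaryCharacter
) -> GainLossReconstruction:
    """Single-gain reconstruction with a minimal set of subsequent losses.

    The gain sits on the branch entering the MRCA of all present leaves (the
    virtual root stem if that MRCA is the root); below it, a node is present
    iff some descendant leaf is present, which places exactly one loss on
    each maximal absent subtree — the minimum possible. All-absent
    characters are rejected (no origin to place).
    """
    character.validate(tree)
    present = [l for l, s in character.tip_states.items() if s == 1]
    if not present:
        raise TreeError(f"{character.mirna_name}: all-absent character under Dollo")
    origin = tree.mrca(present)
    inside: set[str] = set()
    stack = [origin]
    while stack:
        n = stack.pop()
        inside.add(n.node_id)
        stack.extend(n.children)

    states: dict[str, int] = {}
    for n in tree.postorder():
        if n.node_id not in inside:
            states[n.node_id] = 0
        elif n.is_leaf:
            states[n.node_id] = int(character.tip_states[n.label])
        else:
            states[n.node_id] = int(any(states[c.node_id] for c in n.children))

    events: list[tuple[str, str]] = []
    events.append((ROOT_STEM if origin is tree.root else origin.node_id, "gain"))
    for parent, child in tree.edges():
        if child is origin:
            continue
        a, b = states[parent.node_id], states[child.node_id]
        if a == 1 and b == 0:
            events.append((child.node_id, "loss"))
        elif a == 0 and b == 1:  # pragma: no cover - construction forbids
            raise AssertionError("second gain in Dollo reconstruction")
    n_losses = sum(1 for _, k in events if k == "loss")
    return GainLossReconstruction(
        method="dollo",
        mirna_name=character.mirna_name,
        node_states=states,
        events=events,
        total_cost=1.0 + n_losses,
    )


def count_independent_gains(
    tree: SpeciesTree,
    character: BinaryCharacter,
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
) -> int:
    """Minimum number of gain events over all minimum-cost reconstructions.

    Weighted-parsimony dynamic programming with the root prior fixed to
    absent: an all-present character costs one gain, placed on the virtual
    root stem. Among assignments achieving the minimum total cost, the one
    with the fewest gains is counted (the count is tie-break independent).
    """
    character.validate(tree)
    if gain_cost <= 0 or loss_cost <= 0:
        raise TreeError("gain_cost and loss_cost must be positive")

    def edge_cost(a: int, b: int) -> tuple[float, int]:
        if a == b:
            return 0.0, 0
        return (gain_cost, 1) if b == 1 else (loss_cost, 0)

    # per node and state: (min cost, min gains among min-cost subtrees)
    best: dict[str, list[tuple[float, int]]] = {}
    INF = (math.inf, 0)
    for n in tree.postorder():
        if n.is_leaf:
            s = int(character.tip_states[n.label])
            best[n.node_id] = [(0.0, 0) if s == 0 else INF,
                               (0.0, 0) if s == 1 else INF]
        else:
            acc = [(0.0, 0), (0.0, 0)]
            for ch in n.children:
                kb = best[ch.node_id]
                for s in (0, 1):
                    opts = []
                    for t in (0, 1):
                        c, g = edge_cost(s, t)
                        opts.append((kb[t][0] + c, kb[t][1] + g))
                    pick = min(opts)
                    acc[s] = (acc[s][0] + pick[0], acc[s][1] + pick[1])
            best[n.node_id] = acc

    opts = []
    rb = best[tree.root.node_id]
    for s in (0, 1):
        c, g = edge_cost(0, s)  # virtual root stem from an absent ancestor
        opts.append((rb[s][0] + c, rb[s][1] + g))
    total_cost, total_gains = min(opts)
    if math.isinf(total_cost):  # pragma: no cover - binary chars always finite
        raise TreeError("no feasible reconstruction")
    return total_gains
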