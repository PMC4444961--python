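"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's scanning and dynamic-programming
code paths: the scanner oracle compares substrings position by position,
and the parsimony oracle enumerates every ancestral state assignment.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA = set("ACGT")


def naive_revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def naive_scan(
    queries: dict[str, str], contig: str, max_mismatches: int = 0
) -> set[tuple[str, int, str]]:
    """All (name, start, strand) occurrences by direct window comparison."""
    contig = contig.upper()
    out: set[tuple[str, int, str]] = set()
    for name, query in queries.items():
        L = len(query)
        targets = ((query, "+"), (naive_revcomp(query), "-"))
        for start in range(len(contig) - L + 1):
            window = contig[start : start + L]
            if set(window) - _DNA:
                continue
            for pattern, strand in targets:
                if max_mismatches == 0:
                    if window == pattern:
                        out.add((name, start, strand))
                else:
                    mm = sum(a != b for a, b in zip(window, pattern))
                    if mm <= max_mismatches:
                        out.add((name, start, strand))
    return out


def _tree_arrays(tree):
    """Node indexing + edge list for enumeration over a SpeciesTree."""
    nodes = tree.postorder()
    index = {n.node_id: i for i, n in enumerate(nodes)}
    leaves = [(index[n.node_id], n.label) for n in nodes if n.is_leaf]
    internals = [index[n.node_id] for n in nodes if not n.is_leaf]
    edges = [(index[p.node_id], index[c.node_id]) for p, c in tree.edges()]
    root = index[tree.root.node_id]
    return len(nodes), leaves, internals, edges, root


def enumerate_reconstructions(tree, tip_states: dict[str, int]):
    """Exhaustive statistics over all ancestral assignments.

    Returns (fitch_min_cost, min_gains_rootprior0, dollo_min_losses) where
    fitch counts changes on tree branches only, the gain count includes a
    virtual root-stem branch from an absent ancestor, and the Dollo loss
    count is the minimum over assignments with exactly one gain (None for
    all-absent characters).
    """
    n, leaves, internals, edges, root = _tree_arrays(tree)
    k = len(internals)
    m = 2 ** k
    states = np.zeros((m, n), dtype=np.int8)
    for i, label in leaves:
        states[:, i] = tip_states[label]
    if k:
        assign = (
            (np.arange(m)[:, None] >> np.arange(k)[None, :]) & 1
        ).astype(np.int8)
        states[:, internals] = assign
    gains = np.zeros(m, dtype=np.int64)
    losses = np.zeros(m, dtype=np.int64)
    for p, c in edges:
        gains += (states[:, c] > states[:, p]).astype(np.int64)
        losses += (states[:, c] < states[:, p]).astype(np.int64)
    changes = gains + losses
    fitch_min = int(changes.min())

    stem_gain = states[:, root].astype(np.int64)  # super-root is absent
    total = changes + stem_gain
    total_gains = gains + stem_gain
    best = total.min()
    min_gains = int(total_gains[total == best].min())

    dollo_losses = None
    if any(tip_states.values()):
        single = total_gains == 1
        if single.any():
            dollo_losses = int(losses[single].min())
    return fitch_min, min_gains, dollo_losses


def enumerate_weighted_min_gains(
    tree, tip_states: dict[str, int], gain_cost: float, loss_cost: float
) -> int:
    """Min gains among minimum weighted-cost assignments (root prior 0)."""
    n, leaves, internals, edges, root = _tree_arrays(tree)
    k = len(internals)
    m = 2 ** k
    states = np.zeros((m, n), dtype=np.int8)
    for i, label in leaves:
        states[:, i] = tip_states[label]
    if k:
        assign = (
            (np.arange(m)[:, None] >> np.arange(k)[None, :]) & 1
        ).astype(np.int8)
        states[:, internals] = assign
    gains = np.zeros(m, dtype=np.int64)
    losses = np.zeros(m, dtype=np.int64)
    for p, c in edges:
        gains += (states[:, c] > states[:, p]).astype(np.int64)
        losses += (states[:, c] < states[:, p]).astype(np.int64)
    gains += states[:, root]
    cost = gain_cost * gains + loss_cost * losses
    best = cost.min()
    return int(gains[np.isclose(cost, best)].min())


def random_topology(rng: np.random.Generator, n_leaves: int, allow_polytomy=True):
    """Random rooted tree as a Newick string (possibly with polytomies)."""
    parts = [f"L{i}" for i in range(n_leaves)]
    while len(parts) > 1:
        take = 2
        if allow_polytomy and len(parts) > 2 and rng.random() < 0.3:
            take = int(rng.integers(3, min(4, len(parts)) + 1))
        picks = sorted(rng.choice(len(parts), size=take, replace=False))
        group = "(" + ",".join(parts[i] for i in picks) + ")"
        parts = [p for i, p in enumerate(parts) if i not in picks] + [group]
    return parts[0] + ";"
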