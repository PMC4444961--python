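"""Synthetic data with the statistical structure the analysis assumes.

Three layers, all deterministic given a seed:

1. a species tree with branch lengths (random join order, exponential
   branch lengths);
2. per-miRNA presence evolution down the tree under a two-state
   continuous-time gain/loss process (rates per unit branch length, root
   state drawn from a root presence probability);
3. background genomes (i.i.d. nucleotides at a chosen GC content) with each
   truly-present mature sequence planted once at a uniform position and
   strand, minus cells vetoed at a tunable false-negative rate emulating
   assembly gaps.

Backgrounds are rejection-sampled so that no catalog sequence occurs by
chance, which makes recovery tests exact: with ``fn_rate = 0``, scanning the
generated panel reproduces the simulated truth matrix cell for cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import MatureMiRNA, MiRNACatalog, assign_family
from .phylo import ROOT_STEM, SpeciesTree, TreeError, TreeNode
from .profile import PresenceAbsenceMatrix
from .scan import GenomeRecord, HitRecord, reverse_complement, scan_genome

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationError",
    "random_tree",
    "simulate_presence_evolution",
    "make_catalog",
    "generate_genomes",
    "write_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    """Raised on invalid simulation configuration or sizing."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    gain_rate / loss_rate are per unit branch length; fn_rate is the
    probability that a truly-present (miRNA, genome) cell is omitted from
    the assembly (genome-level false negative).
    """

    tree: SpeciesTree
    n_mirnas: int = 50
    gain_rate: float = 0.5
    loss_rate: float = 0.5
    root_presence_prob: float = 0.5
    genome_length: int = 200_000
    gc_content: float = 0.42
    fn_rate: float = 0.0
    seed: int = 0
    mirna_length: int = 22

    def validate(self) -> None:
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise SimulationError("rates must be >= 0")
        for p in (self.root_presence_prob, self.fn_rate, self.gc_content):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("probabilities must lie in [0, 1]")
        if self.genome_length < 10 * self.mirna_length:
            raise SimulationError(
                "genome_length must be >= 10 x query length"
            )
        if self.gain_rate > 0 or self.loss_rate > 0:
            if any(
                n.length is None for n in self.tree.postorder() if n.parent is not None
            ):
                raise SimulationError(
                    "tree must carry branch lengths when rates are positive"
                )


@dataclass
class SimulationTruth:
    """Ground truth of one simulated panel."""

    true_matrix: PresenceAbsenceMatrix
    event_log: list[tuple[str, str, str]]  # (mirna, branch_id, gain|loss)
    planted_positions: list[tuple[str, str, str, int, str]] = field(
        default_factory=list
    )  # (mirna, genome, contig, start, strand)
    dropped: list[tuple[str, str]] = field(default_factory=list)
    collision_probability: float = 0.0


def random_tree(n_leaves: int, seed: int, mean_branch: float = 0.5) -> SpeciesTree:
    """Random rooted binary tree by uniform pair joining; exponential branch
    lengths with the given mean. Leaves are labeled ``g01, g02, ...``."""
    if n_leaves < 2:
        raise SimulationError("need >= 2 leaves")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_leaves)))
    nodes = [
        TreeNode(node_id="", label=f"g{i + 1:0{width}d}",
                 length=float(rng.exponential(mean_branch)))
        for i in range(n_leaves)
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(
            node_id="",
            length=float(rng.exponential(mean_branch)),
            children=[nodes[i], nodes[j]],
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    nodes[0].length = None
    return SpeciesTree(nodes[0])


def _transition_probs(state: int, t: float, gain: float, loss: float) -> float:
    """P(child state = 1 | parent state) under the two-state CTMC."""
    r = gain + loss
    if r == 0.0:
        return float(state)
    decay = 1.0 - np.exp(-r * t)
    if state == 0:
        return (gain / r) * decay
    return 1.0 - (loss / r) * decay


def simulate_presence_evolution(config: SimulationConfig) -> SimulationTruth:
    """Evolve presence/absence for each miRNA down the tree.

    Root states are Bernoulli(root_presence_prob); each branch flips state
    with the closed-form two-state transition probability for its length.
    A root drawn present is logged as a gain on the virtual root stem, so a
    leaf is present iff a gain survives to it in the event log.
    """
    config.validate()
    tree = config.tree
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    names = [f"sim-miR-{i + 1}" for i in range(config.n_mirnas)]
    leaves = tree.leaf_order()
    events: list[tuple[str, str, str]] = []
    rows = {}
    preorder = list(reversed(tree.postorder()))
    for name in names:
        states: dict[str, int] = {}
        root_state = int(rng.random() < config.root_presence_prob)
        states[tree.root.node_id] = root_state
        if root_state == 1:
            events.append((name, ROOT_STEM, "gain"))
        for node in preorder:
            if node.parent is None:
                continue
            parent_state = states[node.parent.node_id]
            p1 = _transition_probs(
                parent_state, node.length or 0.0, config.gain_rate, config.loss_rate
            )
            s = int(rng.random() < p1)
            states[node.node_id] = s
            if s != parent_state:
                events.append((name, node.node_id, "gain" if s == 1 else "loss"))
        rows[name] = [states[leaf] for leaf in leaves]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=leaves)
    return SimulationTruth(
        true_matrix=PresenceAbsenceMatrix(values, panel_tag="simulated"),
        event_log=events,
    )


def make_catalog(config: SimulationConfig) -> MiRNACatalog:
    """One random fixed mature sequence per simulated miRNA.

    Collision-checked: all sequences and their reverse complements are
    pairwise distinct, so presence calls are unambiguous.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    p = np.array(
        [
            (1 - config.gc_content) / 2,
            config.gc_content / 2,
            config.gc_content / 2,
            (1 - config.gc_content) / 2,
        ]
    )
    entries = []
    seen: set[str] = set()
    for i in range(config.n_mirnas):
        for _ in range(1000):
            seq = bytes(
                _BASES[rng.choice(4, size=config.mirna_length, p=p)]
            ).decode()
            rc = reverse_complement(seq)
            if seq not in seen and rc not in seen and seq != rc:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise SimulationError("could not draw collision-free catalog")
        seen.add(seq)
        seen.add(rc)
        name = f"sim-miR-{i + 1}"
        entries.append(
            MatureMiRNA(
                name=name,
                species_prefix="sim",
                family=assign_family(name),
                sequence=seq,
                source_ids=[name],
            )
        )
    return MiRNACatalog(entries)


def _draw_background(
    rng: np.random.Generator, length: int, gc: float
) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def generate_genomes(
    truth: SimulationTruth,
    catalog: MiRNACatalog,
    config: SimulationConfig,
) -> dict[str, GenomeRecord]:
    """Build one single-contig genome per tree leaf with planted matures.

    Each truly-present miRNA is planted once at a uniform non-overlapping
    position and strand, except cells vetoed at ``fn_rate`` (recorded in
    ``truth.dropped``). The background is rejection-sampled and the final
    genome re-scanned so the hit set is exactly the planted set.
    """
    config.validate()
    matrix = truth.true_matrix
    genome_ids = matrix.col_names
    ss = np.random.SeedSequence(config.seed).spawn(4)
    fn_rng = np.random.default_rng(ss[2])
    genome_seeds = ss[3].spawn(len(genome_ids))

    # genome-level false-negative vetoes, drawn cell by cell in fixed order
    truth.dropped = []
    plant_plan: dict[str, list[str]] = {g: [] for g in genome_ids}
    for name in matrix.row_names:
        for g in genome_ids:
            if matrix[name, g] == 1:
                if fn_rng.random() < config.fn_rate:
                    truth.dropped.append((name, g))
                else:
                    plant_plan[g].append(name)

    L = config.mirna_length
    n_windows = 2 * max(0, config.genome_length - L + 1) * len(catalog)
    truth.collision_probability = float(
        1.0 - (1.0 - 0.25 ** L) ** max(1, n_windows)
    )

    genomes: dict[str, GenomeRecord] = {}
    truth.planted_positions = []
    for gid, gseed in zip(genome_ids, genome_seeds):
        rng = np.random.default_rng(gseed)
        for _attempt in range(100):
            arr = _draw_background(rng, config.genome_length, config.gc_content)
            occupied: list[tuple[int, int]] = []
            planted: list[tuple[str, int, str]] = []
            ok = True
            for name in plant_plan[gid]:
                seq = catalog.by_name[name].sequence
                placed = False
                for _try in range(200):
                    start = int(rng.integers(0, config.genome_length - L + 1))
                    if all(start + L <= a or start >= b for a, b in occupied):
                        placed = True
                        break
                if not placed:
                    raise SimulationError(
                        f"cannot place {len(plant_plan[gid])} patterns without "
                        f"overlap in {config.genome_length} nt"
                    )
                strand = "+" if rng.random() < 0.5 else "-"
                text = seq if strand == "+" else reverse_complement(seq)
                arr[start : start + L] = np.frombuffer(
                    text.encode(), dtype=np.uint8
                )
                occupied.append((start, start + L))
                planted.append((name, start, strand))
            genome = GenomeRecord(
                genome_id=gid, contigs={"chr1": bytes(arr).decode()}
            )
            expect = {(n, s, st) for n, s, st in planted}
            got = {
                (h.mirna_name, h.start, h.strand)
                for h in scan_genome(catalog, genome)
            }
            if got == expect:
                genomes[gid] = genome
                truth.planted_positions.extend(
                    (n, gid, "chr1", s, st) for n, s, st in planted
                )
                break
            ok = False
        else:
            raise SimulationError(
                f"could not draw a collision-free genome for {gid}"
            )
    return genomes


def write_panel(
    truth: SimulationTruth,
    genomes: dict[str, GenomeRecord],
    catalog: MiRNACatalog,
    config: SimulationConfig,
    outdir: str | Path,
) -> None:
    """Emit FASTA panel + catalog + truth/event TSVs + Newick tree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gid, genome in genomes.items():
        with open(outdir / f"{gid}.fa", "w") as fh:
            for cid, seq in genome.contigs.items():
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    catalog.to_fasta(outdir / "catalog.fa")
    catalog.to_tsv(outdir / "catalog.tsv")
    truth.true_matrix.to_tsv(outdir / "truth_matrix.tsv")
    with open(outdir / "event_log.tsv", "w") as fh:
        fh.write("mirna\tbranch\tevent\n")
        for name, branch, kind in truth.event_log:
            fh.write(f"{name}\t{branch}\t{kind}\n")
    with open(outdir / "dropped.tsv", "w") as fh:
        fh.write("mirna\tgenome\n")
        for name, g in truth.dropped:
            fh.write(f"{name}\t{g}\n")
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(config.tree.to_newick() + "\n")
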