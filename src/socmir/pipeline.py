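"""One-command orchestration: catalog → scan → matrix → screens → parsimony.

A run is configured by a YAML file (paths, panels, clade bindings,
thresholds) and writes every stage product to the output directory: hits
(BED6 + TSV), the raw and per-panel filtered/tree-ordered matrices,
candidate reports for both screens, per-miRNA parsimony summaries, and a
machine-readable run report. Outputs carry no timestamps, so a rerun on
identical inputs is byte-identical (the human-readable summary isolates its
timestamp to one header line).
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import DEFAULT_PRECEDENCE, dedup_catalog, load_mature_fasta
from .phylo import dollo_reconstruct, fitch_min_changes, count_independent_gains, read_newick
from .profile import PresenceAbsenceMatrix, filter_informative, order_columns, restrict_panel
from .scan import call_presence, load_genome_fasta, scan_genome, write_bed, write_hits_tsv
from .screens import TraitLabels, clade_exclusive, clade_universal, convergence_summary, trait_exclusive
from .phylo import BinaryCharacter

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "render_report"]


class PipelineError(RuntimeError):
    """Stage-labeled pipeline failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    catalog_path: Path
    genomes: dict[str, Path]  # genome_id -> FASTA path
    tree_path: Path
    labels_path: Path
    outdir: Path
    panels: dict[str, list[str]] = field(default_factory=dict)
    clades: dict[str, list[str]] = field(default_factory=dict)
    precedence: list[str] = field(default_factory=lambda: list(DEFAULT_PRECEDENCE))
    max_mismatches: int = 0
    min_positive: int = 1
    min_inside: int = 1
    tolerance: int = 0
    trait_panel: str = "all"
    clade_panel: str = "all"
    screen_clade: str | None = None
    universal_clade: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def p(key: str) -> Path:
            q = Path(raw[key])
            return q if q.is_absolute() else base / q

        genomes = {}
        for entry in raw["genomes"]:
            q = Path(entry["fasta"])
            genomes[entry["genome_id"]] = q if q.is_absolute() else base / q
        screens = raw.get("screens", {})
        scanner = raw.get("scanner", {})
        cfg = cls(
            catalog_path=p("catalog"),
            genomes=genomes,
            tree_path=p("tree"),
            labels_path=p("labels"),
            outdir=Path(raw["outdir"]) if Path(raw["outdir"]).is_absolute() else base / raw["outdir"],
            panels=raw.get("panels", {}),
            clades=raw.get("clades", {}),
            precedence=raw.get("precedence", list(DEFAULT_PRECEDENCE)),
            max_mismatches=int(scanner.get("max_mismatches", 0)),
            min_positive=int(screens.get("min_positive", 1)),
            min_inside=int(screens.get("min_inside", 1)),
            tolerance=int(screens.get("tolerance", 0)),
            trait_panel=screens.get("trait_panel", "all"),
            clade_panel=screens.get("clade_panel", "all"),
            screen_clade=screens.get("clade_exclusive"),
            universal_clade=screens.get("clade_universal"),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for label, q in [("catalog", self.catalog_path), ("tree", self.tree_path),
                         ("labels", self.labels_path)] + [
            (f"genome {g}", q) for g, q in self.genomes.items()
        ]:
            if not Path(q).exists():
                raise PipelineError("config", "missing-path", f"{label}: {q}")
        panel_ids = set(self.genomes)
        for name, members in self.clades.items():
            extra = set(members) - panel_ids
            if extra:
                raise PipelineError(
                    "config", "clade-outside-panel",
                    f"clade {name!r} members not in panel: {sorted(extra)}",
                )
        for name, members in self.panels.items():
            extra = set(members) - panel_ids
            if extra:
                raise PipelineError(
                    "config", "panel-outside-panel",
                    f"panel {name!r} members not in panel: {sorted(extra)}",
                )


def _log(stage: str, message: str) -> None:
    print(f"[socmir:{stage}] {message}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the JSON run report."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "max_mismatches": config.max_mismatches,
            "min_positive": config.min_positive,
            "min_inside": config.min_inside,
            "tolerance": config.tolerance,
        },
        "stages": {},
    }

    # -- catalog -----------------------------------------------------------
    stage = "catalog"
    try:
        entries = load_mature_fasta(config.catalog_path)
        if not entries:
            raise ValueError("empty catalog")
        catalog = dedup_catalog(entries, config.precedence)
        catalog.to_tsv(out / "catalog.tsv")
    except Exception as exc:
        raise PipelineError(stage, "catalog-error", str(exc)) from exc
    report["stages"][stage] = {"records": len(entries), "queries": len(catalog)}
    _log(stage, f"{len(entries)} records -> {len(catalog)} unique queries")

    # -- scan --------------------------------------------------------------
    stage = "scan"
    all_hits = []
    try:
        for gid, path in config.genomes.items():
            genome = load_genome_fasta(path, gid)
            hits = scan_genome(catalog, genome, config.max_mismatches)
            all_hits.extend(hits)
        write_bed(all_hits, out / "hits.bed")
        write_hits_tsv(all_hits, out / "hits.tsv")
    except Exception as exc:
        raise PipelineError(stage, "scan-error", str(exc)) from exc
    report["stages"][stage] = {"genomes": len(config.genomes), "hits": len(all_hits)}
    _log(stage, f"{len(all_hits)} hits across {len(config.genomes)} genomes")

    # -- matrix ------------------------------------------------------------
    stage = "matrix"
    try:
        tree = read_newick(config.tree_path)
        for name, members in config.clades.items():
            tree.bind_clade(name, members)
        matrix = call_presence(all_hits, catalog, list(config.genomes))
        matrix.to_tsv(out / "matrix_raw.tsv")
        panels = dict(config.panels)
        panels.setdefault("all", list(config.genomes))
        panel_mats: dict[str, PresenceAbsenceMatrix] = {}
        for tag, members in panels.items():
            pm = restrict_panel(matrix, members, panel_tag=tag)
            pm = filter_informative(pm)
            leaf_order = [l for l in tree.leaf_order() if l in set(members)]
            if set(leaf_order) == set(members):
                pm = order_columns(pm, leaf_order)
            panel_mats[tag] = pm
            pm.to_tsv(out / f"matrix_{tag}.tsv")
    except Exception as exc:
        raise PipelineError(stage, "matrix-error", str(exc)) from exc
    report["stages"][stage] = {
        tag: {"rows": m.shape[0], "cols": m.shape[1]} for tag, m in panel_mats.items()
    }
    _log(stage, f"panels: { {t: m.shape for t, m in panel_mats.items()} }")

    # -- screens -----------------------------------------------------------
    stage = "associate"
    try:
        labels = TraitLabels.from_tsv(config.labels_path)
        labels.to_tsv(out / "labels.tsv")
        candidates: dict[str, list] = {}
        tmat = panel_mats[config.trait_panel]
        candidates["trait_exclusive"] = trait_exclusive(
            tmat, labels, config.min_positive
        )
        cmat = panel_mats[config.clade_panel]
        if config.screen_clade:
            candidates[f"clade_exclusive:{config.screen_clade}"] = clade_exclusive(
                cmat, tree, config.screen_clade, config.min_inside
            )
        if config.universal_clade:
            candidates[f"clade_universal:{config.universal_clade}"] = clade_universal(
                cmat, tree, config.universal_clade, config.tolerance
            )
        conv = convergence_summary(panel_mats["all"], tree, labels)
        conv.to_csv(out / "convergence_summary.tsv", sep="\t", index=False)
        with open(out / "candidates.json", "w") as fh:
            json.dump(
                {k: [c.to_dict() for c in v] for k, v in candidates.items()},
                fh, indent=2, sort_keys=True,
            )
        rows = [
            {"screen": k, "mirna_name": c.mirna_name,
             "present_in": ";".join(c.present_in)}
            for k, v in sorted(candidates.items()) for c in v
        ]
        pd.DataFrame(rows, columns=["screen", "mirna_name", "present_in"]).to_csv(
            out / "candidates.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise PipelineError(stage, "screen-error", str(exc)) from exc
    report["stages"][stage] = {k: len(v) for k, v in candidates.items()}
    _log(stage, f"candidates: { {k: len(v) for k, v in candidates.items()} }")

    # -- reconstruct -------------------------------------------------------
    stage = "reconstruct"
    try:
        recs = {}
        base = panel_mats["all"]
        for mirna in base.row_names:
            char = BinaryCharacter(
                mirna, {g: base[mirna, g] for g in base.col_names}
            )
            fitch = fitch_min_changes(tree, char)
            entry = {
                "fitch": {
                    "cost": fitch.total_cost,
                    "gains": fitch.n_gains,
                    "losses": fitch.n_losses,
                    "events": [
                        {"branch": b, "event": k} for b, k in fitch.events
                    ],
                },
                "min_independent_gains": count_independent_gains(tree, char),
            }
            if any(char.tip_states.values()):
                dollo = dollo_reconstruct(tree, char)
                entry["dollo"] = {
                    "cost": dollo.total_cost,
                    "losses": dollo.n_losses,
                    "events": [
                        {"branch": b, "event": k} for b, k in dollo.events
                    ],
                }
            recs[mirna] = entry
        with open(out / "reconstructions.json", "w") as fh:
            json.dump(recs, fh, indent=2, sort_keys=True)
        pd.DataFrame(
            [
                {
                    "mirna_name": m,
                    "fitch_cost": r["fitch"]["cost"],
                    "fitch_gains": r["fitch"]["gains"],
                    "fitch_losses": r["fitch"]["losses"],
                    "dollo_cost": r.get("dollo", {}).get("cost"),
                    "independent_gains": r["min_independent_gains"],
                }
                for m, r in recs.items()
            ]
        ).to_csv(out / "reconstructions.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, "reconstruct-error", str(exc)) from exc
    report["stages"][stage] = {"characters": len(recs)}
    _log(stage, f"{len(recs)} characters reconstructed")

    report["complete"] = True
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def output_hashes(outdir: str | Path) -> dict[str, str]:
    """SHA-256 of every pipeline output file (for determinism checks)."""
    outdir = Path(outdir)
    hashes = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "summary.txt":
            hashes[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return hashes


def render_report(outdir: str | Path, heatmaps: bool = True) -> Path:
    """Human-readable summary + figure-style heatmaps for a completed run.

    Heatmaps show present cells in yellow and absent in blue, with
    trait-exclusive rows framed in black and clade-exclusive rows in red.
    The summary's timestamp is isolated to its first line.
    """
    import datetime

    outdir = Path(outdir)
    report_path = outdir / "run_report.json"
    if not report_path.exists():
        raise PipelineError("render", "incomplete-run", f"no run report in {outdir}")
    with open(report_path) as fh:
        report = json.load(fh)
    if not report.get("complete"):
        raise PipelineError("render", "incomplete-run", "run report marked incomplete")
    with open(outdir / "candidates.json") as fh:
        candidates = json.load(fh)

    lines = [f"# generated: {datetime.datetime.now().isoformat()}"]
    lines.append(f"socmir {report['version']} run summary (seed {report['seed']})")
    for stage, info in report["stages"].items():
        lines.append(f"  {stage}: {json.dumps(info, sort_keys=True)}")
    if not any(candidates.values()):
        lines.append("  both screens returned zero candidates")
    for screen, items in sorted(candidates.items()):
        names = ", ".join(c["mirna_name"] for c in items) or "(none)"
        lines.append(f"  {screen} ({len(items)}): {names}")
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")

    if heatmaps:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        framed_black = {
            c["mirna_name"]
            for k, v in candidates.items() if k == "trait_exclusive" for c in v
        }
        framed_red = {
            c["mirna_name"]
            for k, v in candidates.items()
            if k.startswith("clade_") for c in v
        } - framed_black
        for mat_path in sorted(outdir.glob("matrix_*.tsv")):
            tag = mat_path.stem.removeprefix("matrix_")
            if tag == "raw":
                continue
            m = PresenceAbsenceMatrix.from_tsv(mat_path)
            if m.shape[0] == 0:
                continue
            fig, ax = plt.subplots(
                figsize=(0.45 * m.shape[1] + 2, 0.3 * m.shape[0] + 1.5)
            )
            ax.imshow(
                m.values.to_numpy(),
                cmap=ListedColormap(["#2040a0", "#ffd700"]),
                vmin=0, vmax=1, aspect="auto", interpolation="nearest",
            )
            ax.set_xticks(range(m.shape[1]), m.col_names, rotation=90, fontsize=7)
            labels_path = outdir / "labels.tsv"
            if labels_path.exists():
                lab = TraitLabels.from_tsv(labels_path)
                for tick in ax.get_xticklabels():
                    g = tick.get_text()
                    if g in lab.labels and lab[g] == "positive":
                        tick.set_color("red")
            ax.set_yticks(range(m.shape[0]), m.row_names, fontsize=7)
            for i, name in enumerate(m.row_names):
                color = ("black" if name in framed_black
                         else "red" if name in framed_red else None)
                if color:
                    ax.add_patch(
                        plt.Rectangle(
                            (-0.5, i - 0.5), m.shape[1], 1,
                            fill=False, edgecolor=color, lw=1.6,
                        )
                    )
            ax.set_title(f"presence/absence — {tag} panel", fontsize=9)
            fig.tight_layout()
            fig.savefig(outdir / f"heatmap_{tag}.svg")
            plt.close(fig)
    return summary
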