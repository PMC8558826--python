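"""Pipeline orchestration: run the screen end to end, write tables & figures.

`run_screen` wires expression -> screen (-> enrichment when gene sets are
supplied) and writes the atlas outputs: `receptors.tsv`,
`pairs_<category>.tsv`, `orphans.tsv`, `autocrine_ligands.tsv`,
`summary.json`, optional `enrichment_*.tsv`, plus figures. Outputs are
deterministic: re-running on identical inputs overwrites with identical
content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import enrichment as enr
from .expression import load_expression, compute_tpm, summarize, summaries_to_frame
from .lr_database import CATEGORIES, default_pair_db, load_curation, load_pair_db
from .screen import AtlasReport, ScreenConfig, build_report

logger = logging.getLogger("lratlas")

__all__ = ["RunConfig", "run_screen", "make_figures", "write_tables"]


@dataclass
class RunConfig:
    """Paths and options for one pipeline run."""

    receiver: Path
    sender: Path
    outdir: Path
    pairs: Path | None = None  # None -> shipped default database
    curation: Path | None = None
    gene_sets: Path | None = None
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    receiver_mode: str = "tpm"  # "tpm" | "counts"
    sender_mode: str = "tpm"
    duplicate_policy: str = "error"
    alpha: float = 0.05
    image_format: str = "png"
    make_plots: bool = True

    def __post_init__(self) -> None:
        for name in ("receiver", "sender", "pairs", "curation", "gene_sets"):
            value = getattr(self, name)
            if value is not None:
                path = Path(value)
                setattr(self, name, path)
                if not path.exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")
        self.outdir = Path(self.outdir)


def _load_matrix(path: Path, mode: str, duplicate_policy: str):
    loaded = load_expression(path, mode=mode, duplicate_policy=duplicate_policy)
    if mode == "counts":
        loaded = compute_tpm(loaded)
    return loaded


def write_tables(report: AtlasReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "receptors.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene\tmean_tpm\tcategories\tn_ligands\tligands\torphan\n")
        for r in report.receptors:
            fh.write(
                f"{r.gene_id}\t{r.mean_tpm:.6g}\t{';'.join(sorted(r.categories))}"
                f"\t{len(r.ligands)}\t{';'.join(l.gene_id for l in r.ligands)}"
                f"\t{r.orphan}\n"
            )
    for category in sorted(CATEGORIES):
        rows = [p for p in report.pairs if p.category == category]
        with open(outdir / f"pairs_{category}.tsv", "w", encoding="utf-8") as fh:
            fh.write(
                "receptor\treceptor_tpm\tligand\tligand_kind\tmolecule"
                "\tligand_tpm\tligand_missing\tquadrant\tplotted\n"
            )
            for p in rows:
                fh.write(
                    f"{p.receptor_gene}\t{p.receptor_tpm:.6g}\t{p.ligand_gene}"
                    f"\t{p.ligand_kind}\t{p.molecule}\t{p.ligand_tpm:.6g}"
                    f"\t{p.ligand_missing}\t{p.quadrant}\t{p.plotted}\n"
                )
    with open(outdir / "orphans.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene\tmean_tpm\n")
        for r in report.orphans:
            fh.write(f"{r.gene_id}\t{r.mean_tpm:.6g}\n")
    with open(outdir / "autocrine_ligands.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene\tmean_tpm\n")
        for s in report.autocrine_ligands:
            fh.write(f"{s.gene_id}\t{s.mean_tpm:.6g}\n")
    (outdir / "summary.json").write_text(report.to_json(), encoding="utf-8")


def make_figures(report: AtlasReport, config: RunConfig) -> list[Path]:
    """Bar chart of top receptors; per-category scatter and high/high zoom.

    Scatter axes are log10 TPM with dashed cutoff lines at
    log10(high_cutoff) on both axes; only pairs passing the plot-inclusion
    rule (receptor TPM above the expressed cutoff and ligand TPM above the
    ligand plot cutoff) appear, which also guarantees both coordinates are
    log-plottable. Empty panels are skipped with a logged notice.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = config.image_format
    written: list[Path] = []
    cutoff = np.log10(report.config.high_cutoff)

    if report.top_receptors:
        top = report.top_receptors
        fig, ax = plt.subplots(figsize=(7, max(2.0, 0.18 * len(top))))
        ax.barh(
            [r.gene_id for r in reversed(top)],
            [r.mean_tpm for r in reversed(top)],
            color="#4878a8",
        )
        ax.set_xlabel("mean TPM (receiver)")
        ax.set_title(f"Top {len(top)} receptor genes")
        fig.tight_layout()
        path = outdir / f"top_receptors.{fmt}"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)

    if report.top_autocrine_ligands:
        top = report.top_autocrine_ligands
        fig, ax = plt.subplots(figsize=(7, max(2.0, 0.18 * len(top))))
        ax.barh(
            [s.gene_id for s in reversed(top)],
            [s.mean_tpm for s in reversed(top)],
            color="#6a9e58",
        )
        ax.set_xlabel("mean TPM (receiver)")
        ax.set_title(f"Top {len(top)} autocrine ligand genes")
        fig.tight_layout()
        path = outdir / f"top_autocrine_ligands.{fmt}"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)

    for category in sorted(CATEGORIES):
        shown = [p for p in report.pairs if p.category == category and p.plotted]
        if not shown:
            logger.info("no plottable pairs for category %s; figure skipped", category)
            continue
        for zoom, tag in ((False, "pairs"), (True, "pairs_highhigh")):
            pts = [p for p in shown if p.quadrant == "high_high"] if zoom else shown
            if not pts:
                logger.info("no high/high pairs for category %s; zoom skipped", category)
                continue
            fig, ax = plt.subplots(figsize=(5.5, 5))
            x = np.log10([p.ligand_tpm for p in pts])
            y = np.log10([p.receptor_tpm for p in pts])
            ax.scatter(x, y, s=18, alpha=0.8, color="#4878a8")
            if not zoom:
                ax.axhline(cutoff, ls="--", color="grey", lw=1)
                ax.axvline(cutoff, ls="--", color="grey", lw=1)
            else:
                for p, xi, yi in zip(pts, x, y):
                    ax.annotate(
                        f"{p.ligand_gene}-{p.receptor_gene}", (xi, yi), fontsize=6
                    )
            ax.set_xlabel("log10 ligand TPM (sender)")
            ax.set_ylabel("log10 receptor TPM (receiver)")
            ax.set_title(category.replace("_", " / "))
            fig.tight_layout()
            path = outdir / f"{tag}_{category}.{fmt}"
            fig.savefig(path)
            plt.close(fig)
            written.append(path)
    return written


def run_screen(config: RunConfig) -> AtlasReport:
    """Execute the full pipeline and write all outputs to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    try:
        receiver = _load_matrix(config.receiver, config.receiver_mode, config.duplicate_policy)
        sender = _load_matrix(config.sender, config.sender_mode, config.duplicate_policy)
        db = load_pair_db(config.pairs) if config.pairs else default_pair_db()
        curation = load_curation(config.curation) if config.curation else None
        receiver_sum = summarize(receiver, config.screen)
        sender_sum = summarize(sender, config.screen)
        report = build_report(
            receiver_sum, sender_sum, db, curation=curation, config=config.screen
        )
        write_tables(report, outdir)
        if config.gene_sets is not None:
            sets = enr.read_gmt(config.gene_sets)
            universe = {s.gene_id for s in receiver_sum}
            collection = enr.GeneSetCollection(sets=sets, universe=universe)
            for query_name, query in (
                ("receptors", {r.gene_id for r in report.receptors}),
                ("ligands", {s.gene_id for s in report.autocrine_ligands}),
            ):
                if not query:
                    logger.warning("empty %s query; enrichment skipped", query_name)
                    continue
                results = enr.overrepresentation(query, collection, alpha=config.alpha)
                enr.write_results(results, outdir / f"enrichment_{query_name}.tsv")
                logger.info(
                    "%s enrichment: %d/%d sets with p < %g",
                    query_name,
                    sum(r.significant for r in results),
                    len(results),
                    config.alpha,
                )
        if config.make_plots:
            make_figures(report, config)
        logger.info(
            "screen complete: %d receptors, %d pairs, %d orphans, %d autocrine ligands",
            len(report.receptors), len(report.pairs),
            len(report.orphans), len(report.autocrine_ligands),
        )
        return report
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
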