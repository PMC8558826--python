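"""The core screen: expressed receptors, pair table, quadrants, inventories.

Directional convention: the *receiver* tissue (morula) expresses receptors;
the *sender* tissue (endometrium) expresses ligands. The screen

1. identifies receptor genes expressed in the receiver (mean TPM strictly
   above the expressed cutoff, default 2, after curation),
2. joins each receptor to its database ligands and looks the ligand genes
   up in the sender tissue,
3. classifies every (receptor, ligand) pair into one of four quadrants by
   whether each side's mean TPM exceeds the high cutoff (default 10), and
4. inventories orphan receptors (no annotated ligand) and autocrine ligand
   genes expressed by the receiver itself.

Pairs whose ligand is a synthesis-enzyme proxy get quadrants computed on
the proxy gene's expression but are excluded from headline high/high
counts and reported in their own panel: enzyme transcript abundance is a
weak surrogate for small-molecule availability, so those pairs are shown
as receptor inventories rather than co-expression claims.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

from .expression import GeneSummary
from .lr_database import (
    CATEGORIES,
    CurationList,
    LigandRef,
    LRPair,
    apply_curation,
    receptor_genes,
)

logger = logging.getLogger("lratlas")

__all__ = [
    "ScreenConfig",
    "ReceptorRecord",
    "PairResult",
    "AtlasReport",
    "QUADRANTS",
    "identify_receptors",
    "assign_quadrant",
    "build_pair_table",
    "count_quadrants",
    "rank_top",
    "find_orphans",
    "identify_ligand_genes",
    "build_report",
]

#: quadrant labels; first half refers to the receptor, second to the ligand
QUADRANTS = ("high_high", "high_low", "low_high", "low_low")


@dataclass(frozen=True)
class ScreenConfig:
    """Expression cutoffs (TPM) and ranking depth for the screen.

    All comparisons are strict. Defaults: a gene is *expressed* above
    2 TPM, *highly expressed* above 10 TPM (log10 TPM > 1), *very highly
    expressed* above 100 TPM; scatter panels include pairs with receptor
    TPM > 2 and ligand TPM > 1; rankings keep the top 50.
    """

    expressed_cutoff: float = 2.0
    high_cutoff: float = 10.0
    very_high_cutoff: float = 100.0
    ligand_plot_cutoff: float = 1.0
    top_n: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.ligand_plot_cutoff <= self.expressed_cutoff):
            raise ValueError("need 0 < ligand_plot_cutoff <= expressed_cutoff")
        if not (self.expressed_cutoff < self.high_cutoff < self.very_high_cutoff):
            raise ValueError("need expressed_cutoff < high_cutoff < very_high_cutoff")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass(frozen=True)
class ReceptorRecord:
    """An expressed receptor in the receiver tissue."""

    gene_id: str
    mean_tpm: float
    categories: frozenset[str]
    ligands: tuple[LigandRef, ...]
    orphan: bool


@dataclass(frozen=True)
class PairResult:
    """One (receptor, ligand, category) row of the pair table.

    ``ligand_tpm`` is the sender-tissue mean TPM, 0 with
    ``ligand_missing=True`` when the ligand gene is absent from the sender
    table. ``plotted`` applies the figure-inclusion rule (receptor TPM
    above the expressed cutoff and ligand TPM above the ligand plot
    cutoff); quadrant counts ignore it.
    """

    receptor_gene: str
    receptor_tpm: float
    ligand_gene: str
    ligand_kind: str
    molecule: str
    ligand_tpm: float
    ligand_missing: bool
    category: str
    plotted: bool
    quadrant: str


def _summary_map(summaries: Iterable[GeneSummary]) -> dict[str, GeneSummary]:
    return {s.gene_id: s for s in summaries}


def identify_receptors(
    receiver: Sequence[GeneSummary],
    db: list[LRPair],
    curation: CurationList | None,
    config: ScreenConfig,
) -> list[ReceptorRecord]:
    """Expressed receptor genes in the receiver tissue, highest TPM first.

    A gene qualifies when it (a) occurs as a receptor in the database or in
    the curation include list, (b) survives curation, and (c) has receiver
    mean TPM strictly above the expressed cutoff. Force-included genes with
    no database ligands become orphan records.
    """
    candidates = apply_curation(receptor_genes(db), curation)
    by_receptor: dict[str, list[LRPair]] = {}
    for p in db:
        by_receptor.setdefault(p.receptor_gene, []).append(p)
    summaries = _summary_map(receiver)
    records = []
    for gene in candidates:
        s = summaries.get(gene)
        if s is None or not (s.mean_tpm > config.expressed_cutoff):
            continue
        pairs = by_receptor.get(gene, [])
        ligands = tuple(sorted((p.ligand for p in pairs), key=lambda r: r.gene_id))
        cats = frozenset().union(*(p.categories for p in pairs)) if pairs else frozenset()
        records.append(
            ReceptorRecord(
                gene_id=gene,
                mean_tpm=s.mean_tpm,
                categories=cats,
                ligands=ligands,
                orphan=not ligands,
            )
        )
    records.sort(key=lambda r: (-r.mean_tpm, r.gene_id))
    logger.info(
        "identified %d expressed receptor(s) (> %g TPM), %d orphan(s)",
        len(records), config.expressed_cutoff, sum(r.orphan for r in records),
    )
    return records


def assign_quadrant(receptor_tpm: float, ligand_tpm: float, config: ScreenConfig) -> str:
    """Four-way classification against the high cutoff, strict on both axes."""
    if receptor_tpm < 0 or ligand_tpm < 0:
        raise ValueError("TPM values must be non-negative")
    r_high = receptor_tpm > config.high_cutoff
    l_high = ligand_tpm > config.high_cutoff
    return ("high" if r_high else "low") + "_" + ("high" if l_high else "low")


def build_pair_table(
    receptors: Sequence[ReceptorRecord],
    sender: Sequence[GeneSummary],
    db: list[LRPair],
    config: ScreenConfig,
) -> list[PairResult]:
    """One row per (expressed receptor, ligand of that receptor, category).

    Ligand expression is looked up in the sender tissue; a ligand gene
    absent from the sender table contributes 0 TPM with an explicit
    ``ligand_missing`` flag (logged, never dropped). Rows are ordered by
    (category, receptor symbol, ligand symbol).
    """
    sender_map = _summary_map(sender)
    pair_map: dict[tuple[str, str], LRPair] = {
        (p.receptor_gene, p.ligand.gene_id): p for p in db
    }
    missing: set[str] = set()
    rows: list[PairResult] = []
    for rec in receptors:
        for ligand in rec.ligands:
            pair = pair_map[(rec.gene_id, ligand.gene_id)]
            s = sender_map.get(ligand.gene_id)
            if s is None:
                ligand_tpm, ligand_missing = 0.0, True
                missing.add(ligand.gene_id)
            else:
                ligand_tpm, ligand_missing = s.mean_tpm, False
            quadrant = assign_quadrant(rec.mean_tpm, ligand_tpm, config)
            plotted = (
                rec.mean_tpm > config.expressed_cutoff
                and ligand_tpm > config.ligand_plot_cutoff
            )
            for category in sorted(pair.categories):
                rows.append(
                    PairResult(
                        receptor_gene=rec.gene_id,
                        receptor_tpm=rec.mean_tpm,
                        ligand_gene=ligand.gene_id,
                        ligand_kind=ligand.kind,
                        molecule=ligand.molecule,
                        ligand_tpm=ligand_tpm,
                        ligand_missing=ligand_missing,
                        category=category,
                        plotted=plotted,
                        quadrant=quadrant,
                    )
                )
    if missing:
        logger.warning(
            "%d ligand gene(s) absent from sender table (TPM set to 0): %s",
            len(missing), sorted(missing),
        )
    rows.sort(key=lambda r: (r.category, r.receptor_gene, r.ligand_gene))
    return rows


def count_quadrants(
    pairs: Sequence[PairResult],
    category: str,
    plotted_only: bool = False,
    exclude_proxies: bool = False,
) -> dict[str, int]:
    """Quadrant counts over all pairs of one category.

    By default every pair of the category counts, whether or not it passes
    the figure-inclusion rule; ``plotted_only`` restricts to figure rows
    and ``exclude_proxies`` drops synthesis-enzyme-proxy ligands (used for
    the headline high/high tallies).
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    counts = {q: 0 for q in QUADRANTS}
    for p in pairs:
        if p.category != category:
            continue
        if plotted_only and not p.plotted:
            continue
        if exclude_proxies and p.ligand_kind == "synthesis_enzyme_proxy":
            continue
        counts[p.quadrant] += 1
    return counts


def rank_top(items: Sequence, n: int) -> list:
    """Top ``n`` by mean TPM descending, ties broken by gene symbol.

    Accepts :class:`ReceptorRecord` or :class:`GeneSummary` (anything with
    ``mean_tpm`` and ``gene_id``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return sorted(items, key=lambda x: (-x.mean_tpm, x.gene_id))[:n]


def find_orphans(receptors: Sequence[ReceptorRecord]) -> list[ReceptorRecord]:
    """Expressed receptors with no annotated ligand, highest TPM first."""
    return sorted(
        (r for r in receptors if r.orphan), key=lambda r: (-r.mean_tpm, r.gene_id)
    )


def identify_ligand_genes(
    receiver: Sequence[GeneSummary],
    db: list[LRPair],
    config: ScreenConfig,
) -> list[GeneSummary]:
    """Autocrine inventory: protein ligand genes expressed by the receiver.

    Synthesis-enzyme proxies are excluded — the inventory concerns genes
    that themselves encode signaling ligands. Ranked by mean TPM
    descending (symbol ties alphabetical).
    """
    ligand_genes = {p.ligand.gene_id for p in db if p.ligand.kind == "protein"}
    hits = [
        s
        for s in receiver
        if s.gene_id in ligand_genes and s.mean_tpm > config.expressed_cutoff
    ]
    hits.sort(key=lambda s: (-s.mean_tpm, s.gene_id))
    logger.info("found %d expressed autocrine ligand gene(s)", len(hits))
    return hits


@dataclass
class AtlasReport:
    """Full screen output: records, pair tables, counts, rankings, config."""

    config: ScreenConfig
    receptors: list[ReceptorRecord]
    pairs: list[PairResult]
    orphans: list[ReceptorRecord]
    autocrine_ligands: list[GeneSummary]
    top_receptors: list[ReceptorRecord]
    top_autocrine_ligands: list[GeneSummary]
    quadrant_counts: dict[str, dict[str, int]]
    quadrant_counts_plotted: dict[str, dict[str, int]]
    quadrant_counts_headline: dict[str, dict[str, int]]

    def summary_dict(self) -> dict:
        """All counts plus the config echo, JSON-serializable and stable."""
        return {
            "config": asdict(self.config),
            "n_receptors": len(self.receptors),
            "n_orphans": len(self.orphans),
            "n_very_high_receptors": sum(
                r.mean_tpm > self.config.very_high_cutoff for r in self.receptors
            ),
            "n_autocrine_ligands": len(self.autocrine_ligands),
            "n_pairs": len(self.pairs),
            "receptors_per_category": {
                c: len({p.receptor_gene for p in self.pairs if p.category == c})
                for c in sorted(CATEGORIES)
            },
            "quadrant_counts": self.quadrant_counts,
            "quadrant_counts_plotted": self.quadrant_counts_plotted,
            "quadrant_counts_headline": self.quadrant_counts_headline,
            "orphan_genes": [r.gene_id for r in self.orphans],
        }

    def to_json(self) -> str:
        return json.dumps(self.summary_dict(), indent=2, sort_keys=True) + "\n"


def build_report(
    receiver: Sequence[GeneSummary],
    sender: Sequence[GeneSummary],
    db: list[LRPair],
    curation: CurationList | None = None,
    config: ScreenConfig | None = None,
) -> AtlasReport:
    """Run the whole screen and assemble the atlas report."""
    config = config or ScreenConfig()
    receptors = identify_receptors(receiver, db, curation, config)
    pairs = build_pair_table(receptors, sender, db, config)
    orphans = find_orphans(receptors)
    ligands = identify_ligand_genes(receiver, db, config)
    cats = sorted(CATEGORIES)
    return AtlasReport(
        config=config,
        receptors=receptors,
        pairs=pairs,
        orphans=orphans,
        autocrine_ligands=ligands,
        top_receptors=rank_top(receptors, config.top_n),
        top_autocrine_ligands=rank_top(ligands, config.top_n),
        quadrant_counts={c: count_quadrants(pairs, c) for c in cats},
        quadrant_counts_plotted={
            c: count_quadrants(pairs, c, plotted_only=True) for c in cats
        },
        quadrant_counts_headline={
            c: count_quadrants(pairs, c, exclude_proxies=True) for c in cats
        },
    )
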