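"""Ligand-receptor pair database: model, I/O, validation, curation.

A database is a list of directed edges from a ligand gene (or, for
non-protein ligands such as acetylcholine, a synthesis-enzyme proxy gene)
to a receptor gene. Each edge carries one or more signaling categories
(growth factor / WNT, cytokine / chemokine, juxtacrine / matricellular,
small molecule) and a free-text evidence source. Receptor complexes are
represented subunit-by-subunit: each subunit is an independent receptor
gene, so one ligand may map to several receptor rows and one receptor may
appear under several categories.

Manual curation — the removal of genes that are not functional receptors,
or the forced inclusion of receptors absent from the pair atlas (these
become orphan receptors) — is an explicit, versionable TSV input rather
than an ad hoc editing step.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

logger = logging.getLogger("lratlas")

__all__ = [
    "CATEGORIES",
    "LigandRef",
    "LRPair",
    "CurationList",
    "DatabaseError",
    "load_pair_db",
    "write_pair_db",
    "load_curation",
    "apply_curation",
    "ligands_of",
    "receptor_genes",
    "default_pair_db",
]

#: fixed category vocabulary; "small_molecule" pairs must use enzyme proxies
CATEGORIES = frozenset(
    {
        "growth_factor_wnt",
        "cytokine_chemokine",
        "juxtacrine_matricellular",
        "small_molecule",
    }
)

PAIR_DB_COLUMNS = ["receptor", "ligand", "ligand_kind", "molecule", "categories", "source"]


class DatabaseError(ValueError):
    """Raised for invalid pair-database or curation content."""


@dataclass(frozen=True)
class LigandRef:
    """A ligand gene, or an enzyme gene standing in for a non-protein ligand.

    When ``kind`` is ``synthesis_enzyme_proxy``, ``molecule`` names the
    signaling molecule the enzyme produces (e.g. "acetylcholine") and the
    gene's expression is used as a surrogate for ligand availability.
    """

    gene_id: str
    kind: Literal["protein", "synthesis_enzyme_proxy"] = "protein"
    molecule: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise DatabaseError("ligand gene symbol must be non-empty")
        if self.kind not in ("protein", "synthesis_enzyme_proxy"):
            raise DatabaseError(f"unknown ligand kind {self.kind!r}")
        if self.kind == "synthesis_enzyme_proxy" and not self.molecule:
            raise DatabaseError(
                f"proxy ligand {self.gene_id} must name its molecule"
            )
        if self.kind == "protein" and self.molecule:
            raise DatabaseError(
                f"protein ligand {self.gene_id} must not carry a molecule name"
            )


@dataclass(frozen=True)
class LRPair:
    """One ligand-gene -> receptor-gene edge with categories and evidence."""

    receptor_gene: str
    ligand: LigandRef
    categories: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.receptor_gene:
            raise DatabaseError("receptor gene symbol must be non-empty")
        if not self.categories:
            raise DatabaseError(
                f"pair {self.ligand.gene_id}->{self.receptor_gene} has no category"
            )
        unknown = set(self.categories) - CATEGORIES
        if unknown:
            raise DatabaseError(
                f"unknown category token(s) {sorted(unknown)} for pair "
                f"{self.ligand.gene_id}->{self.receptor_gene}"
            )
        if "small_molecule" in self.categories and self.ligand.kind != "synthesis_enzyme_proxy":
            raise DatabaseError(
                f"small_molecule pair {self.ligand.gene_id}->{self.receptor_gene} "
                "requires a synthesis-enzyme proxy ligand"
            )


@dataclass
class CurationList:
    """Explicit include/exclude receptor lists replacing manual scrutiny."""

    include: set[str] = field(default_factory=set)
    exclude: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.include = {g.strip().upper() for g in self.include}
        self.exclude = {g.strip().upper() for g in self.exclude}
        overlap = self.include & self.exclude
        if overlap:
            raise DatabaseError(
                f"curation include/exclude overlap: {sorted(overlap)}"
            )


def _validate_db(pairs: list[LRPair]) -> list[LRPair]:
    seen: set[tuple[str, str]] = set()
    for p in pairs:
        key = (p.receptor_gene, p.ligand.gene_id)
        if key in seen:
            raise DatabaseError(
                f"duplicate pair {p.ligand.gene_id}->{p.receptor_gene}"
            )
        seen.add(key)
    return pairs


def load_pair_db(path) -> list[LRPair]:
    """Read and validate a pair-database TSV.

    Columns: ``receptor``, ``ligand``, ``ligand_kind``, ``molecule``,
    ``categories`` (";"-separated tokens), ``source``. Symbols are
    uppercased; every invariant violation raises :class:`DatabaseError`
    with the offending line number.
    """
    pairs: list[LRPair] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise DatabaseError(f"{path}: empty file, header required")
        missing = set(PAIR_DB_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise DatabaseError(f"{path}: missing column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                ligand = LigandRef(
                    gene_id=(row["ligand"] or "").strip().upper(),
                    kind=(row["ligand_kind"] or "protein").strip() or "protein",
                    molecule=(row["molecule"] or "").strip(),
                )
                cats = frozenset(
                    t.strip() for t in (row["categories"] or "").split(";") if t.strip()
                )
                pair = LRPair(
                    receptor_gene=(row["receptor"] or "").strip().upper(),
                    ligand=ligand,
                    categories=cats,
                    source=(row["source"] or "").strip(),
                )
            except DatabaseError as exc:
                raise DatabaseError(f"{path}: line {lineno}: {exc}") from None
            key = (pair.receptor_gene, pair.ligand.gene_id)
            if key in seen:
                raise DatabaseError(
                    f"{path}: line {lineno}: duplicate pair "
                    f"{pair.ligand.gene_id}->{pair.receptor_gene}"
                )
            seen.add(key)
            pairs.append(pair)
    logger.info(
        "loaded %d ligand-receptor pairs (%d receptors) from %s",
        len(pairs), len({p.receptor_gene for p in pairs}), path,
    )
    return pairs


def write_pair_db(pairs: Iterable[LRPair], path) -> None:
    """Write a validated pair list back to the TSV dialect (round-trips)."""
    pairs = _validate_db(list(pairs))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PAIR_DB_COLUMNS)
        for p in pairs:
            writer.writerow(
                [
                    p.receptor_gene,
                    p.ligand.gene_id,
                    p.ligand.kind,
                    p.ligand.molecule,
                    ";".join(sorted(p.categories)),
                    p.source,
                ]
            )


def load_curation(path) -> CurationList:
    """Read a curation TSV with columns ``gene``, ``action``, ``reason``."""
    include: set[str] = set()
    exclude: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"gene", "action"} <= set(reader.fieldnames):
            raise DatabaseError(f"{path}: curation file needs 'gene' and 'action' columns")
        for lineno, row in enumerate(reader, start=2):
            gene = (row["gene"] or "").strip().upper()
            action = (row["action"] or "").strip().lower()
            if not gene:
                raise DatabaseError(f"{path}: line {lineno}: empty gene symbol")
            if action == "include":
                include.add(gene)
            elif action == "exclude":
                exclude.add(gene)
            else:
                raise DatabaseError(
                    f"{path}: line {lineno}: action must be include|exclude, got {action!r}"
                )
    return CurationList(include=include, exclude=exclude)


def apply_curation(receptor_genes: set[str], curation: CurationList | None) -> set[str]:
    """Apply include/exclude curation to a receptor symbol set.

    Returns ``(receptor_genes \\ exclude) | include``. Curation gates set
    membership only; expression cutoffs are applied separately, so a forced
    include below the expressed cutoff still drops out of the screen.
    """
    if curation is None:
        return set(receptor_genes)
    if curation.include & curation.exclude:  # defensive; ctor also checks
        raise DatabaseError("curation include/exclude overlap")
    kept = (set(receptor_genes) - curation.exclude) | curation.include
    removed = set(receptor_genes) & curation.exclude
    if removed:
        logger.info("curation removed %d receptor(s): %s", len(removed), sorted(removed))
    added = curation.include - set(receptor_genes)
    if added:
        logger.info("curation force-included %d receptor(s): %s", len(added), sorted(added))
    return kept


def ligands_of(db: list[LRPair], receptor_gene: str) -> list[LigandRef]:
    """All ligands paired with a receptor, sorted by ligand symbol.

    Unknown receptors yield an empty list (orphan receptors by definition
    have no rows in the database).
    """
    receptor_gene = receptor_gene.strip().upper()
    refs = [p.ligand for p in db if p.receptor_gene == receptor_gene]
    return sorted(refs, key=lambda r: r.gene_id)


def receptor_genes(db: list[LRPair]) -> set[str]:
    """The set of receptor symbols appearing in the database."""
    return {p.receptor_gene for p in db}


def default_pair_db() -> list[LRPair]:
    """The shipped literature-derived fixture database (~60 named pairs).

    A small bovine morula / endometrium signaling set; the full FANTOM5
    atlas of human ligand-receptor pairs is a user-supplied input, not
    vendored here.
    """
    with resources.as_file(
        resources.files("lratlas.data").joinpath("default_pairs.tsv")
    ) as p:
        return load_pair_db(p)
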