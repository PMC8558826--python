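"""Expression-level preprocessing: TPM computation, replicate averaging, tiers.

The screen consumes per-gene mean TPM for each tissue. Inputs arrive either
as TPM tables (the usual case; upstream quantifiers such as isoEM or
StringTie already produce TPM) or as read-count tables with transcript
lengths, in which case TPM is computed here with the standard definition

    tpm_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j)

per sample, where ``c_i`` is the read count and ``l_i`` the transcript
length in kilobases. Replicate averaging is the unweighted arithmetic mean.
Expression tiers use strict inequalities throughout: a gene exactly at a
cutoff falls into the lower tier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger("lratlas")

__all__ = [
    "CountTable",
    "ExpressionMatrix",
    "GeneSummary",
    "ExpressionError",
    "compute_tpm",
    "load_expression",
    "summarize",
    "summaries_to_frame",
]

#: relative tolerance for the per-sample TPM column-sum invariant
TPM_COLSUM_RTOL = 1e-9

DuplicatePolicy = Literal["error", "sum", "max"]


class ExpressionError(ValueError):
    """Raised for invalid expression inputs (parse or validation failures)."""


def _normalize_symbols(index: pd.Index) -> pd.Index:
    return pd.Index([str(g).strip().upper() for g in index], name="gene")


@dataclass
class CountTable:
    """Read counts per gene with transcript lengths.

    ``counts`` is a genes x samples DataFrame of non-negative values;
    ``length_kb`` holds transcript lengths in kilobases (> 0), aligned to
    the same gene index. Gene symbols are uppercase-normalized on
    construction.
    """

    counts: pd.DataFrame
    length_kb: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.counts.index = _normalize_symbols(self.counts.index)
        self.length_kb = pd.Series(
            np.asarray(self.length_kb, dtype=float), index=self.counts.index
        )
        if self.counts.shape[1] < 1:
            raise ExpressionError("count table needs at least one sample column")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate gene symbols after normalization: {dups}")
        values = self.counts.to_numpy(dtype=float)
        if not np.isfinite(values).all() or (values < 0).any():
            raise ExpressionError("counts must be finite and non-negative")
        if not (self.length_kb > 0).all():
            bad = self.length_kb.index[~(self.length_kb > 0)].tolist()
            raise ExpressionError(f"non-positive transcript length for: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.counts.columns]


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM for one tissue.

    ``provenance`` records whether TPM was computed here from counts
    (``from_counts``; column sums equal 1e6 within relative tolerance) or
    supplied directly (``supplied_tpm``; never renormalized).
    """

    tpm: pd.DataFrame
    provenance: Literal["from_counts", "supplied_tpm"] = "supplied_tpm"

    def __post_init__(self) -> None:
        self.tpm = self.tpm.copy()
        self.tpm.index = _normalize_symbols(self.tpm.index)
        if self.tpm.shape[1] < 1:
            raise ExpressionError("expression matrix needs at least one sample column")
        if self.tpm.index.has_duplicates:
            dups = self.tpm.index[self.tpm.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate gene symbols after normalization: {dups}")
        values = self.tpm.to_numpy(dtype=float)
        if not np.isfinite(values).all() or (values < 0).any():
            raise ExpressionError("TPM values must be finite and non-negative")
        if self.provenance == "from_counts":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1e6, rtol=TPM_COLSUM_RTOL):
                raise ExpressionError(
                    f"from_counts TPM columns must sum to 1e6; got {sums}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.tpm.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)


@dataclass(frozen=True)
class GeneSummary:
    """Replicate-averaged expression of one gene with tier flags.

    Flags are strict: ``expressed`` means mean TPM > expressed_cutoff
    (default 2), ``high`` > high_cutoff (default 10), ``very_high`` >
    very_high_cutoff (default 100).
    """

    gene_id: str
    mean_tpm: float
    n_samples: int
    expressed: bool
    high: bool
    very_high: bool


def compute_tpm(counts: CountTable) -> ExpressionMatrix:
    """Convert read counts to TPM, per sample.

    Each sample's length-normalized count rates are rescaled to sum to one
    million. A sample whose counts are all zero has no defined TPM and
    raises :class:`ExpressionError` naming the sample.
    """
    rates = counts.counts.div(counts.length_kb, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ExpressionError(
            f"sample(s) with all-zero counts, TPM undefined: {list(zero.index)}"
        )
    tpm = rates.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm=tpm, provenance="from_counts")


def load_expression(
    path,
    mode: Literal["tpm", "counts"] = "tpm",
    duplicate_policy: DuplicatePolicy = "error",
) -> ExpressionMatrix | CountTable:
    """Read an expression TSV.

    Layout: first column ``gene``; in counts mode a ``length_kb`` column
    follows; remaining columns are samples. Duplicate symbols (after
    uppercasing) follow ``duplicate_policy``: ``error`` (default), ``sum``
    (counts mode) or ``max`` (TPM mode), with a logged notice.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ExpressionError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0 or df.columns[0].lower().startswith("unnamed"):
        raise ExpressionError(f"{path}: missing header row")
    df = df.rename(columns={df.columns[0]: "gene"})
    df["gene"] = df["gene"].astype(str).str.strip().str.upper()

    if mode == "counts":
        if "length_kb" not in df.columns:
            raise ExpressionError(
                f"{path}: counts mode requires a 'length_kb' column"
            )
        sample_cols = [c for c in df.columns if c not in ("gene", "length_kb")]
    elif mode == "tpm":
        sample_cols = [c for c in df.columns if c != "gene"]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not sample_cols:
        raise ExpressionError(f"{path}: no sample columns")

    numeric_cols = sample_cols + (["length_kb"] if mode == "counts" else [])
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad) > 0:
            # +2: one for the header line, one for 0- vs 1-based numbering
            raise ExpressionError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r} at line {int(bad[0]) + 2}"
            )
        if converted.isna().any():
            raise ExpressionError(f"{path}: empty cell in column {col!r}")
        df[col] = converted

    if df["gene"].duplicated().any():
        dup_genes = sorted(df.loc[df["gene"].duplicated(), "gene"].unique())
        first_line = int(df.index[df["gene"].duplicated()][0]) + 2
        if duplicate_policy == "error":
            raise ExpressionError(
                f"{path}: duplicate gene symbol(s) {dup_genes} "
                f"(first repeat at line {first_line})"
            )
        if duplicate_policy == "sum":
            if mode != "counts":
                raise ExpressionError("duplicate policy 'sum' applies to counts mode")
            logger.warning("summing %d duplicate symbol(s): %s", len(dup_genes), dup_genes)
            agg = {c: "sum" for c in sample_cols}
            agg["length_kb"] = "first"
            df = df.groupby("gene", as_index=False).agg(agg)
        elif duplicate_policy == "max":
            if mode != "tpm":
                raise ExpressionError("duplicate policy 'max' applies to TPM mode")
            logger.warning(
                "keeping per-sample max over %d duplicate symbol(s): %s",
                len(dup_genes), dup_genes,
            )
            df = df.groupby("gene", as_index=False).max()
        else:
            raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")

    df = df.set_index("gene")
    if mode == "counts":
        return CountTable(counts=df[sample_cols], length_kb=df["length_kb"])
    return ExpressionMatrix(tpm=df[sample_cols], provenance="supplied_tpm")


def summarize(matrix: ExpressionMatrix, config) -> list[GeneSummary]:
    """Average replicates and flag expression tiers for every gene.

    ``config`` is a :class:`~lratlas.screen.ScreenConfig` (or anything with
    ``expressed_cutoff``, ``high_cutoff``, ``very_high_cutoff``). The mean
    is the unweighted arithmetic mean across all samples.
    """
    if matrix.tpm.shape[0] == 0:
        raise ExpressionError("cannot summarize an empty expression matrix")
    n = matrix.tpm.shape[1]
    logger.info("averaging %d replicate sample(s) for %d genes", n, matrix.tpm.shape[0])
    means = matrix.tpm.mean(axis=1)
    return [
        GeneSummary(
            gene_id=gene,
            mean_tpm=float(m),
            n_samples=n,
            expressed=bool(m > config.expressed_cutoff),
            high=bool(m > config.high_cutoff),
            very_high=bool(m > config.very_high_cutoff),
        )
        for gene, m in means.items()
    ]


def summaries_to_frame(summaries: list[GeneSummary]) -> pd.DataFrame:
    """Tabulate summaries (index: gene symbol)."""
    return pd.DataFrame(
        {
            "mean_tpm": [s.mean_tpm for s in summaries],
            "n_samples": [s.n_samples for s in summaries],
            "expressed": [s.expressed for s in summaries],
            "high": [s.high for s in summaries],
            "very_high": [s.very_high for s in summaries],
        },
        index=pd.Index([s.gene_id for s in summaries], name="gene"),
    )
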