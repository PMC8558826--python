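"""Synthetic paired-tissue datasets with planted ground truth.

The generator emulates the statistical shape of the real screen inputs: a
receiver tissue (morula analogue, 4 replicates) and a sender tissue
(endometrium analogue, 5 replicates) over a shared universe of ~10-20k
gene symbols whose true mean TPM is heavy-tailed (log10-normal, most genes
below the 2-TPM expressed cutoff), plus a pair database with multi-ligand
receptors, shared ligands, synthesis-enzyme proxies and orphan receptors.

A configurable number of high/high pairs is *planted*: their receptor's
receiver mean and ligand's sender mean are placed at least ``margin``-fold
above the high cutoff, while every other gene on the relevant axis is
capped ``margin``-fold below it. Replicates add multiplicative log-normal
noise. As long as sample means stay within a factor ``margin`` of truth,
the screen must recover exactly the planted set — this is the package's
end-to-end correctness probe.

TPM is simulated directly on the TPM scale (no per-sample renormalization)
so that planted margins are exact; a Poisson counts mode is provided to
exercise the counts-to-TPM path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .lr_database import CurationList, LigandRef, LRPair, write_pair_db
from .screen import ScreenConfig

__all__ = ["SimConfig", "SyntheticTruth", "SyntheticDataset", "generate", "write_dataset"]

PROTEIN_CATEGORIES = (
    "growth_factor_wnt",
    "cytokine_chemokine",
    "juxtacrine_matricellular",
)

MOLECULES = (
    "acetylcholine", "histamine", "serotonin", "retinoic acid",
    "lysophosphatidic acid", "prostaglandin", "bile acid", "oxysterol",
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults mirror the study conditions.

    ``margin`` is the multiplicative separation of planted (and capped)
    true means from the high cutoff; ``noise_sigma`` is the s.d. of the
    log10-normal replicate noise; ``mu``/``sigma`` parametrize the log10
    background TPM distribution.
    """

    n_genes: int = 12_000
    n_receptor_genes: int = 160
    ligands_per_receptor: tuple[int, int] = (1, 4)
    n_orphans: int = 15
    n_proxy_pairs: int = 15
    n_planted_high_high: int = 20
    margin: float = 2.0
    mu: float = -0.5
    sigma: float = 1.0
    n_receiver_samples: int = 4
    n_sender_samples: int = 5
    noise_sigma: float = 0.1
    n_missing_ligands: int = 0
    multi_category_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 1:
            raise ValueError("margin must be > 1")
        for name in (
            "n_genes", "n_receptor_genes", "n_orphans", "n_proxy_pairs",
            "n_planted_high_high", "n_missing_ligands",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.ligands_per_receptor
        if not (1 <= lo <= hi):
            raise ValueError("ligands_per_receptor must satisfy 1 <= lo <= hi")
        if self.n_receiver_samples < 1 or self.n_sender_samples < 1:
            raise ValueError("need at least one replicate per tissue")


@dataclass
class SyntheticTruth:
    """Planted signal plus expected screen output on noise-free data."""

    planted_pairs: list[dict]
    orphan_receptors: list[str]
    true_receiver_mean: dict[str, float]
    true_sender_mean: dict[str, float]
    expected: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_pairs": self.planted_pairs,
                "orphan_receptors": self.orphan_receptors,
                "expected": self.expected,
            },
            indent=2,
            sort_keys=True,
        ) + "\n"


@dataclass
class SyntheticDataset:
    receiver: ExpressionMatrix
    sender: ExpressionMatrix
    db: list[LRPair]
    curation: CurationList
    truth: SyntheticTruth
    config: SimConfig


def _cap_below(values: np.ndarray, cap: float, rng: np.random.Generator) -> np.ndarray:
    """Force values under ``cap`` by redrawing offenders uniformly in log10."""
    out = values.copy()
    over = out >= cap
    if over.any():
        # land well inside (0, cap): log10-uniform over one decade below cap
        out[over] = cap * 10 ** rng.uniform(-1.0, -0.05, size=int(over.sum()))
    return out


def _avoid_band(
    values: np.ndarray, cutoff: float, margin: float, rng: np.random.Generator
) -> np.ndarray:
    """Push values out of (cutoff/margin, cutoff*margin) to the nearest side.

    Keeps every true mean margin-separated from the cutoff so that strict
    threshold decisions are stable under the replicate noise model.
    """
    out = values.copy()
    in_band = (out > cutoff / margin) & (out < cutoff * margin)
    below = in_band & (out <= cutoff)
    above = in_band & (out > cutoff)
    if below.any():
        out[below] = cutoff / margin * 10 ** rng.uniform(-0.08, -0.01, size=int(below.sum()))
    if above.any():
        out[above] = cutoff * margin * 10 ** rng.uniform(0.01, 0.08, size=int(above.sum()))
    return out


def generate(config: SimConfig) -> SyntheticDataset:
    """Build receiver/sender matrices, pair DB, curation and ground truth.

    Deterministic given ``config.seed``. Raises ``ValueError`` when the
    requested planting is infeasible (more planted pairs than disjoint
    receptor-ligand pairs available).
    """
    rng = np.random.default_rng(config.seed)
    screen_cfg = ScreenConfig()
    high, expressed = screen_cfg.high_cutoff, screen_cfg.expressed_cutoff
    cap = high / config.margin
    if expressed * config.margin >= cap:
        raise ValueError(
            "infeasible margin: the expressed- and high-cutoff separation "
            "bands overlap; need margin^2 < high_cutoff / expressed_cutoff"
        )

    receptors = [f"RCP{i:04d}" for i in range(config.n_receptor_genes)]
    orphans = [f"ORP{i:04d}" for i in range(config.n_orphans)]
    slot_counts = rng.integers(
        config.ligands_per_receptor[0],
        config.ligands_per_receptor[1] + 1,
        size=config.n_receptor_genes,
    )
    n_slots = int(slot_counts.sum())
    # ligand pool smaller than the slot count so some ligands are shared
    pool_size = max(1, int(0.7 * n_slots)) if n_slots else 0
    ligand_pool = [f"LIG{i:04d}" for i in range(pool_size)]
    enzymes = [f"ENZ{i:04d}" for i in range(config.n_proxy_pairs)]

    # --- pair database -------------------------------------------------
    pairs: list[LRPair] = []
    seen: set[tuple[str, str]] = set()
    for receptor, k in zip(receptors, slot_counts):
        chosen = rng.choice(pool_size, size=min(int(k), pool_size), replace=False)
        for idx in sorted(int(i) for i in chosen):
            ligand = ligand_pool[idx]
            if (receptor, ligand) in seen:
                continue
            seen.add((receptor, ligand))
            cats = {str(rng.choice(PROTEIN_CATEGORIES))}
            if rng.random() < config.multi_category_prob:
                cats.add(str(rng.choice(PROTEIN_CATEGORIES)))
            pairs.append(
                LRPair(
                    receptor_gene=receptor,
                    ligand=LigandRef(gene_id=ligand),
                    categories=frozenset(cats),
                    source="synthetic",
                )
            )
    # proxy pairs attach enzymes to a subset of receptors
    if config.n_proxy_pairs:
        proxy_receptors = rng.choice(
            config.n_receptor_genes, size=min(config.n_proxy_pairs, config.n_receptor_genes),
            replace=False,
        )
        for enz, ridx in zip(enzymes, sorted(int(i) for i in proxy_receptors)):
            pairs.append(
                LRPair(
                    receptor_gene=receptors[ridx],
                    ligand=LigandRef(
                        gene_id=enz,
                        kind="synthesis_enzyme_proxy",
                        molecule=str(rng.choice(MOLECULES)),
                    ),
                    categories=frozenset({"small_molecule"}),
                    source="synthetic",
                )
            )

    # --- plant high/high pairs -----------------------------------------
    protein_pairs = [p for p in pairs if p.ligand.kind == "protein"]
    if config.n_planted_high_high > len(protein_pairs):
        raise ValueError(
            f"cannot plant {config.n_planted_high_high} high/high pairs in a "
            f"database with {len(protein_pairs)} protein pairs"
        )
    edge_set = {(p.receptor_gene, p.ligand.gene_id) for p in protein_pairs}
    order = rng.permutation(len(protein_pairs))
    planted: list[LRPair] = []
    planted_receptors: set[str] = set()
    planted_ligands: set[str] = set()
    for idx in order:
        if len(planted) == config.n_planted_high_high:
            break
        p = protein_pairs[int(idx)]
        r, l = p.receptor_gene, p.ligand.gene_id
        if r in planted_receptors or l in planted_ligands:
            continue
        # closure check: planting (r, l) must not turn any OTHER edge
        # between planted receptors and planted ligands into high/high
        if any((r, pl) in edge_set for pl in planted_ligands):
            continue
        if any((pr, l) in edge_set for pr in planted_receptors):
            continue
        planted.append(p)
        planted_receptors.add(r)
        planted_ligands.add(l)
    if len(planted) < config.n_planted_high_high:
        raise ValueError(
            "infeasible config: could not select disjoint planted pairs; "
            "reduce n_planted_high_high or increase the database size"
        )

    # --- true mean TPM ---------------------------------------------------
    n_named = len(receptors) + len(orphans) + len(ligand_pool) + len(enzymes)
    if config.n_genes < n_named:
        raise ValueError(f"n_genes={config.n_genes} < {n_named} named genes")
    background = [f"GEN{i:05d}" for i in range(config.n_genes - n_named)]
    genes = receptors + orphans + ligand_pool + enzymes + background
    gene_index = pd.Index(genes, name="gene")

    def draw_background(n: int) -> np.ndarray:
        return 10 ** rng.normal(config.mu, config.sigma, size=n)

    receiver_mean = pd.Series(draw_background(len(genes)), index=gene_index)
    sender_mean = pd.Series(draw_background(len(genes)), index=gene_index)

    # receptor axis (receiver): planted high, everything else capped low and
    # margin-separated from the expressed cutoff so tier calls survive noise
    receiver_mean.loc[receptors] = _avoid_band(
        _cap_below(receiver_mean.loc[receptors].to_numpy(), cap, rng),
        expressed, config.margin, rng,
    )
    # autocrine inventory stability: receiver-side ligand/enzyme means also
    # stay margin-separated from the expressed cutoff
    receiver_mean.loc[ligand_pool + enzymes] = _avoid_band(
        receiver_mean.loc[ligand_pool + enzymes].to_numpy(),
        expressed, config.margin, rng,
    )
    plant_r = sorted(planted_receptors)
    receiver_mean.loc[plant_r] = high * config.margin * 10 ** rng.uniform(
        0.05, 1.0, size=len(plant_r)
    )
    # orphans: reliably expressed but never high
    receiver_mean.loc[orphans] = 10 ** rng.uniform(
        np.log10(expressed * config.margin), np.log10(cap * 0.9), size=len(orphans)
    )
    # ligand/proxy axis (sender): planted high, everything else capped low
    # and margin-separated from the plot-inclusion cutoff
    sender_mean.loc[ligand_pool + enzymes] = _avoid_band(
        _cap_below(sender_mean.loc[ligand_pool + enzymes].to_numpy(), cap, rng),
        screen_cfg.ligand_plot_cutoff, config.margin, rng,
    )
    plant_l = sorted(planted_ligands)
    sender_mean.loc[plant_l] = high * config.margin * 10 ** rng.uniform(
        0.05, 1.0, size=len(plant_l)
    )

    # --- replicates -------------------------------------------------------
    def replicate(true_mean: pd.Series, n: int, prefix: str) -> pd.DataFrame:
        noise = 10 ** rng.normal(0.0, config.noise_sigma, size=(len(true_mean), n))
        return pd.DataFrame(
            true_mean.to_numpy()[:, None] * noise,
            index=true_mean.index,
            columns=[f"{prefix}{i + 1}" for i in range(n)],
        )

    receiver_tpm = replicate(receiver_mean, config.n_receiver_samples, "receiver_")
    sender_df = replicate(sender_mean, config.n_sender_samples, "sender_")
    if config.n_missing_ligands:
        # prefer ligands of planted (hence expressed) receptors so the
        # missing-ligand path is actually exercised in the pair table
        attached = {
            p.ligand.gene_id for p in pairs if p.receptor_gene in planted_receptors
        }
        droppable = sorted(
            (l for l in ligand_pool if l not in planted_ligands),
            key=lambda l: (l not in attached, l),
        )
        drop = droppable[: config.n_missing_ligands]
        sender_df = sender_df.drop(index=drop)

    receiver = ExpressionMatrix(tpm=receiver_tpm, provenance="supplied_tpm")
    sender = ExpressionMatrix(tpm=sender_df, provenance="supplied_tpm")
    curation = CurationList(include=set(orphans))

    # --- ground truth: screen rules applied to the true means -----------
    from .expression import GeneSummary  # local import avoids cycle at module load
    from .screen import build_report

    def true_summaries(means: pd.Series, n: int) -> list[GeneSummary]:
        return [
            GeneSummary(
                gene_id=g,
                mean_tpm=float(m),
                n_samples=n,
                expressed=bool(m > screen_cfg.expressed_cutoff),
                high=bool(m > screen_cfg.high_cutoff),
                very_high=bool(m > screen_cfg.very_high_cutoff),
            )
            for g, m in means.items()
        ]

    truth_report = build_report(
        true_summaries(receiver_mean, config.n_receiver_samples),
        true_summaries(
            sender_mean.loc[sender_df.index], config.n_sender_samples
        ),
        pairs,
        curation=curation,
        config=screen_cfg,
    )
    truth = SyntheticTruth(
        planted_pairs=[
            {
                "receptor": p.receptor_gene,
                "ligand": p.ligand.gene_id,
                "categories": sorted(p.categories),
                "quadrant": "high_high",
            }
            for p in sorted(planted, key=lambda p: (p.receptor_gene, p.ligand.gene_id))
        ],
        orphan_receptors=sorted(orphans),
        true_receiver_mean={g: float(v) for g, v in receiver_mean.items()},
        true_sender_mean={g: float(v) for g, v in sender_mean.items()},
        expected=truth_report.summary_dict(),
    )
    return SyntheticDataset(
        receiver=receiver,
        sender=sender,
        db=pairs,
        curation=curation,
        truth=truth,
        config=config,
    )


def poisson_counts(
    matrix: ExpressionMatrix,
    depth: int = 5_000_000,
    length_kb_range: tuple[float, float] = (0.5, 8.0),
    seed: int = 0,
):
    """Counts-mode companion: Poisson reads from TPM at a given depth.

    Expected count of gene i in a sample is depth * tpm_i * l_i / sum_j
    tpm_j * l_j, so recomputing TPM from these counts recovers the input
    in expectation. Returns a :class:`~lratlas.expression.CountTable`.
    """
    from .expression import CountTable

    rng = np.random.default_rng(seed)
    lengths = pd.Series(
        rng.uniform(*length_kb_range, size=matrix.tpm.shape[0]), index=matrix.tpm.index
    )
    weighted = matrix.tpm.mul(lengths, axis=0)
    expected = weighted.div(weighted.sum(axis=0), axis=1) * depth
    counts = pd.DataFrame(
        rng.poisson(expected.to_numpy()),
        index=matrix.tpm.index,
        columns=matrix.tpm.columns,
    )
    return CountTable(counts=counts, length_kb=lengths)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write receiver.tsv, sender.tsv, pairs.tsv, curation.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "receiver": outdir / "receiver.tsv",
        "sender": outdir / "sender.tsv",
        "pairs": outdir / "pairs.tsv",
        "curation": outdir / "curation.tsv",
        "truth": outdir / "truth.json",
    }
    dataset.receiver.tpm.to_csv(paths["receiver"], sep="\t", float_format="%.6g")
    dataset.sender.tpm.to_csv(paths["sender"], sep="\t", float_format="%.6g")
    write_pair_db(dataset.db, paths["pairs"])
    with open(paths["curation"], "w", encoding="utf-8") as fh:
        fh.write("gene\taction\treason\n")
        for g in sorted(dataset.curation.include):
            fh.write(f"{g}\tinclude\tsynthetic orphan receptor\n")
        for g in sorted(dataset.curation.exclude):
            fh.write(f"{g}\texclude\tsynthetic exclusion\n")
    paths["truth"].write_text(dataset.truth.to_json(), encoding="utf-8")
    return paths
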