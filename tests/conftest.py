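import numpy as np
import pandas as pd
import pytest

from lratlas import (
    ExpressionMatrix,
    GeneSummary,
    LigandRef,
    LRPair,
    ScreenConfig,
)


def make_summary(gene, mean_tpm, config=None, n_samples=4):
    config = config or ScreenConfig()
    return GeneSummary(
        gene_id=gene,
        mean_tpm=float(mean_tpm),
        n_samples=n_samples,
        expressed=mean_tpm > config.expressed_cutoff,
        high=mean_tpm > config.high_cutoff,
        very_high=mean_tpm > config.very_high_cutoff,
    )


def make_pair(receptor, ligand, categories=("growth_factor_wnt",), kind="protein", molecule=""):
    return LRPair(
        receptor_gene=receptor,
        ligand=LigandRef(gene_id=ligand, kind=kind, molecule=molecule),
        categories=frozenset(categories),
        source="test",
    )


@pytest.fixture
def config():
    return ScreenConfig()


@pytest.fixture
def toy_db():
    """Small database: multi-ligand receptor, shared ligand, a proxy pair."""
    return [
        make_pair("SDC4", "MDK"),
        make_pair("SDC4", "CXCL10", categories=("cytokine_chemokine",)),
        make_pair("SDC4", "CCL5", categories=("cytokine_chemokine",)),
        make_pair("ITGB1", "MDK"),
        make_pair("ITGB1", "VEGFA", categories=("growth_factor_wnt", "juxtacrine_matricellular")),
        make_pair("CD48", "IL18", categories=("cytokine_chemokine",)),
        make_pair(
            "CHRNB2", "ACHE",
            categories=("small_molecule",),
            kind="synthesis_enzyme_proxy",
            molecule="acetylcholine",
        ),
    ]


@pytest.fixture
def tpm_matrix():
    rng = np.random.default_rng(7)
    genes = [f"G{i:03d}" for i in range(30)]
    return ExpressionMatrix(
        tpm=pd.DataFrame(
            10 ** rng.normal(0, 1, size=(30, 4)),
            index=pd.Index(genes, name="gene"),
            columns=["s1", "s2", "s3", "s4"],
        ),
        provenance="supplied_tpm",
    )


def write_tsv(path, df):
    df.to_csv(path, sep="\t")
    return path
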