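# Methods

## Model and procedure

The screen treats cell–cell communication as a directed bipartite problem:
receptors live in a *receiver* tissue, ligands in a *sender* tissue, and
edges come from a curated ligand–receptor database. No statistical model of
co-expression is fitted; the method is a deterministic threshold
classification on replicate-averaged TPM, which is appropriate at the
sample sizes involved (single-digit replicates per tissue) and makes every
reported count exactly reproducible from the emitted tables.

Assumptions worth stating explicitly:

- Transcript abundance is used as a surrogate for both receptor protein
  presence (receiver) and ligand availability (sender). This is the usual
  caveat of expression-based interaction screens; it is weakest for
  synthesis-enzyme proxies, where an enzyme transcript stands in for a
  small molecule — which is why proxy pairs are segregated into their own
  panel and never enter headline high/high counts.
- Gene symbols are matched case-insensitively by uppercasing, with no
  ortholog mapping: a bovine expression table is joined to a human-derived
  pair atlas purely by symbol. Symbols missing from the sender table are
  kept with ligand TPM 0 and an explicit `ligand_missing` flag.
- Database content is the user's responsibility. The shipped default
  database is a small literature-derived set of named bovine
  morula/endometrium signaling pairs useful for demos and tests; it
  includes one deliberately preserved assignment (ACHE as the
  acetylcholine proxy for CHRNB2) whose enzymology is questionable, with a
  note in its source column. Real screens should supply the full pair
  atlas of their choice.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `expressed_cutoff` | 2 | TPM | conventional detection floor for bulk TPM; gates receptor/ligand membership |
| `high_cutoff` | 10 | TPM | "highly expressed" (log10 TPM > 1); defines the quadrants |
| `very_high_cutoff` | 100 | TPM | a top tier for headline receptors |
| `ligand_plot_cutoff` | 1 | TPM | scatter inclusion floor for the ligand axis; also keeps log axes finite |
| `top_n` | 50 | genes | depth of the bar-chart rankings |

All comparisons are **strict** (`>`): a gene at exactly 2, 10 or 100 TPM
falls in the lower tier. Cutoffs are user-configurable but must satisfy
`0 < ligand_plot_cutoff ≤ expressed_cutoff < high_cutoff <
very_high_cutoff`.

Replicate averaging is the unweighted arithmetic mean over however many
sample columns are present (the reference datasets have 4 receiver and 5
sender replicates; the pipeline accepts any count and logs it).

## Quadrants, counts and ranking

Each (receptor, ligand) edge yields one row per category it is annotated
with, so a pair carrying two categories appears in both category panels —
deliberately, since multifunctional receptors such as integrin subunits
are analyzed in several signaling classes. Quadrant labels are
`<receptor>_<ligand>` with `high` meaning mean TPM > `high_cutoff`.
Quadrant counts are taken over **all** pairs of a category; the
plot-inclusion rule (receptor > 2, ligand > 1 TPM) only restricts what the
scatter figures display, and plotted-only counts are stored separately for
figure parity. Headline high/high counts additionally exclude proxy
pairs. Rankings sort by mean TPM descending with ties broken by symbol
ascending, making top-N lists deterministic.

## Enrichment

The overrepresentation test is the hypergeometric upper tail
(`scipy.stats.hypergeom.sf(k-1, N, K, n)`), one-sided by construction, with
Benjamini–Hochberg adjustment (`statsmodels`) across all tested sets. The
universe defaults to all genes in the receiver expression table. Pathway
membership comes from user GMT files; no proprietary pathway definitions
are emulated, so pathway *counts* from commercial engines are not
comparable quantities.

## Synthetic data generator

The generator emulates the structure the screen assumes: ~12,000 gene
symbols with log10-normal true mean TPM (μ = −0.5, σ = 1.0, putting most
genes below the expressed cutoff), 160 receptors with 1–4 ligands each
drawn from a shared pool (so some ligands serve several receptors), 15
proxy pairs, 15 orphan receptors entering via the curation include list,
and 4/5 replicates formed as true mean × 10^N(0, σ_noise) multiplicative
noise (σ_noise = 0.1 by default — heavy-tailed like real TPM; the
reference data give no noise model, so a log-normal was the natural
choice).

Planting: 20 pairs are selected so that their receptors and ligands are
pairwise distinct *and* no other database edge connects a planted receptor
to a planted ligand (a closure condition; without it, cross edges would
create unplanned high/high pairs). Planted receptor/ligand true means are
placed above `high_cutoff × margin` (margin 2.0), every other gene on the
relevant axis is redrawn below `high_cutoff / margin`, and true means are
additionally pushed out of the `(cutoff/margin, cutoff·margin)` band
around the expressed and plot cutoffs. Consequently every threshold
decision is margin-separated from its cutoff, and as long as sample means
stay within a factor `margin` of truth the screen must recover exactly the
planted high/high set and the planted orphan/ligand inventories — this is
verified empirically over 100 seeds. The band construction requires
`margin² < high_cutoff / expressed_cutoff`; infeasible settings are
rejected.

TPM is simulated directly on the TPM scale without renormalization so the
planted margins are exact; a Poisson counts mode (`poisson_counts`)
generates reads at a chosen depth to exercise the counts→TPM path, which
recovers the input profile in expectation.

What the generator does **not** emulate: realistic transcriptome
correlation structure, gene-length or GC effects, batch effects,
compositional coupling between genes, or biological variation between
replicate animals. Passing the recovery tests therefore demonstrates the
*screen logic* is correct under its own assumptions, not that thresholded
TPM is a biologically sufficient readout — see the assumptions above.
One consequence of margin separation is that counts relative to the
`very_high_cutoff` are *not* guaranteed noise-stable (planted means may
straddle 100 TPM), so truth comparisons cover the expressed/high-tier
counts only.

## Numerical choices and degenerate inputs

- TPM columns computed from counts must sum to 10⁶ within relative
  tolerance 1e-9; supplied TPM is never renormalized.
- A sample with all-zero counts has no defined TPM and is an error naming
  the sample; non-positive lengths are rejected at construction.
- Duplicate gene symbols after uppercasing: error by default,
  configurable to `sum` (counts) or `max` (TPM), always logged.
- Empty category panels skip their figure with a logged notice; zero or
  missing ligand TPM cannot be log-plotted but is excluded by the plot
  rule anyway, so no pseudo-count is introduced.
- Ties in rankings and in enrichment p-values are broken by name; report
  serialization sorts keys, so identical inputs give byte-identical
  outputs.

## Problem sizes used in the test suite

Oracle-equivalence tests run 1,000 random small instances (≤ 6 receptors,
≤ 7 ligands) against naive reimplementations; recovery runs 100 seeds at
the full default generator size; enumeration checks cover every
hypergeometric configuration with N ≤ 12. The acceptance script runs one
full-size synthetic screen per invocation.

## Known limitations

- Symbol-level joining across species ignores orthology complexities and
  many-to-many gene relationships.
- No significance assessment of co-expression; quadrant membership is a
  threshold call, sensitive to genes near cutoffs (mitigated in synthetic
  evaluation by margin separation, but not in real data).
- Directionality is sender→receiver only; autocrine signaling is
  inventoried but not paired, and vesicle-mediated signaling is out of
  scope.
- The published atlas numbers can only be recomputed when the externally
  distributed supplementary TPM/annotation tables are installed locally
  (`data/file_s1/`); the repository ships no real expression data.
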