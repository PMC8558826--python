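"""Gene-set overrepresentation analysis (hypergeometric ORA).

Given a query gene set (e.g. the expressed morula receptors) and a
collection of pathway gene sets, each set is tested for overrepresentation
with the hypergeometric upper tail

    p = P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n)

where N is the universe size, K the pathway size within the universe, n
the query size within the universe and k the overlap. One-sided by design:
only enrichment, not depletion, is of interest here. Benjamini-Hochberg
q-values are reported alongside the raw p-values; the conventional
significance call uses raw p < alpha (default 0.05), with q preferred for
any serious multiplicity-aware reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "EnrichmentError",
    "read_gmt",
    "write_gmt",
    "overrepresentation",
    "write_results",
]


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a gene universe.

    Sets are intersected with the universe on construction; sets that
    become empty are dropped (they carry no testable signal).
    """

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = {g.strip().upper() for g in self.universe}
        if not self.universe:
            raise EnrichmentError("gene universe is empty")
        clipped = {}
        for name, genes in self.sets.items():
            inter = {g.strip().upper() for g in genes} & self.universe
            if inter:
                clipped[name] = inter
        self.sets = clipped


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overlap statistics for one gene set."""

    set_name: str
    k: int  # overlap
    K: int  # set size within universe
    n: int  # query size within universe
    N: int  # universe size
    p: float  # upper-tail P(X >= k)
    q: float  # Benjamini-Hochberg adjusted
    significant: bool
    overlap_genes: tuple[str, ...] = ()


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EnrichmentError(
                    f"{path}: line {lineno}: GMT needs name, description and >=1 gene"
                )
            name = parts[0].strip()
            genes = {g.strip().upper() for g in parts[2:] if g.strip()}
            if not name or not genes:
                raise EnrichmentError(f"{path}: line {lineno}: empty set name or members")
            if name in sets:
                raise EnrichmentError(f"{path}: line {lineno}: duplicate set {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def overrepresentation(
    query: set[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every set in the collection for overrepresentation in the query.

    The query is intersected with the universe first; an empty intersection
    is an error (nothing to test). Results are sorted by p ascending (set
    name breaks ties) and carry BH q-values computed over all tested sets.
    """
    query = {g.strip().upper() for g in query} & collection.universe
    if not query:
        raise EnrichmentError("query is empty after intersection with the universe")
    if not collection.sets:
        return []
    N, n = len(collection.universe), len(query)
    names = sorted(collection.sets)
    rows = []
    for name in names:
        members = collection.sets[name]
        K = len(members)
        overlap = sorted(query & members)
        k = len(overlap)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, overlap, min(p, 1.0)))
    _, qvals, _, _ = multipletests([r[4] for r in rows], method="fdr_bh")
    results = [
        EnrichmentResult(
            set_name=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p=p,
            q=float(q),
            significant=p < alpha,
            overlap_genes=tuple(overlap),
        )
        for (name, k, K, overlap, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def write_results(results: list[EnrichmentResult], path) -> None:
    """Results TSV with columns set, k, K, n, N, p, q, significant, overlap."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set\tk\tK\tn\tN\tp\tq\tsignificant\toverlap_genes\n")
        for r in results:
            fh.write(
                f"{r.set_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p:.6g}\t{r.q:.6g}"
                f"\t{r.significant}\t{';'.join(r.overlap_genes)}\n"
            )
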