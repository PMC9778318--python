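"""Hypergeometric over-representation test for gene sets against pathways.

For a gene set of size n drawn from a universe of N genes, a pathway with K
members in the universe and k hits in the set gets the upper-tail p-value

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

with Benjamini-Hochberg adjustment across all tested pathways.  The
universe defaults to all genes of the supplied annotation; it can be
restricted to the pathway map's gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    k: int  # hits in the gene set
    K: int  # pathway size within the universe
    n: int  # gene set size
    N: int  # universe size
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("k cannot exceed min(K, n)")


def read_pathway_map(path: str) -> dict[str, set[str]]:
    """Read a two-column TSV (gene_id, pathway_id) into gene -> pathways."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene", "pathway"], dtype=str,
        comment="#",
    )
    out: dict[str, set[str]] = {}
    for gene, pw in zip(df.gene, df.pathway):
        out.setdefault(gene, set()).add(pw)
    return out


def hypergeom_enrich(
    gene_set: Iterable[str],
    pathway_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Test every pathway with >= 1 universe member for over-representation.

    ``gene_set`` must be a subset of ``universe``; genes outside the
    pathway map simply belong to no pathway.  Results are sorted by p-value
    (ties by pathway id for determinism).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe must be non-empty")
    genes = set(gene_set)
    if not genes <= universe_set:
        extra = sorted(genes - universe_set)[:5]
        raise ValueError(f"gene_set contains genes outside the universe: {extra}")
    by_pathway: dict[str, set[str]] = {}
    for gene, pws in pathway_map.items():
        if gene not in universe_set:
            continue
        for pw in pws:
            by_pathway.setdefault(pw, set()).add(gene)
    N, n = len(universe_set), len(genes)
    rows = []
    for pw in sorted(by_pathway):
        members = by_pathway[pw]
        K = len(members)
        k = len(members & genes)
        # upper tail P(X >= k); k = 0 gives p = 1
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((pw, k, K, p))
    if not rows:
        return []
    q = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(pw, k, K, n, N, p, float(qv))
        for (pw, k, K, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def write_enrichment_table(results: Iterable[EnrichmentResult], path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False)
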