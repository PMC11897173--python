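"""GO term over-representation via the one-sided hypergeometric test.

Associations are taken as flat gene -> term sets; no ontology-graph
propagation (ancestor inheritance) is performed.  Terms are flagged
"enriched" at a raw p-value cutoff (default 0.05); a BH-adjusted column is
reported alongside for reference but does not drive the flag.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Set

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["enrich", "hypergeom_upper_tail"]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); the enrichment p-value."""
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def enrich(study: Iterable[str], population: Iterable[str],
           associations: Mapping[str, Set[str]],
           alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of GO terms in a study gene set.

    For a term with K annotated genes in the population of size N, and k
    annotated genes in the study set of size n, the p-value is
    P(X >= k) with X ~ Hypergeometric(N, K, n).  One row per term with at
    least one study hit, sorted by p-value.
    """
    study = set(study)
    population = set(population)
    stray = sorted(study - population)
    if stray:
        raise ValueError(f"study genes outside the population: {stray[:10]}")
    n, N = len(study), len(population)

    pop_hits: dict[str, int] = {}
    study_hits: dict[str, int] = {}
    for gene in population:
        for term in associations.get(gene, ()):
            pop_hits[term] = pop_hits.get(term, 0) + 1
            if gene in study:
                study_hits[term] = study_hits.get(term, 0) + 1
    if not study_hits:
        raise ValueError("no study gene carries any annotation")

    rows = []
    for term, k in study_hits.items():
        K = pop_hits[term]
        rows.append({
            "term_id": term,
            "study_hits": k, "study_size": n,
            "population_hits": K, "population_size": N,
            "fold_enrichment": (k / n) / (K / N),
            "p_value": hypergeom_upper_tail(k, N, K, n),
        })
    df = pd.DataFrame(rows)
    df["fdr_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["enriched"] = df["p_value"] < alpha
    return df.sort_values(["p_value", "term_id"], ignore_index=True)
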