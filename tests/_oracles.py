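"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes results from first principles (per-base sets,
exhaustive enumeration, closed forms) without calling the code paths under
test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import betainc, chdtrc


# ---------------------------------------------------------------------------
# SV impact: per-base rule evaluation
# ---------------------------------------------------------------------------

_GENE_SET_CACHE: dict = {}


def _gene_sets(gene, promoter_len, downstream_len):
    key = (id(gene), promoter_len, downstream_len)
    if key not in _GENE_SET_CACHE:
        tr = gene.transcripts[0]
        cds = set()
        for a, b in tr.cds:
            cds |= set(range(a, b))
        exon = set()
        for a, b in tr.exons:
            exon |= set(range(a, b))
        body = set(range(gene.start, gene.end))
        pa, pb = gene.promoter(promoter_len)
        da, db = gene.downstream(downstream_len)
        prom = set(range(pa, pb))
        down = set(range(da, db))
        coding = sorted(cds)
        terminal = set(coding[:3]) | set(coding[-3:])
        _GENE_SET_CACHE[key] = (cds, exon, body, prom, down, terminal)
    return _GENE_SET_CACHE[key]


def sv_impact_oracle(svtype: str, start: int, end: int, length: int, gene,
                     promoter_len: int, downstream_len: int):
    """(region, impact) by explicit per-base set arithmetic; None if the
    variant touches none of the gene's regions.  Single-transcript genes."""
    cds, exon, body, prom, down, terminal = _gene_sets(
        gene, promoter_len, downstream_len)

    touched = set(range(start, end)) if start < end else {start}

    if touched & body:
        if touched & cds:
            region = "cds"
        elif touched & exon:
            region = "exon_noncoding"
        else:
            region = "intron"
    elif touched & prom:
        region = "promoter_upstream"
    elif touched & down:
        region = "downstream"
    else:
        return None

    if region in ("promoter_upstream", "downstream"):
        return region, "modifier"
    if svtype == "TRA":
        return region, "high" if region == "cds" else "moderate"
    if region == "intron":
        return region, "modifier"
    if region == "exon_noncoding":
        return region, "low"

    # region == cds
    if svtype == "INS":
        return region, "high" if length % 3 else "moderate"
    if svtype == "INV":
        def bkpt_inside(x):
            return x in cds and (x - 1) in cds
        return region, ("high" if bkpt_inside(start) or bkpt_inside(end)
                        else "moderate")
    # DEL / DUP
    removed = touched & cds
    if removed & terminal:
        return region, "high"
    if len(removed) % 3:
        return region, "high"
    return region, "moderate"


# ---------------------------------------------------------------------------
# Rarefaction: exhaustive set enumeration
# ---------------------------------------------------------------------------

def rarefaction_bruteforce(presence: dict[str, set[str]]):
    """Mean pan/core per k over all genome orderings, via python sets."""
    genomes = sorted(presence)
    n = len(genomes)
    pan_sum = np.zeros(n)
    core_sum = np.zeros(n)
    n_orders = 0
    for order in itertools.permutations(genomes):
        union: set[str] = set()
        inter: set[str] | None = None
        for k, g in enumerate(order):
            union = union | presence[g]
            inter = presence[g] if inter is None else inter & presence[g]
            pan_sum[k] += len(union)
            core_sum[k] += len(inter)
        n_orders += 1
    return pan_sum / n_orders, core_sum / n_orders


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values via the explicit step-up walk."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def welch_p(a, b):
    """Two-sided Welch t-test p-value via the regularized incomplete beta."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(betainc(df / 2.0, 0.5, df / (df + t * t)))


def kruskal_wallis(groups):
    """Kruskal-Wallis H and chi-square p from hand-computed rank sums."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    # mid-ranks with ties
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for t in range(i, j):
            ranks[t] = mid
        i = j
    rank_sums = [0.0] * len(groups)
    for r, (_, gi) in zip(ranks, pooled):
        rank_sums[gi] += r
    h = 12.0 / (n * (n + 1)) * sum(
        rs * rs / len(g) for rs, g in zip(rank_sums, groups)) - 3 * (n + 1)
    # tie correction
    ties = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        ties += (j - i) ** 3 - (j - i)
        i = j
    h /= 1.0 - ties / (n ** 3 - n)
    p = float(chdtrc(len(groups) - 1, h))
    return h, p


def chi2_2x2_corrected(table):
    """Pearson chi-square with Yates correction on a 2x2, closed form."""
    (a, b), (c, d) = table
    n = a + b + c + d
    num = n * (abs(a * d - b * c) - n / 2.0) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    stat = num / den
    return stat, float(chdtrc(1, stat))


def hypergeom_tail(k, N, K, n):
    """Upper-tail P(X >= k) by exhaustive enumeration of the pmf."""
    denom = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(k, min(n, K) + 1)) / denom
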