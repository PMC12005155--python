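"""Overlap enrichment of gene groups against gene quartiles.

Given a gene group (e.g. an expression-change class) and quartiles of the
gene universe ranked by length or expression, enrichment is
log2((|group∩quartile|/|group|) / (|quartile|/|universe|)) with hypergeometric
one-sided p-values (upper tail for over-enrichment, lower tail for
depletion) and Benjamini–Hochberg correction across the tested overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneGroup",
    "EnrichmentResult",
    "overlap_enrichment",
    "adjust_bh",
    "enrichment_table",
    "label_groups",
]


@dataclass(frozen=True)
class GeneGroup:
    """A labeled gene set drawn from a background universe."""

    label: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene group {self.label!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    log2_enrichment: float
    p: float  # one-sided p in the direction of the observed enrichment
    p_over: float
    p_under: float
    overlap: int


def overlap_enrichment(
    group: Set[str] | GeneGroup, quartile: Set[str], universe: Set[str]
) -> EnrichmentResult:
    """Log2 enrichment of a group within a quartile plus hypergeometric p.

    Zero overlap yields a ``-inf`` enrichment sentinel with the exact
    depletion p-value. Both one-sided tails are reported; ``p`` is the tail
    matching the sign of the enrichment.
    """
    g = set(group.members) if isinstance(group, GeneGroup) else set(group)
    q, u = set(quartile), set(universe)
    if not g or not q:
        raise ValueError("group and quartile must be non-empty")
    if not g <= u or not q <= u:
        raise ValueError("group and quartile must be subsets of the universe")
    k = len(g & q)
    M, n, N = len(u), len(g), len(q)
    p_over = float(hypergeom.sf(k - 1, M, n, N))
    p_under = float(hypergeom.cdf(k, M, n, N))
    if k == 0:
        return EnrichmentResult(float("-inf"), p_under, p_over, p_under, 0)
    enr = float(np.log2((k / n) / (N / M)))
    p = p_over if enr >= 0 else p_under
    return EnrichmentResult(enr, p, p_over, p_under, k)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(
    groups: Iterable[GeneGroup],
    stratification: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All (group × quartile) overlaps with enrichment, p, BH-adjusted p.

    The universe is the intersection of the stratified gene set with the
    union of group members' background — here, the stratified set itself;
    group members outside it are dropped (they were not eligible for the
    stratification).
    """
    universe = set(stratification)
    labels = sorted(set(stratification.values()))
    quartiles = {q: {g for g, l in stratification.items() if l == q} for q in labels}
    rows = []
    for grp in groups:
        members = set(grp.members) & universe
        if not members:
            continue
        for q in labels:
            r = overlap_enrichment(members, quartiles[q], universe)
            rows.append(
                {
                    "group": grp.label,
                    "quartile": q,
                    "group_size": len(members),
                    "quartile_size": len(quartiles[q]),
                    "overlap": r.overlap,
                    "log2_enrichment": r.log2_enrichment,
                    "p": r.p,
                    "p_over": r.p_over,
                    "p_under": r.p_under,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adj"] = adjust_bh(table["p"].to_numpy())
        table["significant"] = table["p_adj"] < alpha
    return table


def label_groups(
    calls: pd.DataFrame, min_size: int = 20, other_label: str = "other"
) -> list[GeneGroup]:
    """Group genes by their pattern of significant calls across comparisons.

    ``calls``: DataFrame indexed by gene_id with one column per comparison
    holding −1 (down), 0 (no call), or +1 (up). Patterns are ranked by size
    (largest first) and labeled G1, G2, …; patterns with fewer than
    ``min_size`` genes are pooled under ``other_label``. Genes with no call
    in any comparison are excluded.
    """
    patterns: dict[tuple, list[str]] = {}
    for gene, row in calls.iterrows():
        pat = tuple(int(v) for v in row)
        if all(v == 0 for v in pat):
            continue
        patterns.setdefault(pat, []).append(str(gene))
    ordered = sorted(patterns.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    groups: list[GeneGroup] = []
    pooled: list[str] = []
    gi = 0
    for pat, genes in ordered:
        if len(genes) >= min_size:
            gi += 1
            groups.append(GeneGroup(f"G{gi}", frozenset(genes)))
        else:
            pooled.extend(genes)
    if pooled:
        groups.append(GeneGroup(other_label, frozenset(pooled)))
    return groups
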