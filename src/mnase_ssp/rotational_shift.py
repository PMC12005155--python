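"""Rotational-position Z-score statistic for nucleosome positioning shifts.

Nucleosomes can occupy alternative *rotational positions* — placements ~10 bp
apart that preserve the helical orientation of DNA on the histone surface.
For each (gene, nucleosome index) we collect fragment-midpoint occupancy at
the 11 rotational positions −50..+50 bp (10 bp steps, strand-oriented, ±2 bp
collection halfwidth), standardize each row to Z-scores (so positive Z marks
the preferred rotational positions of that one nucleosome in that one gene),
and compare mutant against wild-type: ΔZ = Z_mut − Z_wt per gene. Per
(nucleosome index, rotational position) the median ΔZ across genes is the
effect size and a two-sided Wilcoxon rank-sum test across genes supplies the
p-value, Benjamini–Hochberg-adjusted across all cells of one comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .coverage import CoverageTrack, LengthBin
from .enrichment import adjust_bh
from .metaplots import AnchorSet

__all__ = [
    "ROTATIONAL_POSITIONS",
    "RotationalTable",
    "ShiftResult",
    "GeneStratification",
    "rotational_occupancy",
    "zscore_rows",
    "delta_z",
    "shift_test",
    "stratify_by_length",
    "stratify_by_score",
    "expression_score",
]

logger = logging.getLogger(__name__)

#: Rotational positions interrogated around each dyad (bp, strand-oriented).
ROTATIONAL_POSITIONS = np.arange(-50, 51, 10)


@dataclass
class RotationalTable:
    """Per (gene, nucleosome index) vectors over rotational positions.

    ``values``: DataFrame with MultiIndex (gene_id, nuc_index) and one column
    per rotational position; ``stage`` is "occupancy" or "zscore".
    """

    values: pd.DataFrame
    stage: str = "occupancy"

    def __post_init__(self):
        if list(self.values.columns) != list(ROTATIONAL_POSITIONS):
            raise ValueError("columns must be the 11 rotational positions -50..50")
        if self.stage not in ("occupancy", "zscore"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "occupancy" and (self.values.to_numpy() < 0).any():
            raise ValueError("occupancy must be non-negative")


def rotational_occupancy(
    midpoint_track: CoverageTrack,
    dyads: AnchorSet,
    length_bin: LengthBin | None = None,
    halfwidth: int = 2,
) -> RotationalTable:
    """Sum midpoint coverage in ±``halfwidth`` bp windows at each rotational
    position around every dyad.

    ``midpoint_track`` must be midpoint coverage built from the length bin of
    interest (checked against ``track.length_bin`` when both are given).
    Dyads whose outermost window would cross a chromosome edge are dropped
    and logged.
    """
    if length_bin is not None and midpoint_track.length_bin is not None:
        if (length_bin.min_len, length_bin.max_len) != (
            midpoint_track.length_bin.min_len,
            midpoint_track.length_bin.max_len,
        ):
            raise ValueError("track was built from a different length bin")
    adf = dyads.anchors
    reach = int(ROTATIONAL_POSITIONS.max()) + halfwidth
    rows = []
    index = []
    dropped = 0
    for chrom, grp in adf.groupby("chrom", sort=False):
        vec = midpoint_track.data.get(chrom)
        if vec is None:
            dropped += len(grp)
            continue
        # cumulative sum turns each ±halfwidth window into two lookups
        csum = np.concatenate(([0.0], np.cumsum(vec)))
        pos = grp["pos"].to_numpy()
        ok = (pos - reach >= 0) & (pos + reach < vec.size)
        dropped += int((~ok).sum())
        grp, pos = grp.loc[ok], pos[ok]
        sign = np.where(grp["strand"].to_numpy() == "+", 1, -1)
        centers = pos[:, None] + sign[:, None] * ROTATIONAL_POSITIONS[None, :]
        occ = csum[centers + halfwidth + 1] - csum[centers - halfwidth]
        rows.append(occ)
        index.extend(zip(grp["gene_id"], grp["role"]))
    if dropped:
        logger.info("dropped %d dyads too close to chrom edges", dropped)
    if not rows:
        raise ValueError("no usable dyads")
    values = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["gene_id", "nuc_index"]),
        columns=ROTATIONAL_POSITIONS,
    )
    return RotationalTable(values, stage="occupancy")


def zscore_rows(table: RotationalTable) -> RotationalTable:
    """Standardize each row to mean 0 / population SD 1; zero-variance rows
    map to all zeros."""
    if table.stage != "occupancy":
        raise ValueError("zscore_rows expects an occupancy-stage table")
    x = table.values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return RotationalTable(
        pd.DataFrame(z, index=table.values.index, columns=table.values.columns),
        stage="zscore",
    )


def delta_z(mutant: RotationalTable, wt: RotationalTable) -> RotationalTable:
    """ΔZ = mutant − wild-type per (gene, nucleosome, position), on the key
    intersection (mismatches logged)."""
    if mutant.stage != "zscore" or wt.stage != "zscore":
        raise ValueError("delta_z expects zscore-stage tables")
    common = mutant.values.index.intersection(wt.values.index)
    n_miss = len(mutant.values.index.symmetric_difference(wt.values.index))
    if n_miss:
        logger.info("delta_z: %d keys present in only one table", n_miss)
    if len(common) == 0:
        raise ValueError("no (gene, nucleosome) keys shared between tables")
    diff = mutant.values.loc[common] - wt.values.loc[common]
    return RotationalTable(diff, stage="zscore")


@dataclass
class ShiftResult:
    """Per (nucleosome index, rotational position) shift statistics.

    ``table`` columns: nuc_index, position, n_genes, median_dz, p, p_adj,
    significant (adjusted p < alpha).
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def significant_count(self, nuc_index=None) -> int:
        t = self.table
        if nuc_index is not None:
            t = t[t["nuc_index"] == nuc_index]
        return int(t["significant"].sum())


def shift_test(
    mutant_z: RotationalTable,
    wt_z: RotationalTable,
    gene_subset: Sequence[str] | None = None,
    alpha: float = 0.05,
    min_genes: int = 10,
) -> ShiftResult:
    """Test per (nucleosome index, rotational position) whether mutant
    rotational Z-scores differ from wild-type across genes.

    Effect size is the median ΔZ across genes; the p-value is a two-sided
    Wilcoxon rank-sum comparing mutant vs wild-type Z values across genes at
    that position; BH adjustment spans all cells of the comparison. A
    nucleosome index with fewer than ``min_genes`` eligible genes is skipped
    with a warning.
    """
    if mutant_z.stage != "zscore" or wt_z.stage != "zscore":
        raise ValueError("shift_test expects zscore-stage tables")
    common = mutant_z.values.index.intersection(wt_z.values.index)
    if gene_subset is not None:
        subset = set(gene_subset)
        common = common[[g in subset for g in common.get_level_values("gene_id")]]
    if len(common) == 0:
        raise ValueError("no shared (gene, nucleosome) keys to test")
    mz = mutant_z.values.loc[common]
    wz = wt_z.values.loc[common]

    rows = []
    for idx in sorted(set(common.get_level_values("nuc_index"))):
        sel = common.get_level_values("nuc_index") == idx
        n = int(sel.sum())
        if n < min_genes:
            logger.warning(
                "nucleosome index %s skipped: %d genes < floor %d", idx, n, min_genes
            )
            continue
        m_block = mz.loc[sel].to_numpy()
        w_block = wz.loc[sel].to_numpy()
        for j, pos in enumerate(ROTATIONAL_POSITIONS):
            stat, p = ranksums(m_block[:, j], w_block[:, j])
            rows.append(
                {
                    "nuc_index": idx,
                    "position": int(pos),
                    "n_genes": n,
                    "median_dz": float(np.median(m_block[:, j] - w_block[:, j])),
                    "p": float(p),
                }
            )
    if not rows:
        raise ValueError("no nucleosome index met the gene-count floor")
    table = pd.DataFrame(rows)
    table["p_adj"] = adjust_bh(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return ShiftResult(table, alpha=alpha)


@dataclass
class GeneStratification:
    """Quartile (or k-tile) labels per gene under one ranking criterion."""

    assignment: dict[str, str]
    criterion: str = "length"

    def quartile(self, label: str) -> set[str]:
        return {g for g, q in self.assignment.items() if q == label}

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))


def stratify_by_score(
    scores: Mapping[str, float], k: int = 4, criterion: str = "score"
) -> GeneStratification:
    """Rank genes by score ascending and split into k contiguous groups of
    equal size (±1); ties broken by gene id. Q1 holds the lowest scores."""
    if len(scores) < k:
        raise ValueError(f"need at least {k} genes to form {k} groups")
    ranked = sorted(scores, key=lambda g: (scores[g], g))
    assignment: dict[str, str] = {}
    for i, chunk in enumerate(np.array_split(np.asarray(ranked, dtype=object), k)):
        for g in chunk:
            assignment[g] = f"Q{i + 1}"
    return GeneStratification(assignment, criterion)


def stratify_by_length(genes, k: int = 4) -> GeneStratification:
    """Quartiles of gene length with equal gene numbers (Q1 shortest).

    ``genes`` is a mapping gene_id → length or a DataFrame with columns
    gene_id and length.
    """
    if isinstance(genes, pd.DataFrame):
        genes = dict(zip(genes["gene_id"], genes["length"]))
    strat = stratify_by_score(genes, k, criterion="length")
    return strat


def expression_score(
    netseq_counts: Mapping[str, np.ndarray], gene: Mapping
) -> float:
    """Sum nascent-transcription counts over the strand-oriented window
    [TSS+100, TSS+200] inclusive (101 bp).

    ``gene`` needs keys chrom, tss, strand.
    """
    chrom, tss, strand = gene["chrom"], int(gene["tss"]), gene["strand"]
    vec = netseq_counts[chrom]
    if strand == "+":
        lo, hi = tss + 100, tss + 200
    else:
        lo, hi = tss - 200, tss - 100
    if lo < 0 or hi >= vec.size:
        raise ValueError("expression window outside chromosome bounds")
    return float(np.asarray(vec[lo : hi + 1]).sum())
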