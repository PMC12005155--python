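"""Dyad-anchored V-plots, metagene profiles, and occupancy heatmaps.

Offsets are strand-oriented throughout: for a gene on the − strand the
offset axis is reflected so that "downstream of the dyad" is positive for
every gene, which lets genes on both strands be pooled.

Fragments are counted once per anchor whose window they fall in (an
anchor-centric sum), so closely spaced dyads may each count the same
fragment — the usual metagene convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import (
    CoverageTrack,
    LengthBin,
    filter_by_length,
    fragment_coverage,
    midpoint_coverage,
    normalization_factor,
)
from .fragments_io import fragment_midpoint

__all__ = [
    "AnchorSet",
    "VPlotMatrix",
    "OccupancyHeatmap",
    "dyad_anchors",
    "tss_anchors",
    "build_vplot",
    "metagene_profile",
    "occupancy_heatmap",
    "difference_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class AnchorSet:
    """Genomic anchor positions (dyads or TSS) with strand and gene labels.

    ``anchors`` columns: chrom, pos, strand, gene_id, role (nucleosome index
    as int, or the string "TSS").
    """

    anchors: pd.DataFrame

    def __post_init__(self):
        required = {"chrom", "pos", "strand", "gene_id", "role"}
        missing = required - set(self.anchors.columns)
        if missing:
            raise ValueError(f"anchor frame missing columns {sorted(missing)}")
        bad = ~self.anchors["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("anchor strands must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.anchors)

    def subset_role(self, roles) -> "AnchorSet":
        roles = set(np.atleast_1d(roles).tolist())
        return AnchorSet(self.anchors[self.anchors["role"].isin(roles)].reset_index(drop=True))


def dyad_anchors(genome, indices: Sequence[int] | None = None) -> AnchorSet:
    """Anchor set from a genome model's nucleosome dyads (+1..+K by default)."""
    d = genome.dyads
    if indices is None:
        d = d[d["index"] >= 1]
    else:
        d = d[d["index"].isin(list(indices))]
    return AnchorSet(
        d.rename(columns={"index": "role"})[
            ["chrom", "pos", "strand", "gene_id", "role"]
        ].reset_index(drop=True)
    )


def tss_anchors(genome) -> AnchorSet:
    g = genome.genes
    return AnchorSet(
        pd.DataFrame(
            {
                "chrom": g["chrom"],
                "pos": g["tss"],
                "strand": g["strand"],
                "gene_id": g["gene_id"],
                "role": "TSS",
            }
        )
    )


@dataclass
class VPlotMatrix:
    """2-D histogram of (midpoint offset from anchor) × (fragment length)."""

    counts: pd.DataFrame  # index: offset, columns: length
    n_anchors: int
    normalized: bool = False

    @property
    def offsets(self) -> np.ndarray:
        return self.counts.index.to_numpy()

    @property
    def lengths(self) -> np.ndarray:
        return self.counts.columns.to_numpy()

    def argmax(self) -> tuple[int, int]:
        """(offset, length) of the maximal cell."""
        arr = self.counts.to_numpy()
        i, j = np.unravel_index(np.argmax(arr), arr.shape)
        return int(self.counts.index[i]), int(self.counts.columns[j])


def build_vplot(
    frags: pd.DataFrame,
    anchors: AnchorSet,
    max_offset: int = 500,
    length_range: tuple[int, int] = (35, 170),
) -> VPlotMatrix:
    """Count fragment midpoints around anchors by strand-oriented offset and
    fragment length.

    A fragment contributes one count at (offset, length) for every anchor
    with |offset| ≤ ``max_offset``; the total count therefore equals the
    number of in-window (fragment, anchor) pairs.
    """
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    min_len, max_len = length_range
    offsets_axis = np.arange(-max_offset, max_offset + 1)
    lengths_axis = np.arange(min_len, max_len + 1)
    counts = np.zeros((offsets_axis.size, lengths_axis.size), dtype=np.int64)

    lengths_all = (frags["end"] - frags["start"]).to_numpy()
    keep = (lengths_all >= min_len) & (lengths_all <= max_len)
    frags = frags.loc[keep]

    adf = anchors.anchors
    for chrom, fgrp in frags.groupby("chrom", sort=False):
        agrp = adf[adf["chrom"] == chrom]
        if agrp.empty:
            continue
        apos = agrp["pos"].to_numpy()
        asign = np.where(agrp["strand"].to_numpy() == "+", 1, -1)
        order = np.argsort(apos, kind="stable")
        apos, asign = apos[order], asign[order]

        mids = fragment_midpoint(fgrp["start"].to_numpy(), fgrp["end"].to_numpy())
        lens = (fgrp["end"] - fgrp["start"]).to_numpy()
        lo = np.searchsorted(apos, mids - max_offset, side="left")
        hi = np.searchsorted(apos, mids + max_offset, side="right")
        n_pairs = hi - lo
        with_pairs = np.flatnonzero(n_pairs > 0)
        if with_pairs.size == 0:
            continue
        frag_idx = np.repeat(with_pairs, n_pairs[with_pairs])
        anchor_idx = (
            np.concatenate([np.arange(lo[i], hi[i]) for i in with_pairs])
            if with_pairs.size
            else np.array([], int)
        )
        off = (mids[frag_idx] - apos[anchor_idx]) * asign[anchor_idx]
        np.add.at(counts, (off + max_offset, lens[frag_idx] - min_len), 1)

    return VPlotMatrix(
        pd.DataFrame(counts, index=offsets_axis, columns=lengths_axis),
        n_anchors=len(anchors),
    )


def _oriented_slices(
    track: CoverageTrack, anchors: AnchorSet, flank: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack per-anchor strand-oriented coverage slices [-flank, +flank].

    Anchors too close to a chromosome edge are dropped (logged).
    """
    adf = anchors.anchors
    rows = []
    kept = []
    dropped = 0
    offsets = np.arange(-flank, flank + 1)
    for chrom, grp in adf.groupby("chrom", sort=False):
        vec = track.data.get(chrom)
        if vec is None:
            dropped += len(grp)
            continue
        pos = grp["pos"].to_numpy()
        ok = (pos - flank >= 0) & (pos + flank < vec.size)
        dropped += int((~ok).sum())
        grp = grp.loc[ok]
        pos = pos[ok]
        sign = np.where(grp["strand"].to_numpy() == "+", 1, -1)
        idx = pos[:, None] + sign[:, None] * offsets[None, :]
        rows.append(vec[idx])
        kept.append(grp)
    if dropped:
        logger.info("dropped %d anchors too close to chrom edges", dropped)
    if not rows:
        raise ValueError("no usable anchors within chromosome bounds")
    return np.vstack(rows), pd.concat(kept, ignore_index=True)


def metagene_profile(
    frags: pd.DataFrame,
    anchors: AnchorSet,
    flank: int = 1000,
    length_bin: LengthBin | None = None,
    mode: str = "overlap",
    chrom_sizes: Mapping[str, int] | None = None,
    norm_factor: float | None = None,
) -> pd.Series:
    """Mean normalized coverage across anchors at strand-oriented offsets.

    ``norm_factor`` defaults to the depth factor computed from the *total*
    (pre-length-filter) fragment count, mirroring per-library normalization.
    ``chrom_sizes`` is required to build the underlying track.
    """
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if chrom_sizes is None:
        raise ValueError("chrom_sizes is required")
    if norm_factor is None:
        norm_factor = normalization_factor(len(frags))
    builder = fragment_coverage if mode == "overlap" else midpoint_coverage
    if mode not in ("overlap", "midpoint"):
        raise ValueError("mode must be 'overlap' or 'midpoint'")
    track = builder(frags, chrom_sizes, length_bin, norm_factor)
    stack, _ = _oriented_slices(track, anchors, flank)
    return pd.Series(stack.mean(axis=0), index=np.arange(-flank, flank + 1), name="coverage")


@dataclass
class OccupancyHeatmap:
    """Per-gene coverage rows around the +1 dyad, ranked by gene length
    (descending)."""

    matrix: pd.DataFrame  # index: gene_id (length-ranked), columns: offset
    length_bin: LengthBin | None = None


def occupancy_heatmap(
    frags: pd.DataFrame,
    genome,
    length_bin: LengthBin | None = None,
    flank: int = 500,
    mode: str = "overlap",
    norm_factor: float | None = None,
) -> OccupancyHeatmap:
    """One row per gene: normalized coverage at strand-oriented offsets from
    the gene's +1 nucleosome dyad; rows sorted by gene length, longest first.

    Genes lacking a +1 dyad (or with the dyad too close to a chrom edge) are
    dropped with a logged count.
    """
    dyads1 = genome.dyads[genome.dyads["index"] == 1]
    genes = genome.genes.set_index("gene_id")
    missing = set(genes.index) - set(dyads1["gene_id"])
    if missing:
        logger.info("dropping %d genes without a +1 dyad", len(missing))
    anchors = AnchorSet(
        dyads1.rename(columns={"index": "role"})[
            ["chrom", "pos", "strand", "gene_id", "role"]
        ].reset_index(drop=True)
    )
    if norm_factor is None:
        norm_factor = normalization_factor(len(frags))
    builder = fragment_coverage if mode == "overlap" else midpoint_coverage
    track = builder(frags, genome.chrom_sizes, length_bin, norm_factor)
    stack, kept = _oriented_slices(track, anchors, flank)
    mat = pd.DataFrame(stack, index=kept["gene_id"], columns=np.arange(-flank, flank + 1))
    order = (
        genes.loc[mat.index, "length"]
        .sort_values(ascending=False, kind="stable")
        .index
    )
    return OccupancyHeatmap(mat.loc[order], length_bin)


def difference_matrix(mutant, wt):
    """Elementwise mutant − wild-type for congruent matrices."""
    m = mutant.matrix if isinstance(mutant, OccupancyHeatmap) else mutant
    w = wt.matrix if isinstance(wt, OccupancyHeatmap) else wt
    if isinstance(m, pd.DataFrame) and isinstance(w, pd.DataFrame):
        if m.shape != w.shape or not m.index.equals(w.index) or not m.columns.equals(w.columns):
            raise ValueError("matrices are not congruent")
        return m - w
    m, w = np.asarray(m), np.asarray(w)
    if m.shape != w.shape:
        raise ValueError("matrices are not congruent")
    return m - w
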