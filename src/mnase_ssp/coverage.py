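"""Normalized per-bp coverage for fragment-length bins.

Two track types are used downstream: *overlap* coverage (each fragment adds
the normalization factor to every bp it covers) and *midpoint* coverage (each
fragment adds it at its midpoint bp only). Fragment-length distributions of
multiple samples can be matched exactly by per-length random subsampling
before any comparison between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments_io import fragment_midpoint

__all__ = [
    "DEFAULT_NORM_CONSTANT",
    "LengthBin",
    "CoverageTrack",
    "STANDARD_BINS",
    "normalization_factor",
    "filter_by_length",
    "fragment_coverage",
    "midpoint_coverage",
    "match_length_distributions",
]

#: Numerator of the depth-normalization factor N = constant / total mapped
#: reads. The value is an arbitrary fixed constant so that tracks from
#: libraries of different depth are on a common scale.
DEFAULT_NORM_CONSTANT = 139_712_364


@dataclass(frozen=True)
class LengthBin:
    """Inclusive fragment-length interval [min_len, max_len] in bp."""

    min_len: int
    max_len: int
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.min_len <= self.max_len):
            raise ValueError(f"invalid length bin {self.min_len}:{self.max_len}")

    def __str__(self) -> str:
        return self.label or f"{self.min_len}-{self.max_len}"


#: Fragment-length classes used throughout: sub-60 bp non-nucleosomal
#: footprints, tetrasome (~61-71), hexasome (~83-93 / ~102-112), nucleosome
#: core (~147), and a broad body bin.
STANDARD_BINS = {
    "short": LengthBin(0, 60, "short"),
    "tetrasome": LengthBin(61, 71, "tetrasome"),
    "hexasome_distal": LengthBin(83, 93, "hexasome_distal"),
    "hexasome": LengthBin(102, 112, "hexasome"),
    "nucleosome": LengthBin(142, 152, "nucleosome"),
    "body": LengthBin(80, 170, "body"),
}


@dataclass
class CoverageTrack:
    """Dense per-bp normalized counts per chromosome."""

    data: dict[str, np.ndarray]
    length_bin: LengthBin | None = None
    norm_factor: float = 1.0
    kind: str = "overlap"  # or "midpoint"

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        if set(self.data) != set(other.data):
            raise ValueError("tracks cover different chromosomes")
        return replace(
            self, data={c: self.data[c] + other.data[c] for c in self.data}
        )


def normalization_factor(
    total_mapped_reads: int, constant: int = DEFAULT_NORM_CONSTANT
) -> float:
    """Depth normalization factor N = constant / total mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return constant / total_mapped_reads


def filter_by_length(frags: pd.DataFrame, length_bin: LengthBin) -> pd.DataFrame:
    """Keep fragments whose length lies in the bin (inclusive both ends)."""
    lengths = frags["end"] - frags["start"]
    mask = (lengths >= length_bin.min_len) & (lengths <= length_bin.max_len)
    return frags.loc[mask]


def _new_data(chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    return {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}


def _check_bounds(frags: pd.DataFrame, chrom_sizes: Mapping[str, int]) -> None:
    for chrom, grp in frags.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            raise ValueError(f"fragment on unknown chrom {chrom!r}")
        if (grp["start"] < 0).any() or (grp["end"] > chrom_sizes[chrom]).any():
            raise ValueError(f"fragment outside bounds of {chrom}")


def fragment_coverage(
    frags: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    length_bin: LengthBin | None = None,
    norm_factor: float = 1.0,
) -> CoverageTrack:
    """Overlap coverage: each fragment adds ``norm_factor`` to every bp it
    spans, so the genome-wide sum equals ``norm_factor * sum(lengths)``."""
    if length_bin is not None:
        frags = filter_by_length(frags, length_bin)
    _check_bounds(frags, chrom_sizes)
    data = _new_data(chrom_sizes)
    for chrom, grp in frags.groupby("chrom", sort=False):
        delta = np.zeros(chrom_sizes[chrom] + 1, dtype=float)
        np.add.at(delta, grp["start"].to_numpy(), norm_factor)
        np.add.at(delta, grp["end"].to_numpy(), -norm_factor)
        data[chrom] = np.cumsum(delta[:-1])
    return CoverageTrack(data, length_bin, norm_factor, kind="overlap")


def midpoint_coverage(
    frags: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    length_bin: LengthBin | None = None,
    norm_factor: float = 1.0,
) -> CoverageTrack:
    """Fragment-center coverage: ``norm_factor`` at each fragment midpoint,
    so the genome-wide sum equals ``norm_factor * n_fragments``."""
    if length_bin is not None:
        frags = filter_by_length(frags, length_bin)
    _check_bounds(frags, chrom_sizes)
    data = _new_data(chrom_sizes)
    for chrom, grp in frags.groupby("chrom", sort=False):
        mids = fragment_midpoint(
            grp["start"].to_numpy(), grp["end"].to_numpy()
        )
        np.add.at(data[chrom], mids, norm_factor)
    return CoverageTrack(data, length_bin, norm_factor, kind="midpoint")


def match_length_distributions(samples: Sequence, seed: int) -> list:
    """Subsample every sample so all share one fragment-length histogram.

    For each length L, every output sample keeps exactly
    ``min_s count_s(L)`` fragments of length L, drawn uniformly without
    replacement; deterministic given ``seed``. Accepts and returns
    :class:`~mnase_ssp.synthetic_data.FragmentSet` objects (or any object
    with a ``frags`` DataFrame attribute).
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples to match distributions")
    frames = [s.frags for s in samples]
    if any(len(f) == 0 for f in frames):
        raise ValueError("cannot match length distributions with an empty sample")
    lengths = [(f["end"] - f["start"]).to_numpy() for f in frames]
    counts = [pd.Series(l).value_counts() for l in lengths]
    common = counts[0]
    for c in counts[1:]:
        common = np.minimum(common.reindex(common.index.union(c.index), fill_value=0),
                            c.reindex(common.index.union(c.index), fill_value=0))
    common = common[common > 0].sort_index()

    root = np.random.SeedSequence(seed)
    out = []
    for s, frame, lens, child in zip(
        samples, frames, lengths, root.spawn(len(samples))
    ):
        rng = np.random.default_rng(child)
        keep_parts = []
        for L, m in common.items():
            idx = np.flatnonzero(lens == L)
            if m < idx.size:
                idx = rng.choice(idx, size=int(m), replace=False)
            keep_parts.append(idx)
        keep = np.sort(np.concatenate(keep_parts)) if keep_parts else np.array([], int)
        sub = frame.iloc[keep].reset_index(drop=True)
        out.append(replace_frags(s, sub))
    return out


def replace_frags(sample, frags: pd.DataFrame):
    """Return a copy of a FragmentSet-like object with a new fragment frame."""
    try:
        return replace(sample, frags=frags)
    except TypeError:
        import copy

        s = copy.copy(sample)
        s.frags = frags
        return s
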