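"""Reading/writing fragment intervals, coverage tracks, and read preprocessing.

Coordinates are 0-based half-open (BED convention) throughout the package.
Nucleosome dyad annotations supplied as 1-based single positions are converted
on input (see :func:`read_dyads_bed`).

Fragments are held in bulk as a pandas DataFrame with columns
``chrom, start, end, strand`` (the "fragment frame"); :class:`FragmentRecord`
is the single-record view used at IO boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FragmentRecord",
    "ReadRecord",
    "BedParseError",
    "preprocess_reads",
    "fragment_midpoint",
    "fragments_frame",
    "read_fragments_bed",
    "write_fragments_bed",
    "write_bedgraph",
    "read_bedgraph",
    "read_dyads_bed",
    "write_tsv_matrix",
    "MAX_READ_LENGTH",
    "MIN_READ_LENGTH",
]

#: Reads are capped at this many bp after adapter removal.
MAX_READ_LENGTH = 140
#: Reads shorter than this are discarded.
MIN_READ_LENGTH = 35

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class FragmentRecord:
    """One MNase-protected fragment as a genomic interval.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``length`` is derived
    as ``end - start``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read after adapter removal, reduced to id and length."""

    read_id: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("read length must be non-negative")


class BedParseError(ValueError):
    """Raised for malformed BED input; carries offending line numbers."""

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        msgs = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors)
        super().__init__(f"malformed BED input ({msgs})")


def preprocess_reads(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Apply the read-length rules: cap at 140 bp, discard reads under 35 bp.

    Order is preserved and the operation is idempotent — survivors always lie
    in ``[MIN_READ_LENGTH, MAX_READ_LENGTH]``.
    """
    out = []
    for r in reads:
        if r.length < MIN_READ_LENGTH:
            continue
        if r.length > MAX_READ_LENGTH:
            r = ReadRecord(r.read_id, MAX_READ_LENGTH)
        out.append(r)
    return out


def fragment_midpoint(start, end):
    """Midpoint of a half-open interval, rounding down for even lengths.

    Accepts scalars or arrays; ``FragmentRecord.midpoint`` applies the same
    rule. The floor tie-rule is applied uniformly so relative comparisons
    between samples are unaffected.
    """
    if isinstance(start, FragmentRecord):
        return start.midpoint
    return (np.asarray(start) + np.asarray(end)) // 2 if np.ndim(start) else (start + end) // 2


def fragments_frame(records: Iterable[FragmentRecord]) -> pd.DataFrame:
    """Assemble a fragment frame (chrom/start/end/strand) from records."""
    rows = [(r.chrom, r.start, r.end, r.strand) for r in records]
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_fragments_bed(
    path, chrom_sizes: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Read fragments from a BED file (≥3 columns) into a fragment frame.

    Malformed lines (too few fields, non-integer coordinates, end ≤ start,
    or — when ``chrom_sizes`` is given — unknown chromosome / out-of-bounds
    interval) are collected and raised together as :class:`BedParseError`
    with their 1-based line numbers.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    errors: list[tuple[int, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                errors.append((ln, "fewer than 3 columns"))
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                errors.append((ln, "non-integer coordinates"))
                continue
            if end <= start:
                errors.append((ln, f"end {end} <= start {start}"))
                continue
            chrom = fields[0]
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    errors.append((ln, f"unknown chrom {chrom!r}"))
                    continue
                if start < 0 or end > chrom_sizes[chrom]:
                    errors.append((ln, "interval outside chrom bounds"))
                    continue
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            strands.append(fields[5] if len(fields) >= 6 else ".")
    if errors:
        raise BedParseError(errors)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "strand": strands,
        }
    )
    return df


def write_fragments_bed(frags: pd.DataFrame, path, name: str = ".") -> None:
    """Write a fragment frame as 6-column BED: name column carries the sample
    id, score column the fragment length."""
    lengths = (frags["end"] - frags["start"]).to_numpy()
    strand = frags["strand"] if "strand" in frags else pd.Series(["."] * len(frags))
    with open(path, "w") as fh:
        for c, s, e, ln, st in zip(
            frags["chrom"], frags["start"], frags["end"], lengths, strand
        ):
            fh.write(f"{c}\t{s}\t{e}\t{name}\t{ln}\t{st}\n")


def write_bedgraph(track, path) -> None:
    """Write per-bp values as a run-length-merged bedGraph.

    ``track`` is a :class:`~mnase_ssp.coverage.CoverageTrack` or a plain
    ``{chrom: array}`` mapping. Zero runs are omitted (bedGraph convention);
    values are formatted to 6 significant digits.
    """
    data = getattr(track, "data", track)
    with open(path, "w") as fh:
        for chrom in sorted(data):
            values = np.asarray(data[chrom], dtype=float)
            if values.size == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph back into dense per-bp arrays (zeros where absent)."""
    data = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            s, e = int(s), int(e)
            if chrom not in data or s < 0 or e > chrom_sizes[chrom]:
                raise BedParseError([(ln, "interval outside chrom bounds")])
            data[chrom][s:e] = float(v)
    return data


def read_dyads_bed(path) -> pd.DataFrame:
    """Read dyad annotations (BED6: name="geneID/+k", score=index, strand).

    Positions in column 2/3 follow BED (0-based half-open, width-1 interval);
    a 1-based single-position variant (start == end) is converted by taking
    ``position = start - 1``.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise BedParseError([(ln, "dyad BED needs 6 columns")])
            start, end = int(f[1]), int(f[2])
            pos = start if end == start + 1 else start - 1
            gene_id = f[3].split("/")[0]
            rows.append((f[0], pos, gene_id, int(f[4]), f[5]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "index", "strand"])


def write_tsv_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a labeled matrix as TSV with row and column headers."""
    matrix.to_csv(path, sep="\t", index=True)
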