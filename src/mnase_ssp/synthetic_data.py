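"""Synthetic MNase-digestion data: toy genome, digestion model, phenotypes.

The generator emulates the chromatin organisation interrogated by
MNase-based footprinting in budding yeast:

* genes carry a well-positioned array of nucleosomes downstream of the TSS
  (+1 dyad ~60 bp into the gene, subsequent dyads one spacing apart, up to
  +10), a −1 nucleosome upstream, and a nucleosome-depleted region (NDR)
  between −1 and +1 occupied by 1–3 short non-histone footprints;
* protected fragments fall into length classes — nucleosome (~147 bp),
  hexasome (~102–112 or ~83–93 bp, midpoint displaced toward the intact
  side by (147−len)/2), tetrasome (~61–71 bp), short NDR footprints
  (20–60 bp) and a uniform genomic background;
* nucleosome-class midpoints occupy rotational positions at 10 bp steps
  within ±30 bp of the dyad with occupancy decaying away from the dyad;
* MNase cleaves linker DNA 25× faster than nucleosome-protected DNA; ends
  receive a geometric "nibble" whose mean is 25-fold higher outside
  protected cores, and digestion dose (32U ↔ low, 128U ↔ high) controls
  nibbling depth, nucleosome-length spread, and NDR-footprint survival;
* mutant phenotypes are expressed as parameters: loss of NDR footprints at
  high dose (dose-dependent fragility), and redistribution of rotational
  occupancy one 10 bp step downstream with probability growing with
  nucleosome index and the gene-length quartile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .rotational_shift import stratify_by_length

__all__ = [
    "GenomeModel",
    "ConditionParams",
    "FragmentSet",
    "CLASS_NAMES",
    "DEFAULT_CLASS_WEIGHTS",
    "generate_genome",
    "simulate_digestion",
    "mutant_presets",
    "simulate_cut_positions",
    "estimate_cleavage_rate_ratio",
    "simulate_netseq",
    "write_genome",
    "read_genome",
    "params_to_yaml",
    "params_from_yaml",
]

CLASS_NAMES = ("nucleosome", "hexasome", "tetrasome", "ndr_short", "background")

DEFAULT_CLASS_WEIGHTS = {
    "nucleosome": 0.55,
    "hexasome": 0.15,
    "tetrasome": 0.08,
    "ndr_short": 0.10,
    "background": 0.12,
}

#: Rotational offsets that carry occupancy in the generator (bp, oriented).
ROT_OFFSETS = np.arange(-30, 31, 10)

_NUC_HALF = 73  # bp protected on each side of a nucleosome dyad


@dataclass
class GenomeModel:
    """A toy genome: chromosome sizes, genes, dyad annotations, NDR
    footprints.

    ``genes``: gene_id, chrom, tss, strand, length, start, end (body interval).
    ``dyads``: chrom, pos, gene_id, index (−1 or +1..+10), strand.
    ``ndr_footprints``: chrom, center, width, weight, gene_id.
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame
    dyads: pd.DataFrame
    ndr_footprints: pd.DataFrame

    def validate(self) -> None:
        for _, d in self.dyads.iterrows():
            size = self.chrom_sizes.get(d["chrom"])
            if size is None or not (0 <= d["pos"] < size):
                raise ValueError(f"dyad at {d['chrom']}:{d['pos']} out of bounds")
        genes = self.genes.set_index("gene_id")
        for gid, grp in self.dyads.groupby("gene_id"):
            sign = 1 if genes.loc[gid, "strand"] == "+" else -1
            ordered = grp.sort_values("index")
            pos = (ordered["pos"].to_numpy() * sign)
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"dyads of {gid} not ordered along strand")
            plus = sorted(ordered.loc[ordered["index"] >= 1, "index"])
            if plus != list(range(1, len(plus) + 1)):
                raise ValueError(f"nucleosome indices of {gid} not consecutive from +1")
        dyad_idx = self.dyads.set_index(["gene_id", "index"])["pos"]
        for _, f in self.ndr_footprints.iterrows():
            lo = dyad_idx[(f["gene_id"], -1)]
            hi = dyad_idx[(f["gene_id"], 1)]
            lo, hi = min(lo, hi), max(lo, hi)
            if not (lo < f["center"] < hi):
                raise ValueError(f"NDR footprint of {f['gene_id']} outside −1..+1 span")

    def dyad_count(self) -> int:
        return int((self.dyads["index"] >= 1).sum())


@dataclass
class ConditionParams:
    """Digestion and phenotype parameters for one simulated condition.

    ``shift_magnitude_bp`` maps nucleosome index → expected downstream
    midpoint displacement in bp; a magnitude m translates into moving m/10 of
    the rotational occupancy one 10 bp step downstream, scaled per gene by
    ``shift_length_coupling`` of its length quartile. When
    ``five_prime_shift_enabled`` is false, indices +1/+2 never shift.
    """

    ndr_protection_scale: float = 1.0
    shift_magnitude_bp: dict[int, float] = field(default_factory=dict)
    shift_length_coupling: dict[str, float] = field(
        default_factory=lambda: {"Q1": 1.0, "Q2": 1.0, "Q3": 1.0, "Q4": 1.0}
    )
    five_prime_shift_enabled: bool = False
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    mnase_dose: str = "high"  # {"low", "high"}; 32U vs 128U
    linker_rate_ratio: float = 25.0
    #: relative occupancy decay per 10 bp rotational step away from the dyad
    rotational_decay: float = 0.5
    #: mean geometric end-nibble (bp per end) inside protected cores, high dose
    core_nibble_mean: float = 0.02
    #: NDR footprint survival probability at low dose (fragility floor)
    low_dose_ndr_floor: float = 0.9

    def validate(self) -> None:
        if set(self.class_weights) != set(CLASS_NAMES):
            raise ValueError(f"class_weights must have keys {CLASS_NAMES}")
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_weights sum to {total}, expected 1")
        if not 0.0 <= self.ndr_protection_scale <= 1.0:
            raise ValueError("ndr_protection_scale must lie in [0, 1]")
        if self.linker_rate_ratio <= 1:
            raise ValueError("linker_rate_ratio must exceed 1")
        if self.mnase_dose not in ("low", "high"):
            raise ValueError("mnase_dose must be 'low' or 'high'")
        if not 0 < self.rotational_decay <= 1:
            raise ValueError("rotational_decay must lie in (0, 1]")


@dataclass
class FragmentSet:
    """Simulated MNase-protected fragments for one sample."""

    frags: pd.DataFrame
    sample_id: str
    seed: int

    def __len__(self) -> int:
        return len(self.frags)


def generate_genome(
    n_genes: int,
    seed: int,
    spacing_bp: int = 165,
    ndr_width_bp: int = 140,
    genes_per_chrom: int = 50,
) -> GenomeModel:
    """Build a toy genome with nucleosome arrays, NDRs, and both strands.

    Gene lengths are log-normal (median ~1.8 kb, clipped to 0.5–8 kb) so
    length quartiles are non-degenerate. Each gene gets a −1 dyad, an NDR
    with 1–3 short footprints between the −1 and +1 nucleosomes, and +1..+K
    dyads with K set by gene length at the given spacing (capped at +10).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if spacing_bp < 147:
        raise ValueError("spacing_bp must be >= 147")
    if ndr_width_bp < 80:
        raise ValueError("ndr_width_bp must be >= 80")
    rng = np.random.default_rng(seed)

    pad = ndr_width_bp + 160  # room upstream of the TSS for −1 dyad + NDR
    gap = 300

    chrom_sizes: dict[str, int] = {}
    gene_rows, dyad_rows, ndr_rows = [], [], []
    width_id = len(str(n_genes))

    cursor = 0
    chrom_i = 1
    chrom = f"chr{chrom_i:02d}"
    for i in range(n_genes):
        if i > 0 and i % genes_per_chrom == 0:
            chrom_sizes[chrom] = cursor + gap
            chrom_i += 1
            chrom = f"chr{chrom_i:02d}"
            cursor = 0
        gid = f"gene{i + 1:0{width_id}d}"
        length = int(np.clip(rng.lognormal(np.log(1800), 0.65), 500, 8000))
        strand = "+" if rng.random() < 0.5 else "-"
        sign = 1 if strand == "+" else -1
        body_start = cursor + pad
        body_end = body_start + length
        tss = body_start if strand == "+" else body_end - 1

        n_nuc = max(1, min(10, (length - 60 - (_NUC_HALF + 1)) // spacing_bp + 1))
        for k in range(1, n_nuc + 1):
            dyad_rows.append((chrom, tss + sign * (60 + (k - 1) * spacing_bp), gid, k, strand))
        minus1_off = -(86 + ndr_width_bp)
        dyad_rows.append((chrom, tss + sign * minus1_off, gid, -1, strand))

        # NDR spans oriented offsets [minus1_off + 73, 60 - 73]
        ndr_lo, ndr_hi = minus1_off + _NUC_HALF, 60 - _NUC_HALF
        for _ in range(int(rng.integers(1, 4))):
            width = int(rng.integers(20, 51))
            margin = width // 2 + 1
            c_off = int(rng.integers(ndr_lo + margin, ndr_hi - margin + 1))
            ndr_rows.append(
                (chrom, tss + sign * c_off, width, float(rng.uniform(0.5, 1.5)), gid)
            )

        gene_rows.append((gid, chrom, tss, strand, length, body_start, body_end))
        cursor = body_end + gap
    chrom_sizes[chrom] = cursor + gap

    genome = GenomeModel(
        chrom_sizes=chrom_sizes,
        genes=pd.DataFrame(
            gene_rows,
            columns=["gene_id", "chrom", "tss", "strand", "length", "start", "end"],
        ),
        dyads=pd.DataFrame(
            dyad_rows, columns=["chrom", "pos", "gene_id", "index", "strand"]
        ),
        ndr_footprints=pd.DataFrame(
            ndr_rows, columns=["chrom", "center", "width", "weight", "gene_id"]
        ),
    )
    return genome


def mutant_presets(name: str) -> ConditionParams:
    """Condition parameters for the wild-type and the two mutant phenotypes.

    * ``WT`` — full NDR protection, no positioning shifts.
    * ``K192N`` — NDR short-footprint protection nearly lost at high dose
      (retained at low dose), downstream rotational shifts only at
      nucleosome indices ≥ 3, growing with index and gene length.
    * ``141-305`` — NDR intact; shifts at all indices including +1/+2
      (``five_prime_shift_enabled``), with larger magnitudes.
    """
    coupling = {"Q1": 0.3, "Q2": 0.7, "Q3": 1.3, "Q4": 2.0}
    if name == "WT":
        return ConditionParams()
    if name == "K192N":
        return ConditionParams(
            ndr_protection_scale=0.05,
            shift_magnitude_bp={k: 1.0 + 0.5 * (k - 3) for k in range(3, 11)},
            shift_length_coupling=dict(coupling),
            five_prime_shift_enabled=False,
        )
    if name == "141-305":
        return ConditionParams(
            ndr_protection_scale=1.0,
            shift_magnitude_bp={k: 1.5 + 0.5 * (k - 1) for k in range(1, 11)},
            shift_length_coupling=dict(coupling),
            five_prime_shift_enabled=True,
        )
    raise ValueError(f"unknown preset {name!r}; expected WT, K192N, or 141-305")


def _geom_nibble(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    """Geometric end-nibble with the given mean (support 0, 1, 2, ...)."""
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    p = 1.0 / (1.0 + mean)
    return rng.geometric(p, size=n) - 1


def _rotational_weights(decay: float) -> np.ndarray:
    w = decay ** np.abs(ROT_OFFSETS // 10)
    return w / w.sum()


def simulate_digestion(
    genome: GenomeModel,
    params: ConditionParams,
    n_fragments: int,
    seed: int,
    sample_id: str = "sample",
) -> FragmentSet:
    """Draw MNase-protected fragments from the class mixture.

    One seed governs the whole simulation through a splittable generator;
    each class consumes its own substream so class counts and placements are
    independent of each other's draws. Output rows are sorted by coordinate
    and carry a ``frag_class`` column.
    """
    params.validate()
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if len(genome.genes) == 0 or genome.dyad_count() == 0:
        raise ValueError("genome has no genes/dyads to digest")

    root = np.random.SeedSequence(seed)
    ss_counts, ss_nuc, ss_hex, ss_tet, ss_ndr, ss_bg = root.spawn(6)
    weights = np.array([params.class_weights[c] for c in CLASS_NAMES])
    counts = np.random.default_rng(ss_counts).multinomial(n_fragments, weights)
    count_of = dict(zip(CLASS_NAMES, counts))

    # --- dyad-level arrays shared by the positioned classes -----------------
    dyads = genome.dyads[genome.dyads["index"] >= 1].reset_index(drop=True)
    dpos = dyads["pos"].to_numpy()
    dsign = np.where(dyads["strand"].to_numpy() == "+", 1, -1)
    dindex = dyads["index"].to_numpy()
    quartiles = stratify_by_length(genome.genes, k=min(4, len(genome.genes)))
    coupling = np.array(
        [
            params.shift_length_coupling.get(quartiles.assignment[g], 1.0)
            for g in dyads["gene_id"]
        ]
    )
    mag = np.array([params.shift_magnitude_bp.get(int(k), 0.0) for k in dindex])
    if not params.five_prime_shift_enabled:
        mag = np.where(dindex < 3, 0.0, mag)
    p_shift = np.clip(mag / 10.0 * coupling, 0.0, 1.0)
    dchrom = dyads["chrom"].to_numpy()
    rot_w = _rotational_weights(params.rotational_decay)

    high = params.mnase_dose == "high"
    nuc_sigma, nuc_clip = (3.0, (142, 152)) if high else (5.0, (137, 157))
    core_nibble = params.core_nibble_mean * (1.0 if high else 10.0)
    linker_nibble = core_nibble * params.linker_rate_ratio

    def positioned(rng, n, length_sampler):
        """Fragments anchored at dyads with rotational offsets and shifts."""
        di = rng.integers(0, len(dpos), n)
        r = ROT_OFFSETS[rng.choice(ROT_OFFSETS.size, n, p=rot_w)]
        r = r + 10 * (rng.random(n) < p_shift[di])
        lens, disp = length_sampler(rng, n)
        mid = dpos[di] + dsign[di] * (r + disp)
        start = mid - lens // 2
        end = start + lens
        nib1 = _geom_nibble(rng, n, core_nibble)
        nib2 = _geom_nibble(rng, n, core_nibble)
        max_nib = (lens - 1) // 2
        start = start + np.minimum(nib1, max_nib)
        end = end - np.minimum(nib2, max_nib)
        return pd.DataFrame(
            {"chrom": dchrom[di], "start": start, "end": end, "strand": "."}
        )

    def nuc_lengths(rng, n):
        lens = np.clip(
            np.rint(rng.normal(147.0, nuc_sigma, n)), *nuc_clip
        ).astype(np.int64)
        return lens, np.zeros(n, dtype=np.int64)

    def hex_lengths(rng, n):
        in_upper = rng.random(n) < 0.5
        lens = np.where(
            in_upper, rng.integers(102, 113, n), rng.integers(83, 94, n)
        ).astype(np.int64)
        side = np.where(rng.random(n) < 0.5, 1, -1)  # proximal vs distal dimer loss
        disp = side * np.rint((147 - lens) / 2).astype(np.int64)
        return lens, disp

    def tet_lengths(rng, n):
        lens = rng.integers(61, 72, n).astype(np.int64)
        side = np.where(rng.random(n) < 0.5, 1, -1)
        disp = side * np.rint((147 - lens) / 2).astype(np.int64)
        return lens, disp

    parts = []

    n = count_of["nucleosome"]
    if n:
        df = positioned(np.random.default_rng(ss_nuc), n, nuc_lengths)
        df["frag_class"] = "nucleosome"
        parts.append(df)

    n = count_of["hexasome"]
    if n:
        df = positioned(np.random.default_rng(ss_hex), n, hex_lengths)
        df["frag_class"] = "hexasome"
        parts.append(df)

    n = count_of["tetrasome"]
    if n:
        df = positioned(np.random.default_rng(ss_tet), n, tet_lengths)
        df["frag_class"] = "tetrasome"
        parts.append(df)

    n = count_of["ndr_short"]
    if n and len(genome.ndr_footprints):
        rng = np.random.default_rng(ss_ndr)
        fp = genome.ndr_footprints
        probs = fp["weight"].to_numpy()
        probs = probs / probs.sum()
        fi = rng.choice(len(fp), n, p=probs)
        lens = rng.integers(20, 61, n)
        mid = fp["center"].to_numpy()[fi] + rng.integers(-3, 4, n)
        start = mid - lens // 2
        end = start + lens
        emit_p = (
            params.ndr_protection_scale
            if high
            else max(params.ndr_protection_scale, params.low_dose_ndr_floor)
        )
        keep = rng.random(n) < emit_p
        df = pd.DataFrame(
            {
                "chrom": fp["chrom"].to_numpy()[fi],
                "start": start,
                "end": end,
                "strand": ".",
            }
        ).loc[keep]
        df["frag_class"] = "ndr_short"
        parts.append(df)

    n = count_of["background"]
    if n:
        rng = np.random.default_rng(ss_bg)
        chroms = list(genome.chrom_sizes)
        sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
        ci = rng.choice(len(chroms), n, p=sizes / sizes.sum())
        lens = rng.integers(35, 171, n)
        start = (rng.random(n) * (sizes[ci] - lens)).astype(np.int64)
        end = start + lens
        nib1 = _geom_nibble(rng, n, linker_nibble)
        nib2 = _geom_nibble(rng, n, linker_nibble)
        max_nib = (lens - 1) // 2
        start = start + np.minimum(nib1, max_nib)
        end = end - np.minimum(nib2, max_nib)
        df = pd.DataFrame(
            {
                "chrom": np.asarray(chroms, dtype=object)[ci],
                "start": start,
                "end": end,
                "strand": ".",
            }
        )
        df["frag_class"] = "background"
        parts.append(df)

    frags = pd.concat(parts, ignore_index=True)
    frags = frags.sort_values(
        ["chrom", "start", "end", "frag_class"], kind="stable"
    ).reset_index(drop=True)
    frags["start"] = frags["start"].astype(np.int64)
    frags["end"] = frags["end"].astype(np.int64)
    return FragmentSet(frags=frags, sample_id=sample_id, seed=seed)


def _core_linker_positions(genome: GenomeModel):
    """Genome-wide nucleosome-core mask split into core/linker position lists."""
    core_pos, linker_pos, chrom_codes_core, chrom_codes_linker = [], [], [], []
    chroms = list(genome.chrom_sizes)
    for ci, chrom in enumerate(chroms):
        size = genome.chrom_sizes[chrom]
        mask = np.zeros(size, dtype=bool)
        for _, d in genome.dyads[genome.dyads["chrom"] == chrom].iterrows():
            lo = max(0, d["pos"] - _NUC_HALF)
            hi = min(size, d["pos"] + _NUC_HALF + 1)
            mask[lo:hi] = True
        cp = np.flatnonzero(mask)
        lp = np.flatnonzero(~mask)
        core_pos.append(cp)
        linker_pos.append(lp)
        chrom_codes_core.append(np.full(cp.size, ci, dtype=np.int32))
        chrom_codes_linker.append(np.full(lp.size, ci, dtype=np.int32))
    return (
        chroms,
        np.concatenate(core_pos),
        np.concatenate(linker_pos),
        np.concatenate(chrom_codes_core),
        np.concatenate(chrom_codes_linker),
    )


def simulate_cut_positions(
    genome: GenomeModel,
    n_cuts: int,
    seed: int,
    linker_rate_ratio: float = 25.0,
) -> pd.DataFrame:
    """Simulate MNase cut events: per-bp cleavage rate is
    ``linker_rate_ratio``-fold higher in linker than inside nucleosome cores
    (dyad ± 73 bp). Returns a DataFrame (chrom, pos)."""
    if n_cuts < 1:
        raise ValueError("n_cuts must be >= 1")
    chroms, core, linker, cc, cl = _core_linker_positions(genome)
    rng = np.random.default_rng(seed)
    w_linker = linker_rate_ratio * linker.size
    w_core = float(core.size)
    n_linker = rng.binomial(n_cuts, w_linker / (w_linker + w_core))
    li = rng.integers(0, linker.size, n_linker)
    ki = rng.integers(0, core.size, n_cuts - n_linker)
    pos = np.concatenate([linker[li], core[ki]])
    code = np.concatenate([cl[li], cc[ki]])
    return pd.DataFrame(
        {"chrom": np.asarray(chroms, dtype=object)[code], "pos": pos}
    )


def estimate_cleavage_rate_ratio(cuts: pd.DataFrame, genome: GenomeModel) -> float:
    """Estimate the linker:core per-bp cut-rate ratio from cut positions."""
    chroms, core, linker, cc, cl = _core_linker_positions(genome)
    n_core = 0
    for ci, chrom in enumerate(chroms):
        size = genome.chrom_sizes[chrom]
        mask = np.zeros(size, dtype=bool)
        mask[core[cc == ci]] = True
        sub = cuts.loc[cuts["chrom"] == chrom, "pos"].to_numpy()
        n_core += int(mask[sub].sum())
    n_linker = len(cuts) - n_core
    if n_core == 0:
        raise ValueError("no cuts landed in nucleosome cores; cannot estimate")
    rate_core = n_core / core.size
    rate_linker = n_linker / linker.size
    return rate_linker / rate_core


def simulate_netseq(
    genome: GenomeModel, seed: int, mean_rate: float = 0.05
) -> dict[str, np.ndarray]:
    """Per-bp nascent-transcription counts: each gene body gets Poisson counts
    at a gene-specific log-normal rate (used for expression stratification)."""
    rng = np.random.default_rng(seed)
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in genome.chrom_sizes.items()}
    for _, g in genome.genes.iterrows():
        rate = mean_rate * rng.lognormal(0.0, 1.0)
        body = counts[g["chrom"]][g["start"] : g["end"]]
        body += rng.poisson(rate, size=body.size)
    return counts


# --- file interfaces --------------------------------------------------------


def write_genome(genome: GenomeModel, outdir) -> dict[str, Path]:
    """Write genome annotations as plain-text BED/TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "genes": outdir / "genes.bed",
        "dyads": outdir / "dyads.bed",
        "ndr": outdir / "ndr_footprints.bed",
    }
    with open(paths["chrom_sizes"], "w") as fh:
        for c, n in genome.chrom_sizes.items():
            fh.write(f"{c}\t{n}\n")
    with open(paths["genes"], "w") as fh:
        for _, g in genome.genes.iterrows():
            fh.write(
                f"{g['chrom']}\t{g['start']}\t{g['end']}\t{g['gene_id']}"
                f"\t{g['length']}\t{g['strand']}\n"
            )
    with open(paths["dyads"], "w") as fh:
        for _, d in genome.dyads.iterrows():
            k = d["index"]
            fh.write(
                f"{d['chrom']}\t{d['pos']}\t{d['pos'] + 1}\t{d['gene_id']}/"
                f"{'+' if k > 0 else ''}{k}\t{k}\t{d['strand']}\n"
            )
    with open(paths["ndr"], "w") as fh:
        for _, f in genome.ndr_footprints.iterrows():
            half = f["width"] // 2
            fh.write(
                f"{f['chrom']}\t{f['center'] - half}"
                f"\t{f['center'] - half + f['width']}\t{f['gene_id']}\n"
            )
    return paths


def read_genome(indir) -> GenomeModel:
    """Read genome annotations written by :func:`write_genome`."""
    indir = Path(indir)
    chrom_sizes = {}
    with open(indir / "chrom.sizes") as fh:
        for line in fh:
            c, n = line.split("\t")
            chrom_sizes[c] = int(n)
    genes = pd.read_csv(
        indir / "genes.bed",
        sep="\t",
        names=["chrom", "start", "end", "gene_id", "length", "strand"],
    )
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    genes = genes[["gene_id", "chrom", "tss", "strand", "length", "start", "end"]]
    dyads = pd.read_csv(
        indir / "dyads.bed",
        sep="\t",
        names=["chrom", "start", "end", "name", "index", "strand"],
    )
    dyads["gene_id"] = dyads["name"].str.split("/").str[0]
    dyads["pos"] = dyads["start"]
    dyads = dyads[["chrom", "pos", "gene_id", "index", "strand"]]
    ndr = pd.read_csv(
        indir / "ndr_footprints.bed",
        sep="\t",
        names=["chrom", "start", "end", "gene_id"],
    )
    ndr["width"] = ndr["end"] - ndr["start"]
    ndr["center"] = ndr["start"] + ndr["width"] // 2
    ndr["weight"] = 1.0
    ndr = ndr[["chrom", "center", "width", "weight", "gene_id"]]
    return GenomeModel(chrom_sizes, genes, dyads, ndr)


def params_to_yaml(params: ConditionParams, path) -> None:
    d = asdict(params)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def params_from_yaml(path) -> ConditionParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "shift_magnitude_bp" in d and d["shift_magnitude_bp"]:
        d["shift_magnitude_bp"] = {int(k): float(v) for k, v in d["shift_magnitude_bp"].items()}
    p = ConditionParams(**d)
    p.validate()
    return p
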