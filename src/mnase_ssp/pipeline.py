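"""End-to-end orchestration: simulate → coverage → metaplots → shift-test.

Stages communicate only through files (BED / bedGraph / TSV) so any stage can
be fed real fragment data in place of the simulator without code changes. A
manifest records inputs, a parameter hash, and output checksums; re-running
with an identical config reproduces identical checksums for deterministic
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coverage as cov
from . import metaplots as mp
from . import rotational_shift as rs
from . import synthetic_data as synth
from .fragments_io import read_fragments_bed, write_bedgraph, write_fragments_bed

logger = logging.getLogger(__name__)

STAGES = ["simulate", "coverage", "vplot", "profile", "heatmap", "shift-test"]

KNOWN_KEYS = {
    "seed",
    "outdir",
    "simulate",
    "bins",
    "vplot",
    "profile",
    "heatmap",
    "shift_test",
}


@dataclass
class ConfigReport:
    valid: bool
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    """Validated run configuration (see examples/demo.yaml)."""

    seed: int
    outdir: Path
    simulate: dict
    bins: dict[str, cov.LengthBin]
    vplot: dict
    profile: dict
    heatmap: dict
    shift_test: dict
    raw: dict = field(default_factory=dict)


def _parse_bin(label: str, spec: str) -> cov.LengthBin:
    lo, hi = str(spec).split(":")
    return cov.LengthBin(int(lo), int(hi), label)


def validate_config(path) -> ConfigReport:
    """Check a YAML config: unknown keys warn, structural problems error."""
    errors: list[str] = []
    warnings: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        return ConfigReport(False, [f"cannot read config: {exc}"])
    if not isinstance(raw, dict):
        return ConfigReport(False, ["config must be a YAML mapping"])
    for key in raw:
        if key not in KNOWN_KEYS:
            warnings.append(f"unknown key {key!r} ignored")
    if "seed" not in raw:
        errors.append("missing 'seed'")
    for label, spec in (raw.get("bins") or {}).items():
        try:
            _parse_bin(label, spec)
        except ValueError as exc:
            errors.append(f"bin {label!r}: {exc}")
    sim = raw.get("simulate") or {}
    if sim and sim.get("n_genes", 1) < 1:
        errors.append("simulate.n_genes must be >= 1")
    for sample in sim.get("samples", ["WT"]):
        try:
            synth.mutant_presets(str(sample))
        except ValueError as exc:
            errors.append(str(exc))
    return ConfigReport(not errors, errors, warnings)


def load_config(path) -> RunConfig:
    report = validate_config(path)
    for w in report.warnings:
        logger.warning("%s", w)
    if not report.valid:
        raise ValueError("invalid config: " + "; ".join(report.errors))
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    bins = {
        label: _parse_bin(label, spec)
        for label, spec in (raw.get("bins") or {"short": "0:60"}).items()
    }
    return RunConfig(
        seed=int(raw["seed"]),
        outdir=Path(raw.get("outdir", "out")),
        simulate=raw.get("simulate") or {},
        bins=bins,
        vplot=raw.get("vplot") or {},
        profile=raw.get("profile") or {},
        heatmap=raw.get("heatmap") or {},
        shift_test=raw.get("shift_test") or {},
        raw=raw,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class MissingArtifactError(RuntimeError):
    """An upstream stage's output is missing; names the stage to run first."""


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing {path.name}; run the '{producer}' stage first"
        )
    return path


def run(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    stages = STAGES if stages is None else [s for s in STAGES if s in set(stages)]
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    phash = _params_hash(config.raw)
    manifest: dict = {"parameter_hash": phash, "seed": config.seed, "outputs": {}}

    def record(path: Path):
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    sim = config.simulate
    samples = [str(s) for s in sim.get("samples", ["WT", "K192N", "141-305"])]
    genome_dir = out / "genome"

    if "simulate" in stages:
        logger.info("stage=simulate seed=%d hash=%s", config.seed, phash)
        genome = synth.generate_genome(
            n_genes=int(sim.get("n_genes", 50)),
            seed=config.seed,
            spacing_bp=int(sim.get("spacing_bp", 165)),
            ndr_width_bp=int(sim.get("ndr_width_bp", 140)),
        )
        for p in synth.write_genome(genome, genome_dir).values():
            record(p)
        n_frag = int(sim.get("n_fragments", 20000))
        for i, name in enumerate(samples):
            params = synth.mutant_presets(name)
            dose = sim.get("mnase_dose")
            if dose:
                params.mnase_dose = str(dose)
            fs = synth.simulate_digestion(
                genome, params, n_frag, seed=config.seed + 1 + i, sample_id=name
            )
            path = out / f"fragments_{name}.bed"
            write_fragments_bed(fs.frags, path, name=name)
            record(path)
            synth.params_to_yaml(params, out / f"params_{name}.yaml")
            record(out / f"params_{name}.yaml")

    if set(stages) & {"coverage", "vplot", "profile", "heatmap", "shift-test"}:
        _require(genome_dir / "chrom.sizes", "simulate")
        genome = synth.read_genome(genome_dir)
        frags = {}
        for name in samples:
            path = _require(out / f"fragments_{name}.bed", "simulate")
            frags[name] = read_fragments_bed(path, genome.chrom_sizes)

    if "coverage" in stages:
        logger.info("stage=coverage seed=%d hash=%s", config.seed, phash)
        for name, df in frags.items():
            nf = cov.normalization_factor(len(df))
            for label, lbin in config.bins.items():
                kept = cov.filter_by_length(df, lbin)
                logger.info("sample=%s bin=%s fragments=%d", name, label, len(kept))
                track = cov.fragment_coverage(df, genome.chrom_sizes, lbin, nf)
                path = out / f"coverage_{name}_{label}.bedgraph"
                write_bedgraph(track, path)
                record(path)
                mtrack = cov.midpoint_coverage(df, genome.chrom_sizes, lbin, nf)
                path = out / f"midpoints_{name}_{label}.bedgraph"
                write_bedgraph(mtrack, path)
                record(path)

    if "vplot" in stages:
        logger.info("stage=vplot seed=%d hash=%s", config.seed, phash)
        roles = config.vplot.get("anchors", [1, 2, 5])
        lo, hi = str(config.vplot.get("length_range", "35:170")).split(":")
        for name, df in frags.items():
            for role in roles:
                anchors = mp.dyad_anchors(genome, [int(role)])
                vp = mp.build_vplot(
                    df,
                    anchors,
                    max_offset=int(config.vplot.get("max_offset", 500)),
                    length_range=(int(lo), int(hi)),
                )
                path = out / f"vplot_{name}_dyad{role}.tsv"
                vp.counts.to_csv(path, sep="\t")
                record(path)

    if "profile" in stages:
        logger.info("stage=profile seed=%d hash=%s", config.seed, phash)
        label = config.profile.get("bin", "short")
        lbin = config.bins[label]
        anchors = mp.dyad_anchors(genome, [1])
        for name, df in frags.items():
            prof = mp.metagene_profile(
                df,
                anchors,
                flank=int(config.profile.get("flank", 1000)),
                length_bin=lbin,
                mode=config.profile.get("mode", "overlap"),
                chrom_sizes=genome.chrom_sizes,
            )
            path = out / f"profile_{name}_{label}.tsv"
            prof.rename_axis("offset").to_csv(path, sep="\t")
            record(path)

    if "heatmap" in stages:
        logger.info("stage=heatmap seed=%d hash=%s", config.seed, phash)
        label = config.heatmap.get("bin", "short")
        lbin = config.bins[label]
        flank = int(config.heatmap.get("flank", 500))
        maps = {
            name: mp.occupancy_heatmap(df, genome, lbin, flank)
            for name, df in frags.items()
        }
        wt_name = samples[0]
        for name, hm in maps.items():
            path = out / f"heatmap_{name}_{label}.tsv"
            hm.matrix.to_csv(path, sep="\t")
            record(path)
            if name != wt_name:
                diff = mp.difference_matrix(hm, maps[wt_name])
                path = out / f"heatmap_diff_{name}-{wt_name}_{label}.tsv"
                diff.to_csv(path, sep="\t")
                record(path)

    if "shift-test" in stages:
        logger.info("stage=shift-test seed=%d hash=%s", config.seed, phash)
        label = config.shift_test.get("bin", "nucleosome")
        lbin = config.bins.get(label, cov.STANDARD_BINS["nucleosome"])
        alpha = float(config.shift_test.get("alpha", 0.05))
        min_genes = int(config.shift_test.get("min_genes", 10))
        dyads = mp.dyad_anchors(genome)
        ztabs = {}
        for name, df in frags.items():
            nf = cov.normalization_factor(len(df))
            track = cov.midpoint_coverage(df, genome.chrom_sizes, lbin, nf)
            ztabs[name] = rs.zscore_rows(rs.rotational_occupancy(track, dyads, lbin))
        wt_name = samples[0]
        strat = rs.stratify_by_length(genome.genes)
        stratify = config.shift_test.get("stratify", "length")
        for name in samples[1:]:
            parts = []
            res = rs.shift_test(
                ztabs[name], ztabs[wt_name], alpha=alpha, min_genes=min_genes
            )
            res.table.insert(0, "quartile", "all")
            parts.append(res.table)
            if stratify:
                for q in strat.labels:
                    try:
                        r = rs.shift_test(
                            ztabs[name],
                            ztabs[wt_name],
                            gene_subset=strat.quartile(q),
                            alpha=alpha,
                            min_genes=min_genes,
                        )
                    except ValueError:
                        continue
                    r.table.insert(0, "quartile", q)
                    parts.append(r.table)
            path = out / f"shift_{name}-{wt_name}_{label}.tsv"
            pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)
            record(path)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
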