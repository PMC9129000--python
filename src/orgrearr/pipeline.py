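"""End-to-end pipeline orchestration: simulate -> align -> scan -> junctions
-> quantify, with a reproducible run manifest.

A run is described by a :class:`RunConfig` (YAML-loadable) naming exactly one
input source -- a simulation block, a FASTQ pair, or a SAM file -- plus the
genome, the per-stage parameter blocks, an output directory and a seed.
Every intermediate (FASTQ, SAM, coverage and junction tables, crossover
tables) is written to the output directory, and a manifest JSON records the
package version, seed, parameters and the SHA-256 checksum of every output,
so identical config + seed gives identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clipjunction import (
    call_junctions,
    events_per_genome_copy,
    extract_clips,
    filter_isomerization,
    map_clips,
    write_events,
)
from .covscan import bin_coverage, compare_profiles
from .microalign import AlignParams, align_pairs, read_sam, write_sam
from .repeatome import (
    CircularGenome,
    find_exact_repeats,
    read_fasta,
    write_fasta,
    write_repeat_table,
)
from .simlib import (
    LibraryParams,
    SubgenomeSpec,
    build_mixture,
    make_test_genome,
    simulate_reads,
    write_fastq,
)
from .xoverquant import classify_spanning_pairs, relative_accumulation, write_quant_table

log = logging.getLogger("orgrearr")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run description; see ``demo_config`` for a worked example."""

    genome: str | dict  # FASTA path or {"toy": {length, seed, repeat_plan}}
    outdir: str
    seed: int = 0
    mode: str = "mtDNA-like"  # or "cpDNA-like" (enables isomerization filtering)
    simulate: dict | None = None  # {"specs": [...], "depth": .., "error_rate": ..}
    control: dict | None = None  # same shape as simulate (weight-0 control if {})
    fastq: list | None = None  # [r1, r2]
    sam: str | None = None
    min_repeat_len: int = 50
    align: dict = field(default_factory=dict)
    flag_threshold: float = 1.0
    crossover_repeats: list = field(default_factory=list)  # repeat ids to quantify
    crossover_flank: int = 300
    # normalization total for coverage profiles; None = actual library read
    # count.  Simulated libraries are purely organellar, so sample/control
    # comparisons should use a common nominal total (in real data the library
    # total is dominated by an unchanged nuclear background)
    normalize_total: int | None = None

    def __post_init__(self) -> None:
        sources = [s is not None for s in (self.simulate, self.fastq, self.sam)]
        if sum(sources) != 1:
            raise ConfigError(
                "exactly one input source (simulate | fastq | sam) must be given"
            )
        if self.mode not in ("mtDNA-like", "cpDNA-like"):
            raise ConfigError(f"unknown mode: {self.mode}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _load_genome(spec) -> tuple[CircularGenome, list]:
    if isinstance(spec, dict) and "toy" in spec:
        t = spec["toy"]
        plan = [tuple(p) for p in t.get("repeat_plan", [])]
        return make_test_genome(t["length"], t["seed"], plan, t.get("name", "toy"))
    genomes = read_fasta(spec)
    if len(genomes) != 1:
        raise ConfigError("exactly one genome record expected")
    return genomes[0], []


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _parse_specs(block: dict) -> list[SubgenomeSpec]:
    out = []
    for s in block.get("specs", []):
        s = dict(s)
        if "breakpoints" in s and s["breakpoints"] is not None:
            s["breakpoints"] = tuple(s["breakpoints"])
        out.append(SubgenomeSpec(**s))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the manifest (also written to the output
    directory).  Stage failures raise with the stage name; outputs written
    before the failure are left in place."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "stages": {},
        "outputs": {},
        "metrics": {},
    }
    stage = "setup"
    try:
        genome, planted = _load_genome(config.genome)
        write_fasta([genome], outdir / "genome.fasta")

        stage = "repeats"
        ts = time.time()
        repeats = find_exact_repeats(genome, config.min_repeat_len)
        # keep planted labels where the planted pair was recovered (a maximal
        # repeat can extend a base or two past the planted copy by chance)
        def _label(r):
            for p in planted:
                if (
                    p.orientation == r.orientation
                    and abs(p.copy1.start - r.copy1.start) <= 5
                    and abs(p.copy2.start - r.copy2.start) <= 5
                    and abs(p.rep_length - r.rep_length) <= 10
                ):
                    return type(r)(p.id, r.copy1, r.copy2, r.orientation, r.rep_length)
            return r

        repeats = [_label(r) for r in repeats]
        write_repeat_table(repeats, outdir / "repeats.tsv")
        manifest["stages"]["repeats"] = {"seconds": round(time.time() - ts, 2),
                                         "n_repeats": len(repeats)}

        stage = "input"
        ts = time.time()
        sams = {}
        if config.simulate is not None:
            for label, block in (("sample", config.simulate), ("control", config.control)):
                if block is None:
                    continue
                specs = _parse_specs(block)
                mixture, truth = build_mixture(genome, specs, repeats, label)
                params = LibraryParams(
                    depth=block.get("depth", 30.0),
                    seed=config.seed + (0 if label == "sample" else 1),
                    error_rate=block.get("error_rate", 0.002),
                )
                r1, r2 = simulate_reads(mixture, params, sample_label=label)
                write_fastq(r1, outdir / f"{label}_R1.fastq")
                write_fastq(r2, outdir / f"{label}_R2.fastq")
                truth.to_json(outdir / f"{label}_truth.json")
                sams[label] = (outdir / f"{label}_R1.fastq", outdir / f"{label}_R2.fastq")
        elif config.fastq is not None:
            sams["sample"] = (Path(config.fastq[0]), Path(config.fastq[1]))
        manifest["stages"]["input"] = {"seconds": round(time.time() - ts, 2)}

        stage = "align"
        ts = time.time()
        align_params = AlignParams(**config.align)
        records = {}
        if config.sam is not None:
            records["sample"] = read_sam(config.sam, ref_name=genome.name)
        else:
            for label, (f1, f2) in sams.items():
                recs = align_pairs(genome, f1, f2, align_params, tie_seed=config.seed)
                write_sam(recs, genome, outdir / f"{label}.sam")
                records[label] = recs
        manifest["stages"]["align"] = {"seconds": round(time.time() - ts, 2)}

        stage = "coverage"
        ts = time.time()
        profiles = {}
        for label, recs in records.items():
            total = config.normalize_total or len(recs)
            prof = bin_coverage(recs, genome.length, total, genome.name)
            prof.to_tsv(outdir / f"{label}_coverage.tsv")
            profiles[label] = prof
        if "sample" in profiles and "control" in profiles:
            report = compare_profiles(
                profiles["sample"], profiles["control"], config.flag_threshold, repeats
            )
            report.to_tsv(outdir / "stoichiometry.tsv")
            manifest["metrics"]["flagged_regions"] = [
                {
                    "start_bin": r.start_bin,
                    "end_bin": r.end_bin,
                    "mean_log2": round(r.mean_log2, 3),
                    "repeat_ids": list(r.repeat_ids),
                }
                for r in report.regions
            ]
        manifest["stages"]["coverage"] = {"seconds": round(time.time() - ts, 2)}

        stage = "junctions"
        ts = time.time()
        clips, clip_stats = extract_clips(records["sample"])
        placed, map_stats = map_clips(clips, genome, align_params)
        events = call_junctions(placed)
        irs = repeats if config.mode == "cpDNA-like" else []
        events = filter_isomerization(events, irs)
        write_events(events, outdir / "junctions.tsv")
        (outdir / "junction_stats.json").write_text(
            json.dumps({"clip_filter": clip_stats, "clip_mapping": map_stats}, indent=1)
        )
        kept = [e for e in events if not e.is_isomerization]
        manifest["metrics"]["junction_events"] = len(kept)
        manifest["metrics"]["events_per_genome_copy"] = (
            round(events_per_genome_copy(events, profiles["sample"]), 4)
            if profiles.get("sample") is not None
            else None
        )
        manifest["stages"]["junctions"] = {
            "seconds": round(time.time() - ts, 2),
            **clip_stats,
            **{f"clip_{k}": v for k, v in map_stats.items()},
        }

        stage = "crossovers"
        ts = time.time()
        if config.crossover_repeats and "control" in records:
            by_id = {r.id: r for r in repeats}
            reports = []
            for rid in config.crossover_repeats:
                rep = by_id[rid]
                sc = classify_spanning_pairs(
                    records["sample"], rep, config.crossover_flank, genome.length
                )
                cc = classify_spanning_pairs(
                    records["control"], rep, config.crossover_flank, genome.length
                )
                reports.append(relative_accumulation(sc, cc))
            write_quant_table(reports, outdir / "crossovers.tsv")
            manifest["metrics"]["crossover_log2"] = {
                r.repeat_id: {k: round(v, 3) for k, v in r.log2.items()} for r in reports
            }
        manifest["stages"]["crossovers"] = {"seconds": round(time.time() - ts, 2)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    manifest["total_seconds"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def demo_config(outdir: str | Path, seed: int = 0) -> RunConfig:
    """A recombination-surveillance demo: toy 100-kb genome carrying direct
    repeat pairs of 556/350/249/127/60 bp; the sample library amplifies the
    loop-out circle of the 127-bp pair seven-fold, adds the 60-bp loop-out at
    weight 1 and a chimeric circle, and is compared against a clean control."""
    return RunConfig(
        genome={
            "toy": {
                "length": 100_000,
                "seed": seed + 100,
                "name": "mt_toy",
                "repeat_plan": [
                    ["A", 556, 5_001, 45_001, "direct"],
                    ["F", 350, 62_001, 82_001, "direct"],
                    ["L", 249, 30_001, 57_001, "direct"],
                    ["EE", 127, 12_001, 24_001, "direct"],
                    ["M60", 60, 70_001, 90_001, "direct"],
                ],
            }
        },
        outdir=str(outdir),
        seed=seed,
        simulate={
            "depth": 60.0,
            "error_rate": 0.002,
            "specs": [
                {"kind": "loopout_circle", "repeat_id": "EE", "weight": 7.0},
                {"kind": "loopout_circle", "repeat_id": "M60", "weight": 2.0},
                {"kind": "chimera", "breakpoints": [35_500, 52_500], "weight": 0.5},
            ],
        },
        control={"depth": 60.0, "error_rate": 0.002, "specs": []},
        crossover_repeats=["EE", "M60"],
        normalize_total=1_000_000,
    )
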