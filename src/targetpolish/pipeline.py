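"""End-to-end orchestration: targeting → liftover → polishing → reinsertion.

The mapping stage is delegated: callers supply a PAF (from ntLink,
minimap2, or the fixture generator) or ask for minimap2 to be invoked.
Every intermediate artifact (targets FASTA, lifted PAF, polished targets
FASTA) is written in its standard format so each stage is independently
re-runnable and debuggable.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import io_formats, paf_lift, polisher, reinsertion, targeting
from .io_formats import PafRecord, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one polishing run."""

    assembly_path: str
    reads_path: str
    out_prefix: str
    paf_path: Optional[str] = None
    mapper: Optional[str] = None  # "minimap2" | None
    bed_path: Optional[str] = None
    flank_len: int = 64
    k_values: tuple[int, ...] = (32, 28, 24, 20)
    bloom_fpr: float = 0.01
    min_kmer_count: int = 2
    # None -> the engine's own defaults (PolishParams)
    verify_window: Optional[int] = None
    accept_fraction: Optional[float] = None
    max_indel: Optional[int] = None
    rounds_per_k: Optional[int] = None
    min_overlap: int = 1
    threads: int = 1
    uppercase: bool = True
    edit_log: bool = False

    def __post_init__(self) -> None:
        if self.paf_path and self.mapper:
            raise ValueError("give either a PAF file or a mapper, not both")
        if not self.paf_path and not self.mapper:
            raise ValueError("a mapping source is required (--paf or --mapper)")

    def polish_params(self) -> polisher.PolishParams:
        overrides = {
            name: value
            for name, value in (
                ("verify_window", self.verify_window),
                ("accept_fraction", self.accept_fraction),
                ("max_indel", self.max_indel),
                ("rounds_per_k", self.rounds_per_k),
            )
            if value is not None
        }
        return polisher.PolishParams(k_values=tuple(self.k_values), **overrides)


def run_mapper(
    reads_path: str, assembly_path: str, mapper: str, out_paf: str,
    extra_args: Sequence[str] = (),
) -> str:
    """Invoke an external mapper and validate its PAF output."""
    if mapper != "minimap2":
        raise ValueError(f"unsupported mapper {mapper!r}; supply a PAF instead")
    exe = shutil.which("minimap2")
    if exe is None:
        raise RuntimeError(
            "minimap2 not found on PATH; map the reads yourself and pass --paf"
        )
    cmd = [exe, "-x", "map-ont", *extra_args, assembly_path, reads_path]
    logger.info("running mapper: %s", " ".join(cmd))
    with open(out_paf, "w") as out:
        proc = subprocess.run(cmd, stdout=out, stderr=subprocess.PIPE, text=True)
    if proc.returncode != 0:
        tail = "\n".join(proc.stderr.splitlines()[-10:])
        raise RuntimeError(f"minimap2 exited {proc.returncode}:\n{tail}")
    io_formats.read_paf(out_paf)  # validation pass
    return out_paf


def run_pipeline(config: RunConfig) -> dict:
    """Execute stages 2-5 and write the final polished assembly.

    Returns a machine-readable report of per-stage counts.  A run that
    finds zero targets copies the input to the output, warns, and reports
    normally — an unmasked assembly is a valid input state.
    """
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    assembly = io_formats.read_fasta(config.assembly_path)
    bed = io_formats.read_bed(config.bed_path) if config.bed_path else None

    # stage 2: targeting
    targets = targeting.extract_targets(
        assembly, bed, targeting.FlankPolicy(config.flank_len)
    )
    report: dict = {
        "n_contigs": len(assembly),
        "n_targets": len(targets),
        "target_bases": sum(len(t.sequence) for t in targets),
    }
    final_path = f"{prefix}.polished.fa"
    if not targets:
        logger.warning("no target regions found; copying input to output unchanged")
        io_formats.write_fasta(assembly, final_path)
        report.update(n_lifted=0, n_discarded=0, n_subs=0, n_ins=0, n_del=0,
                      output=final_path)
        _write_report(report, f"{prefix}.report.json")
        return report
    io_formats.write_fasta(targeting.targets_to_records(targets), f"{prefix}.targets.fa")

    # stage 1 (delegated) + stage 3: mapping and liftover
    paf_path = config.paf_path
    if paf_path is None:
        paf_path = run_mapper(
            config.reads_path, config.assembly_path, config.mapper, f"{prefix}.map.paf"
        )
    index = paf_lift.build_target_index(targets)
    stats = paf_lift.LiftStats()
    lifted = paf_lift.lift_paf(
        io_formats.iter_paf(paf_path), index, config.min_overlap, stats
    )
    io_formats.write_paf(lifted, f"{prefix}.lifted.paf")
    report.update(
        n_paf_records=stats.n_input,
        n_lifted=stats.n_lifted,
        n_discarded=stats.n_discarded,
    )

    # stage 4: polishing
    reads = {rec.name: rec.sequence for rec in io_formats.read_reads(config.reads_path)}
    outcomes = polisher.polish_all(
        targets,
        lifted,
        reads,
        config.polish_params(),
        config.bloom_fpr,
        min_kmer_count=config.min_kmer_count,
        threads=config.threads,
    )
    io_formats.write_fasta(
        [SequenceRecord(o.target_name, o.sequence) for o in outcomes],
        f"{prefix}.polished_targets.fa",
    )
    report.update(
        n_subs=sum(o.n_subs for o in outcomes),
        n_ins=sum(o.n_ins for o in outcomes),
        n_del=sum(o.n_del for o in outcomes),
        n_sites_visited=sum(o.n_sites_visited for o in outcomes),
    )
    if config.edit_log:
        _write_edit_log(outcomes, f"{prefix}.edits.tsv")
        report["edit_log"] = f"{prefix}.edits.tsv"

    # stage 5: reinsertion
    polished_assembly = reinsertion.reinsert(assembly, outcomes, config.uppercase)
    io_formats.write_fasta(polished_assembly, final_path)
    report["output"] = final_path
    _write_report(report, f"{prefix}.report.json")
    logger.info(
        "pipeline done: %d targets, %d edits, output %s",
        report["n_targets"],
        report["n_subs"] + report["n_ins"] + report["n_del"],
        final_path,
    )
    return report


def _write_edit_log(outcomes, path: str) -> None:
    with open(path, "w") as out:
        out.write("target\tposition\ttype\tref\talt\tsupport\tk\n")
        for o in outcomes:
            for e in o.edits:
                out.write(
                    f"{o.target_name}\t{e.position}\t{e.type}\t{e.ref}\t{e.alt}"
                    f"\t{e.support:.4f}\t{e.k}\n"
                )


def _write_report(report: dict, path: str) -> None:
    with open(path, "w") as out:
        json.dump(report, out, indent=2, sort_keys=True)
        out.write("\n")
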