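"""End-to-end orchestration: simulate/ingest -> statistics -> JSON report.

Gathers the per-library bias diagnostics, optional assembly summary,
misassembly report and partial-gene fraction into one machine-readable
document, and applies an explicit, configurable recommendation rule: when a
library shows a high exact-duplicate ratio AND shorter inserts in high-depth
regions (negative Cohen's d), read deduplication plus a single-cell assembler
mode is advised.  The rule is a documented heuristic — the raw statistics are
always printed alongside the flag.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import assembly as asm
from . import bias as bias_mod
from . import ingest as ingest_mod
from . import misassembly as mis_mod
from . import simulate as sim_mod

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: defaults of the recommendation rule (both configurable)
DUP_RATIO_THRESHOLD = 0.25
COHENS_D_THRESHOLD = -0.2


@dataclass
class RunConfig:
    """Inputs and thresholds of one report run."""

    contigs: str | Path | None = None  # reference contigs FASTA
    alignments: str | Path | None = None  # SAM/BAM or truth TSV
    reads_r1: str | Path | None = None  # optional FASTQ for sequence-exact dedup
    reads_r2: str | Path | None = None
    gene_table: str | Path | None = None  # 4-column TSV
    segments: str | Path | None = None  # PAF or 7-column TSV
    read_len: int | None = None  # required when alignments is a truth TSV
    library_id: str = "library"
    hi_frac: float = 0.70
    lo_frac: float = 0.30
    window: int = 100
    edge: int = 200
    gap_threshold: int = 1000
    dup_threshold: float = DUP_RATIO_THRESHOLD
    d_threshold: float = COHENS_D_THRESHOLD
    subsample_n: int = 20_000
    seed: int = 0
    outdir: str | Path | None = None


def recommend_dedup_sc(
    dup_ratio: float | None,
    cohens_d: float | None,
    dup_threshold: float = DUP_RATIO_THRESHOLD,
    d_threshold: float = COHENS_D_THRESHOLD,
) -> bool:
    """True when deduplication + single-cell assembly mode is advised."""
    if dup_ratio is None or cohens_d is None:
        return False
    return dup_ratio >= dup_threshold and cohens_d <= d_threshold


def _read_fastq_seqs(path: str | Path) -> list[str]:
    seqs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                seqs.append(line.strip())
    return seqs


def bias_report_from_files(config: RunConfig) -> bias_mod.LibraryBiasReport:
    if config.contigs is None or config.alignments is None:
        raise ValueError("bias analysis requires 'contigs' and 'alignments'")
    from Bio import SeqIO

    refs = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(config.contigs), "fasta")
    }
    pairs, _dropped = ingest_mod.parse_alignments(
        config.alignments, refs, read_len=config.read_len
    )
    seq_pairs = None
    if config.reads_r1 and config.reads_r2:
        r1 = _read_fastq_seqs(config.reads_r1)
        r2 = _read_fastq_seqs(config.reads_r2)
        if len(r1) != len(r2):
            raise ValueError("R1/R2 FASTQ files differ in read count")
        seq_pairs = list(zip(r1, r2))
    return bias_mod.compile_library_report(
        refs,
        pairs,
        seq_pairs=seq_pairs,
        library_id=config.library_id,
        hi_frac=config.hi_frac,
        lo_frac=config.lo_frac,
        window_size=config.window,
        edge_exclusion=config.edge,
    )


def bias_report_from_simulation(
    config: sim_mod.SimulationConfig,
    hi_frac: float = 0.70,
    lo_frac: float = 0.30,
    use_sequences: bool = True,
) -> tuple[bias_mod.LibraryBiasReport, sim_mod.SimulatedLibrary]:
    """Simulate one library and run the full bias analysis on it.

    This is the harness used for parameter-recovery checks: the simulator's
    truth table is ingested exactly like a mapped library.
    """
    lib = sim_mod.simulate_library(config)
    pairs = ingest_mod.pairs_from_truth(
        lib.reads.truth, lib.reference, config.read_len
    )
    seq_pairs = lib.reads.seq_pairs() if use_sequences else None
    report = bias_mod.compile_library_report(
        lib.reference,
        pairs,
        seq_pairs=seq_pairs,
        library_id=f"sim_c{config.pcr_cycles}",
        hi_frac=hi_frac,
        lo_frac=lo_frac,
    )
    return report, lib


def run_report(config: RunConfig) -> dict[str, Any]:
    """Produce the consolidated report document (and write it when outdir set).

    Every number is computed by the underlying module operation; this
    function only aggregates.
    """
    doc: dict[str, Any] = {"schema_version": SCHEMA_VERSION, "library_id": config.library_id}

    bias_rep = None
    if config.contigs is not None and config.alignments is not None:
        bias_rep = bias_report_from_files(config)
        doc["bias"] = _bias_to_dict(bias_rep)

    if config.contigs is not None:
        lengths = asm.lengths_from_fasta(config.contigs)
        doc["assembly"] = dataclasses.asdict(asm.assembly_summary(list(lengths.values())))

    if config.segments is not None:
        segs = _read_segments(config.segments)
        if config.contigs is not None:
            contig_lengths = asm.lengths_from_fasta(config.contigs)
        else:
            contig_lengths = _segment_query_spans(segs)
        bps, n_skip = mis_mod.classify_breakpoints(segs, gap_threshold=config.gap_threshold)
        doc["misassembly"] = dataclasses.asdict(
            mis_mod.misassembly_rate(bps, contig_lengths, n_skipped_pairs=n_skip)
        )

    if config.gene_table is not None:
        genes = pd.read_csv(config.gene_table, sep="\t")
        doc["partial_genes"] = dataclasses.asdict(
            asm.partial_gene_fraction(
                genes, subsample_n=config.subsample_n, seed=config.seed
            )
        )

    if bias_rep is not None:
        doc["recommendation"] = {
            "dedup_single_cell_advised": recommend_dedup_sc(
                bias_rep.dup_ratio,
                bias_rep.cohens_d,
                config.dup_threshold,
                config.d_threshold,
            ),
            "dup_threshold": config.dup_threshold,
            "d_threshold": config.d_threshold,
        }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report_json(doc, outdir / "report.json")
        if bias_rep is not None:
            _write_bias_tables(bias_rep, outdir)
    return doc


def write_report_json(doc: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _bias_to_dict(rep: bias_mod.LibraryBiasReport) -> dict[str, Any]:
    d = dataclasses.asdict(rep)
    d["mean_cv"] = rep.mean_cv
    return d


def _write_bias_tables(rep: bias_mod.LibraryBiasReport, outdir: Path) -> None:
    rows = [
        {"contig_id": cid, "cv_pct": cv} for cid, cv in sorted(rep.cv_per_contig.items())
    ]
    pd.DataFrame(rows).to_csv(outdir / "per_contig_cv.tsv", sep="\t", index=False)
    one = _bias_to_dict(rep)
    one.pop("cv_per_contig")
    pd.DataFrame([one]).to_csv(outdir / "library_report.tsv", sep="\t", index=False)


def _read_segments(path: str | Path) -> list[mis_mod.SegmentAlignment]:
    p = Path(path)
    if p.suffix.lower() == ".paf":
        return mis_mod.read_paf(p)
    return mis_mod.read_segments_tsv(p)


def _segment_query_spans(segs: Sequence[mis_mod.SegmentAlignment]) -> dict[str, int]:
    spans: dict[str, int] = {}
    for s in segs:
        spans[s.query_id] = max(spans.get(s.query_id, 0), s.q_end)
    return spans
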