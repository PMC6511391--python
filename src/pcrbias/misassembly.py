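"""Breakpoint classification of contig-to-reference segment alignments.

A simplified evaluator in the spirit of assembly QC tools: walk adjacent
aligned segments of each assembled contig (sorted along the contig) and type
the junction between them:

* different reference contig            -> translocation
* same reference, opposite strands      -> inversion
* same reference, same strand, but the reference jump is inconsistent with
  the query gap by more than ``gap_threshold`` (or the segment order
  contradicts the strand)                -> relocation

The misassembly rate counts relocations + inversions per bp of contigs
>= 1 kb; translocations are reported but excluded, since on a fragmented
reference they can reflect two correct assemblies with different contig
boundaries rather than an error.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

RELOCATION, INVERSION, TRANSLOCATION = "relocation", "inversion", "translocation"


@dataclass(frozen=True)
class SegmentAlignment:
    """One aligned block of an assembled contig on a reference contig.

    All coordinates 0-based, half-open; for '-' strand segments the query
    interval still ascends on the contig while the reference interval is the
    span of the match.
    """

    query_id: str
    q_start: int
    q_end: int
    ref_id: str
    r_start: int
    r_end: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"invalid query interval on {self.query_id}")
        if not (0 <= self.r_start < self.r_end):
            raise ValueError(f"invalid reference interval on {self.ref_id}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class Breakpoint:
    query_id: str
    q_pos: int  # junction position on the assembled contig
    kind: str  # relocation | inversion | translocation


@dataclass
class MisassemblyReport:
    n_relocation: int
    n_inversion: int
    n_translocation: int
    n_skipped_pairs: int
    total_bp_ge_1kb: int
    rate: float | None  # (relocations + inversions) per bp of >=1 kb contigs


def classify_breakpoints(
    segments: Sequence[SegmentAlignment],
    gap_threshold: int = 1000,
    overlap_tol: int = 50,
    min_seg_len: int = 65,
) -> tuple[list[Breakpoint], int]:
    """Type the junction between every adjacent segment pair of each contig.

    Segments shorter than ``min_seg_len`` on the query are ignored; adjacent
    pairs whose query intervals overlap by more than ``overlap_tol`` are
    skipped with a warning.  Returns (breakpoints, n_skipped_pairs).
    """
    by_query: dict[str, list[SegmentAlignment]] = defaultdict(list)
    for seg in segments:
        if seg.q_end - seg.q_start >= min_seg_len:
            by_query[seg.query_id].append(seg)
    breakpoints: list[Breakpoint] = []
    n_skipped = 0
    for qid in sorted(by_query):
        segs = sorted(by_query[qid], key=lambda s: (s.q_start, s.q_end))
        for a, b in zip(segs, segs[1:]):
            q_gap = b.q_start - a.q_end
            if q_gap < -overlap_tol:
                n_skipped += 1
                logger.warning(
                    "query overlap beyond tolerance between segments of %s "
                    "(%d..%d vs %d..%d); pair skipped",
                    qid, a.q_start, a.q_end, b.q_start, b.q_end,
                )
                continue
            kind = _classify_pair(a, b, q_gap, gap_threshold, overlap_tol)
            if kind is not None:
                breakpoints.append(Breakpoint(qid, a.q_end, kind))
    return breakpoints, n_skipped


def _classify_pair(
    a: SegmentAlignment,
    b: SegmentAlignment,
    q_gap: int,
    gap_threshold: int,
    overlap_tol: int,
) -> str | None:
    if a.ref_id != b.ref_id:
        return TRANSLOCATION
    if a.strand != b.strand:
        return INVERSION
    # reference gap in the direction implied by the strand
    if a.strand == "+":
        r_gap = b.r_start - a.r_end
    else:
        r_gap = a.r_start - b.r_end
    if abs(r_gap - q_gap) > gap_threshold or r_gap < -overlap_tol:
        return RELOCATION
    return None


def misassembly_rate(
    breakpoints: Iterable[Breakpoint],
    contig_lengths: Mapping[str, int],
    n_skipped_pairs: int = 0,
    min_contig_len: int = 1000,
) -> MisassemblyReport:
    """Relocations + inversions per bp of contigs >= ``min_contig_len``.

    Translocations enter the report but not the rate.
    """
    counts = {RELOCATION: 0, INVERSION: 0, TRANSLOCATION: 0}
    for bp in breakpoints:
        counts[bp.kind] += 1
    total = sum(l for l in contig_lengths.values() if l >= min_contig_len)
    rate = (counts[RELOCATION] + counts[INVERSION]) / total if total > 0 else None
    return MisassemblyReport(
        n_relocation=counts[RELOCATION],
        n_inversion=counts[INVERSION],
        n_translocation=counts[TRANSLOCATION],
        n_skipped_pairs=n_skipped_pairs,
        total_bp_ge_1kb=total,
        rate=rate,
    )


# ---------------------------------------------------------------------------
# readers


def read_paf(path: str | Path) -> list[SegmentAlignment]:
    """Read PAF columns 1-12 (query name/len/start/end, strand, target
    name/len/start/end, matches, block len, MAPQ)."""
    segs: list[SegmentAlignment] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: PAF needs >= 12 columns, got {len(f)}")
            segs.append(
                SegmentAlignment(
                    query_id=f[0],
                    q_start=int(f[2]),
                    q_end=int(f[3]),
                    strand=f[4],
                    ref_id=f[5],
                    r_start=int(f[7]),
                    r_end=int(f[8]),
                )
            )
    return segs


def read_segments_tsv(path: str | Path) -> list[SegmentAlignment]:
    """7-column TSV: query_id, q_start, q_end, ref_id, r_start, r_end, strand.
    A header line starting with 'query_id' is allowed."""
    segs: list[SegmentAlignment] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or (ln == 1 and line.startswith("query_id")):
                continue
            f = line.split("\t")
            if len(f) != 7:
                raise ValueError(f"{path}:{ln}: expected 7 columns, got {len(f)}")
            segs.append(
                SegmentAlignment(
                    f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]), f[6]
                )
            )
    return segs
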