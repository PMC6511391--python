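"""Parse paired-end alignments into unique insert events and depth profiles.

The atom of the coverage-bias analysis is the *unique insert-mapping event*:
a distinct (contig, start coordinate, insert length) combination, carrying the
number of read pairs that support it (its multiplicity) and the GC fraction of
the reference span it covers.  PCR duplicates collapse onto a single event
with multiplicity > 1.

Coordinates are 0-based, half-open throughout; SAM's 1-based POS is converted
on ingest.  The insert is the template span of a proper pair, taken from
|TLEN| at the leftmost mate.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODE_GE10KB = "ge10kb"  # contigs >= 10 kb, cumulative >= 50 kb
MODE_GE2KB = "ge2kb"  # fallback: contigs >= 2 kb
MODE_NOT_ESTIMABLE = "not_estimable"


class AlignmentParseError(ValueError):
    """Malformed or unresolvable alignment record."""


@dataclass(frozen=True)
class ReadPairAlignment:
    """One properly paired read-pair mapping, summarized at the template level."""

    contig_id: str
    start: int  # 0-based leftmost mapped position
    insert_len: int  # |TLEN|
    mate_starts: tuple[int, int]  # 0-based start of each mate
    read_len: int


@dataclass(frozen=True)
class UniqueInsertEvent:
    contig_id: str
    start: int
    insert_len: int
    multiplicity: int
    gc: float


@dataclass
class DepthProfile:
    """Per-base read depth along one contig with a windowed view."""

    contig_id: str
    depth: np.ndarray
    window_size: int = 100
    edge_exclusion: int = 200

    def windowed(self) -> pd.DataFrame:
        """Mean depth over non-overlapping full tiles, excluding any window
        whose span intersects the first or last ``edge_exclusion`` bp."""
        n = len(self.depth)
        w = self.window_size
        rows = []
        for s in range(0, n - w + 1, w):
            e = s + w
            if s < self.edge_exclusion or e > n - self.edge_exclusion:
                continue
            rows.append((s, e, float(self.depth[s:e].mean())))
        return pd.DataFrame(rows, columns=["start", "end", "mean_depth"])

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0


@dataclass
class DroppedCounts:
    secondary: int = 0
    supplementary: int = 0
    unmapped: int = 0
    not_proper: int = 0
    zero_tlen: int = 0
    mate_other_contig: int = 0

    @property
    def total(self) -> int:
        return sum(vars(self).values())


def parse_alignments(
    path: str | Path,
    refs: Mapping[str, str] | Mapping[str, int],
    read_len: int | None = None,
) -> tuple[list[ReadPairAlignment], DroppedCounts]:
    """Parse a SAM/BAM file or a simulator truth TSV into read-pair alignments.

    Dispatches on file content: files ending in .tsv (or with the truth-table
    header) go through :func:`parse_truth_tsv`, everything else through
    :func:`parse_sam`.  ``read_len`` is required for the TSV route.
    """
    p = Path(path)
    if p.suffix.lower() in {".tsv", ".txt"}:
        if read_len is None:
            raise AlignmentParseError("read_len is required to ingest a truth TSV")
        return parse_truth_tsv(p, refs, read_len), DroppedCounts()
    return parse_sam(p, refs)


def parse_truth_tsv(
    path: str | Path,
    refs: Mapping[str, str] | Mapping[str, int],
    read_len: int,
) -> list[ReadPairAlignment]:
    df = pd.read_csv(path, sep="\t")
    required = {"contig_id", "start", "insert_len"}
    if not required.issubset(df.columns):
        raise AlignmentParseError(
            f"truth table missing columns {sorted(required - set(df.columns))}"
        )
    return pairs_from_truth(df, refs, read_len)


def pairs_from_truth(
    truth: pd.DataFrame,
    refs: Mapping[str, str] | Mapping[str, int],
    read_len: int,
) -> list[ReadPairAlignment]:
    lengths = _ref_lengths(refs)
    pairs = []
    for row in truth.itertuples(index=False):
        cid, start, ilen = str(row.contig_id), int(row.start), int(row.insert_len)
        if cid not in lengths:
            raise AlignmentParseError(f"unknown contig {cid!r} in truth table")
        if start < 0 or start + ilen > lengths[cid]:
            raise AlignmentParseError(
                f"insert [{start}, {start + ilen}) exceeds contig {cid!r}"
            )
        pairs.append(
            ReadPairAlignment(
                contig_id=cid,
                start=start,
                insert_len=ilen,
                mate_starts=(start, start + ilen - read_len),
                read_len=read_len,
            )
        )
    return pairs


def parse_sam(
    path: str | Path,
    refs: Mapping[str, str] | Mapping[str, int],
) -> tuple[list[ReadPairAlignment], DroppedCounts]:
    """One record per properly paired primary alignment, counted at the
    leftmost mate (TLEN > 0); secondary/supplementary/unpaired dropped."""
    import pysam

    lengths = _ref_lengths(refs)
    pairs: list[ReadPairAlignment] = []
    dropped = DroppedCounts()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary:
                dropped.secondary += 1
                continue
            if rec.is_supplementary:
                dropped.supplementary += 1
                continue
            if rec.is_unmapped or rec.mate_is_unmapped or not rec.is_paired:
                dropped.unmapped += 1
                continue
            if not rec.is_proper_pair:
                dropped.not_proper += 1
                continue
            if rec.reference_id != rec.next_reference_id:
                dropped.mate_other_contig += 1
                continue
            tlen = rec.template_length
            if tlen == 0:
                dropped.zero_tlen += 1
                continue
            if tlen < 0:  # count each pair once, at the leftmost mate
                continue
            cid = rec.reference_name
            if cid not in lengths:
                raise AlignmentParseError(f"unknown contig {cid!r} in {path}")
            start = rec.reference_start
            if start + tlen > lengths[cid]:
                raise AlignmentParseError(
                    f"pair {rec.query_name!r}: insert [{start}, {start + tlen}) "
                    f"exceeds contig {cid!r} length {lengths[cid]}"
                )
            rlen = rec.infer_query_length() or rec.query_length
            pairs.append(
                ReadPairAlignment(
                    contig_id=cid,
                    start=start,
                    insert_len=tlen,
                    mate_starts=(start, rec.next_reference_start),
                    read_len=rlen,
                )
            )
    if dropped.total:
        logger.info("dropped records while parsing %s: %s", path, vars(dropped))
    return pairs, dropped


def _ref_lengths(refs: Mapping[str, str] | Mapping[str, int]) -> dict[str, int]:
    out = {}
    for k, v in refs.items():
        out[k] = v if isinstance(v, int) else len(v)
    return out


# ---------------------------------------------------------------------------
# unique insert events


def collapse_events(
    pairs: Sequence[ReadPairAlignment],
    refs: Mapping[str, str],
) -> list[UniqueInsertEvent]:
    """Collapse pairs into unique (contig, start, insert_len) events.

    Multiplicity is the pair count for that exact mapping; gc is computed on
    the reference substring [start, start+insert_len).
    """
    counts: Counter[tuple[str, int, int]] = Counter(
        (p.contig_id, p.start, p.insert_len) for p in pairs
    )
    events = []
    for (cid, start, ilen), mult in sorted(counts.items()):
        seq = refs[cid]
        if start + ilen > len(seq):
            raise AlignmentParseError(
                f"insert [{start}, {start + ilen}) exceeds contig {cid!r}"
            )
        events.append(
            UniqueInsertEvent(
                contig_id=cid,
                start=start,
                insert_len=ilen,
                multiplicity=mult,
                gc=gc_fraction(seq[start : start + ilen]),
            )
        )
    return events


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


# ---------------------------------------------------------------------------
# depth


def depth_profile(
    intervals: Iterable[tuple[int, int]],
    contig_id: str,
    contig_len: int,
    window_size: int = 100,
    edge_exclusion: int = 200,
) -> DepthProfile:
    """Per-base depth from aligned [start, end) intervals (one per mate)."""
    delta = np.zeros(contig_len + 1, dtype=np.int64)
    for s, e in intervals:
        s = max(0, s)
        e = min(contig_len, e)
        if e > s:
            delta[s] += 1
            delta[e] -= 1
    depth = np.cumsum(delta[:-1])
    return DepthProfile(contig_id, depth, window_size, edge_exclusion)


def mate_intervals(
    pairs: Iterable[ReadPairAlignment], span: str = "read"
) -> list[tuple[int, int]]:
    """Aligned intervals of each mate (``span='read'``, the default depth
    semantics) or of the whole template (``span='insert'``)."""
    out = []
    for p in pairs:
        if span == "insert":
            out.append((p.start, p.start + p.insert_len))
        else:
            for m in p.mate_starts:
                out.append((m, m + p.read_len))
    return out


def depth_profile_from_pairs(
    pairs: Sequence[ReadPairAlignment],
    contig_id: str,
    contig_len: int,
    window_size: int = 100,
    edge_exclusion: int = 200,
    span: str = "read",
) -> DepthProfile:
    sel = [p for p in pairs if p.contig_id == contig_id]
    return depth_profile(
        mate_intervals(sel, span=span), contig_id, contig_len, window_size, edge_exclusion
    )


# ---------------------------------------------------------------------------
# contig selection


def select_bias_contigs(
    lengths: Mapping[str, int],
) -> tuple[list[str], str]:
    """Apply the contig-selection rule for the bias analysis.

    All contigs >= 10 kb if these total >= 50 kb; otherwise all contigs
    >= 2 kb; if that set is empty the bias is not estimable.
    """
    big = [c for c, l in lengths.items() if l >= 10_000]
    if sum(lengths[c] for c in big) >= 50_000:
        return big, MODE_GE10KB
    mid = [c for c, l in lengths.items() if l >= 2_000]
    if mid:
        return mid, MODE_GE2KB
    return [], MODE_NOT_ESTIMABLE
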