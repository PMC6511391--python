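"""Forward simulator of a PCR-amplified shotgun library.

Low-input metagenome libraries are PCR-amplified after adapter ligation
(typically >= 9 cycles).  Shorter inserts amplify more efficiently, so with
every cycle they make up a growing share of the read pool and eventually show
up as stacks of exact-duplicate read pairs over narrow loci.  This module
simulates that mechanism end to end:

1. random reference contigs at a target GC content,
2. insert molecules fragmented uniformly with Gaussian lengths,
3. deterministic per-molecule amplification weight ``(1 + e(L))**c`` where the
   per-cycle efficiency decays exponentially with insert length,
   ``e(L) = e0 * exp(-lambda * max(0, L - L0))``,
4. multinomial sampling of the final read pairs (repeated draws of the same
   molecule are the PCR duplicates),
5. paired FASTQ rendering with optional substitution errors, plus a
   ground-truth table of every sampled insert.

A single seeded RNG is consumed in the fixed order reference -> inserts ->
sampling -> errors, so identical configs produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


class SimulationError(RuntimeError):
    """Raised when a simulation step cannot proceed (e.g. no host contig)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated library.

    Defaults describe a small but realistic low-input virome library:
    2x150 bp reads, 350 +/- 50 bp inserts, and an amplification efficiency
    that starts at 0.9 per cycle and decays with rate 0.01/bp beyond a
    200 bp pivot.
    """

    n_contigs: int = 100
    contig_len: tuple[int, int] = (2000, 3000)
    gc_target: float = 0.5
    n_molecules: int = 10_000
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    pcr_cycles: int = 10
    base_efficiency: float = 0.9
    length_bias_rate: float = 0.01
    ref_insert_len: int = 200
    n_reads: int = 50_000
    read_len: int = 150
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.contig_len
        if self.n_contigs < 1:
            raise ConfigurationError("n_contigs must be >= 1")
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid contig_len range {self.contig_len}")
        for name in ("gc_target", "base_efficiency", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.pcr_cycles < 0:
            raise ConfigurationError("pcr_cycles must be >= 0")
        if self.length_bias_rate < 0:
            raise ConfigurationError("length_bias_rate must be >= 0")
        if self.insert_sd < 0:
            raise ConfigurationError("insert_sd must be >= 0")
        if self.insert_mean + 4 * self.insert_sd > lo:
            raise ConfigurationError(
                "insert_mean + 4*insert_sd must fit inside the minimum contig "
                f"length ({self.insert_mean} + 4*{self.insert_sd} > {lo})"
            )
        if self.read_len > self.insert_mean:
            raise ConfigurationError("read_len must be <= insert_mean")
        if self.n_molecules < 1 or self.n_reads < 1:
            raise ConfigurationError("n_molecules and n_reads must be >= 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TrueInsert:
    """One original insert molecule with its expected post-PCR copy number."""

    contig_id: str
    start: int  # 0-based
    length: int
    weight: float  # (1 + e(length))**cycles, >= 1


@dataclass(frozen=True)
class SampledInsert:
    """One sampled (sequenced) copy of an insert molecule."""

    insert: TrueInsert
    copy_id: int


@dataclass
class LibraryReads:
    """Rendered paired reads plus the ground-truth table."""

    r1: list[str]
    r2: list[str]
    names: list[str]
    truth: pd.DataFrame  # columns: contig_id, start, insert_len, copy_id
    n_skipped: int = 0

    def seq_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.r1, self.r2))


@dataclass
class SimulatedLibrary:
    config: SimulationConfig
    reference: dict[str, str]
    inserts: list[TrueInsert]
    samples: list[SampledInsert]
    reads: LibraryReads


def amplification_efficiency(length, config: SimulationConfig):
    """Per-cycle amplification efficiency e(L) = e0*exp(-lambda*max(0, L-L0))."""
    excess = np.maximum(0.0, np.asarray(length, dtype=float) - config.ref_insert_len)
    return config.base_efficiency * np.exp(-config.length_bias_rate * excess)


def amplification_weight(length, config: SimulationConfig):
    """Expected copy number after ``pcr_cycles`` cycles: (1 + e(L))**c."""
    return (1.0 + amplification_efficiency(length, config)) ** config.pcr_cycles


def generate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Generate ``n_contigs`` random sequences at the target GC content.

    Each base is drawn i.i.d. with P(G) = P(C) = gc_target/2 and
    P(A) = P(T) = (1-gc_target)/2.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.contig_len
    p_gc = config.gc_target
    probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    ref: dict[str, str] = {}
    lengths = rng.integers(lo, hi + 1, size=config.n_contigs)
    for i, length in enumerate(lengths):
        idx = rng.choice(4, size=int(length), p=probs)
        ref[f"contig_{i + 1}"] = _BASES[idx].tobytes().decode("ascii")
    return ref


def simulate_inserts(
    ref: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[TrueInsert]:
    """Fragment the reference into ``n_molecules`` insert molecules.

    Contigs are chosen proportionally to length, starts uniformly over valid
    positions, lengths from Normal(insert_mean, insert_sd) truncated (by
    rejection) to [2*read_len, contig length] and rounded.
    """
    if not ref:
        raise SimulationError("reference is empty")
    min_len = 2 * config.read_len
    names = [n for n in ref if len(ref[n]) >= min_len]
    if not names:
        raise SimulationError(
            f"no contig can host the minimum insert length {min_len}"
        )
    lengths = np.array([len(ref[n]) for n in names], dtype=float)
    contig_idx = rng.choice(len(names), size=config.n_molecules, p=lengths / lengths.sum())
    clens = lengths[contig_idx].astype(int)

    ins_len = np.zeros(config.n_molecules, dtype=int)
    todo = np.arange(config.n_molecules)
    while todo.size:
        draw = np.rint(
            rng.normal(config.insert_mean, config.insert_sd, size=todo.size)
        ).astype(int)
        ok = (draw >= min_len) & (draw <= clens[todo])
        ins_len[todo[ok]] = draw[ok]
        todo = todo[~ok]

    starts = rng.integers(0, clens - ins_len + 1)
    weights = amplification_weight(ins_len, config)
    return [
        TrueInsert(names[c], int(s), int(l), float(w))
        for c, s, l, w in zip(contig_idx, starts, ins_len, weights)
    ]


def amplify_and_sample(
    inserts: Sequence[TrueInsert],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[SampledInsert]:
    """Draw ``n_reads`` sequenced pairs, multinomial with p ∝ amplification weight.

    Repeated draws of the same molecule are exact PCR duplicates; the copy_id
    indexes copies of one molecule.
    """
    if not inserts:
        raise SimulationError("no inserts to sample from")
    weights = np.array([ins.weight for ins in inserts], dtype=float)
    total = weights.sum()
    if not total > 0:
        raise SimulationError("total amplification weight is zero")
    counts = rng.multinomial(config.n_reads, weights / total)
    samples: list[SampledInsert] = []
    for i in np.flatnonzero(counts):
        for k in range(counts[i]):
            samples.append(SampledInsert(inserts[i], k))
    return samples


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def render_library(
    samples: Sequence[SampledInsert],
    ref: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> LibraryReads:
    """Render each sampled insert as a read pair.

    The forward read is the first ``read_len`` bases of the insert, the
    reverse read the reverse complement of its last ``read_len`` bases.
    Substitution errors are applied per base with probability ``error_rate``.
    """
    if not samples:
        raise SimulationError("no sampled inserts to render")
    r = config.read_len
    r1: list[str] = []
    r2: list[str] = []
    names: list[str] = []
    rows: list[tuple[str, int, int, int]] = []
    n_skipped = 0
    for i, s in enumerate(samples):
        ins = s.insert
        if r > ins.length:
            n_skipped += 1
            continue
        insert_seq = ref[ins.contig_id][ins.start : ins.start + ins.length]
        r1.append(insert_seq[:r])
        r2.append(reverse_complement(insert_seq[-r:]))
        names.append(f"pair_{i}:{ins.contig_id}:{ins.start}:{ins.length}:{s.copy_id}")
        rows.append((ins.contig_id, ins.start, ins.length, s.copy_id))
    if n_skipped:
        logger.warning("skipped %d sampled inserts shorter than read_len", n_skipped)
    if config.error_rate > 0 and r1:
        arr = np.frombuffer("".join(r1 + r2).encode("ascii"), dtype=np.uint8).copy()
        hit = np.flatnonzero(rng.random(arr.size) < config.error_rate)
        if hit.size:
            # substitute with one of the 3 other bases
            base_idx = np.searchsorted(_BASES, arr[hit])
            shift = rng.integers(1, 4, size=hit.size)
            arr[hit] = _BASES[(base_idx + shift) % 4]
        flat = arr.tobytes().decode("ascii")
        n = len(r1)
        r1 = [flat[i * r : (i + 1) * r] for i in range(n)]
        r2 = [flat[(n + i) * r : (n + i + 1) * r] for i in range(n)]
    truth = pd.DataFrame(rows, columns=["contig_id", "start", "insert_len", "copy_id"])
    return LibraryReads(r1=r1, r2=r2, names=names, truth=truth, n_skipped=n_skipped)


def simulate_library(config: SimulationConfig) -> SimulatedLibrary:
    """Run the full pipeline: reference -> inserts -> sampling -> reads."""
    rng = np.random.default_rng(config.seed)
    ref = generate_reference(config, rng)
    inserts = simulate_inserts(ref, config, rng)
    samples = amplify_and_sample(inserts, config, rng)
    reads = render_library(samples, ref, config, rng)
    return SimulatedLibrary(config, ref, inserts, samples, reads)


# ---------------------------------------------------------------------------
# writers


def write_fasta(ref: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq_pair(reads: LibraryReads, r1_path: str | Path, r2_path: str | Path) -> None:
    qual_cache: dict[int, str] = {}
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for name, s1, s2 in zip(reads.names, reads.r1, reads.r2):
            q1 = qual_cache.setdefault(len(s1), "I" * len(s1))
            q2 = qual_cache.setdefault(len(s2), "I" * len(s2))
            f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")


def write_truth_tsv(reads: LibraryReads, path: str | Path) -> None:
    reads.truth.to_csv(path, sep="\t", index=False)


def write_sam(
    reads: LibraryReads,
    ref: dict[str, str],
    config: SimulationConfig,
    path: str | Path,
) -> None:
    """Write one SAM record per mate, proper-pair flags, leftmost-signed TLEN."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in ref.items()],
    }
    tids = {n: i for i, n in enumerate(ref)}
    r = config.read_len
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, s1, s2, row in zip(
            reads.names, reads.r1, reads.r2, reads.truth.itertuples(index=False)
        ):
            tid = tids[row.contig_id]
            start, ilen = int(row.start), int(row.insert_len)
            for is_r1 in (True, False):
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = s1 if is_r1 else reverse_complement(s2)
                a.flag = (0x1 | 0x2 | 0x40 | 0x20) if is_r1 else (0x1 | 0x2 | 0x80 | 0x10)
                a.reference_id = tid
                a.reference_start = start if is_r1 else start + ilen - r
                a.mapping_quality = 60
                a.cigarstring = f"{r}M"
                a.next_reference_id = tid
                a.next_reference_start = start + ilen - r if is_r1 else start
                a.template_length = ilen if is_r1 else -ilen
                a.query_qualities = pysam.qualitystring_to_array("I" * r)
                out.write(a)


def write_library(lib: SimulatedLibrary, outdir: str | Path, sam: bool = True) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fasta",
        "r1": outdir / "reads_R1.fastq",
        "r2": outdir / "reads_R2.fastq",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(lib.reference, paths["reference"])
    write_fastq_pair(lib.reads, paths["r1"], paths["r2"])
    write_truth_tsv(lib.reads, paths["truth"])
    if sam:
        paths["sam"] = outdir / "alignments.sam"
        write_sam(lib.reads, lib.reference, lib.config, paths["sam"])
    return paths
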