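"""Per-library coverage-bias diagnostics.

Statistics that quantify how unevenly a PCR-amplified library covers its
contigs and whether high-depth regions are enriched in short inserts:

* coefficient of variation (CV) of per-base depth, per contig;
* 70%/30% depth classification of unique insert events;
* two-sample Kolmogorov-Smirnov distance and Cohen's d between the insert-size
  distributions of the high- and low-depth classes;
* exact-duplicate read-pair ratio;
* library-size-normalized coverage and cross-library agreement.

The sign convention for Cohen's d is high-depth minus low-depth, so a negative
d means shorter inserts in high-depth regions — the signature of preferential
short-insert amplification.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .ingest import (
    DepthProfile,
    ReadPairAlignment,
    UniqueInsertEvent,
    MODE_NOT_ESTIMABLE,
    collapse_events,
    depth_profile_from_pairs,
    select_bias_contigs,
)

HIGH, LOW, INTERMEDIATE = "high", "low", "intermediate"

#: |d| cutoffs for negligible/small/medium/large
_D_BANDS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"))


def coverage_cv(profile: DepthProfile | np.ndarray) -> float | None:
    """CV of per-base depth in percent: 100 * sample sd / mean.

    Returns None (not estimable) when the mean depth is zero.
    """
    depth = profile.depth if isinstance(profile, DepthProfile) else np.asarray(profile)
    depth = depth.astype(float)
    mean = depth.mean()
    if mean == 0:
        return None
    return float(100.0 * depth.std(ddof=1) / mean)


def classify_event_depth(
    events: Sequence[UniqueInsertEvent],
    hi_frac: float = 0.70,
    lo_frac: float = 0.30,
) -> list[str]:
    """Label each event high/low/intermediate by its multiplicity relative to
    the maximum event multiplicity of its contig (>=70% high, <=30% low)."""
    if not events:
        return []
    max_by_contig: dict[str, int] = defaultdict(int)
    for ev in events:
        max_by_contig[ev.contig_id] = max(max_by_contig[ev.contig_id], ev.multiplicity)
    labels = []
    for ev in events:
        m = max_by_contig[ev.contig_id]
        if ev.multiplicity >= hi_frac * m:
            labels.append(HIGH)
        elif ev.multiplicity <= lo_frac * m:
            labels.append(LOW)
        else:
            labels.append(INTERMEDIATE)
    return labels


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float | None:
    """Standardized mean difference (a minus b) with (n-1)-weighted pooled sd.

    None when either sample has fewer than 2 values or the pooled sd is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return None
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        return 0.0 if a.mean() == b.mean() else None
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def d_magnitude(d: float | None) -> str:
    if d is None:
        return "not_estimable"
    for cut, name in _D_BANDS:
        if abs(d) < cut:
            return name
    return "large"


@dataclass
class InsertSizeBiasResult:
    ks_distance: float | None
    ks_pvalue: float | None
    cohens_d: float | None
    d_magnitude: str
    mean_high: float | None
    mean_low: float | None
    n_high: int
    n_low: int


def insert_size_bias_test(
    high_sizes: Sequence[float], low_sizes: Sequence[float]
) -> InsertSizeBiasResult:
    """Compare high- vs low-depth insert-size distributions.

    KS distance D = max |ECDF difference| with the asymptotic two-sided
    p-value; Cohen's d = (mean_high - mean_low) / pooled sd.
    """
    n_hi, n_lo = len(high_sizes), len(low_sizes)
    if n_hi == 0 or n_lo == 0:
        return InsertSizeBiasResult(
            None, None, None, "not_estimable", None, None, n_hi, n_lo
        )
    with np.errstate(divide="ignore"):
        ks = sps.ks_2samp(high_sizes, low_sizes, method="asymp")
    d = cohens_d(high_sizes, low_sizes)
    return InsertSizeBiasResult(
        ks_distance=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        cohens_d=d,
        d_magnitude=d_magnitude(d),
        mean_high=float(np.mean(high_sizes)),
        mean_low=float(np.mean(low_sizes)),
        n_high=n_hi,
        n_low=n_lo,
    )


# ---------------------------------------------------------------------------
# duplication


def duplication_ratio(seq_pairs: Iterable[tuple[str, str]]) -> float:
    """Fraction of read pairs that are exact-sequence copies of another pair:
    1 - distinct/total, keyed on the ordered (mate-1, mate-2) sequences."""
    total = 0
    seen = set()
    for pair in seq_pairs:
        total += 1
        seen.add(pair)
    if total == 0:
        raise ValueError("duplication_ratio needs at least one pair")
    return 1.0 - len(seen) / total


def duplication_ratio_reads(seq_pairs: Iterable[tuple[str, str]]) -> float:
    """Same statistic counted per read (both mates pooled) rather than per pair."""
    total = 0
    seen = set()
    for s1, s2 in seq_pairs:
        total += 2
        seen.add(s1)
        seen.add(s2)
    if total == 0:
        raise ValueError("duplication_ratio_reads needs at least one pair")
    return 1.0 - len(seen) / total


def duplication_ratio_from_events(n_events: int, n_pairs: int) -> float:
    """Mapping-identity duplication: 1 - distinct events / pairs.  Equals the
    sequence-based ratio when reads carry no sequencing errors."""
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    return 1.0 - n_events / n_pairs


# ---------------------------------------------------------------------------
# normalized coverage & cross-library agreement


def normalized_contig_coverage(mean_depth: float, library_total_bp: float) -> float:
    """Mean per-base depth normalized by library size, in depth per Gbp."""
    if library_total_bp <= 0:
        raise ValueError("library_total_bp must be > 0")
    return mean_depth / (library_total_bp / 1e9)


@dataclass
class AgreementResult:
    pearson_r2: float | None
    spearman_rho: float | None
    detected_fraction: float | None
    frac_ge_5x: float | None
    n_shared: int


def cross_library_agreement(
    cov_a: Mapping[str, float],
    cov_b: Mapping[str, float],
    read_counts_b: Mapping[str, int] | None = None,
    mean_depths_b: Mapping[str, float] | None = None,
) -> AgreementResult:
    """Agreement between two libraries over the same contig universe.

    Correlations (Pearson r^2, Spearman rho) use contigs with coverage > 0 in
    both libraries.  Detection (>= 1 mapped read) uses raw read counts when
    given, else positive coverage in B; the >= 5x fraction uses mean depths.
    """
    if set(cov_a) != set(cov_b):
        raise ValueError("cross_library_agreement requires the same contig universe")
    contigs = sorted(cov_a)
    a = np.array([cov_a[c] for c in contigs], dtype=float)
    b = np.array([cov_b[c] for c in contigs], dtype=float)
    shared = (a > 0) & (b > 0)
    n_shared = int(shared.sum())
    if n_shared >= 3 and len(set(a[shared])) > 1 and len(set(b[shared])) > 1:
        r = sps.pearsonr(a[shared], b[shared]).statistic
        rho = sps.spearmanr(a[shared], b[shared]).statistic
        pearson_r2, spearman_rho = float(r**2), float(rho)
    else:
        pearson_r2 = spearman_rho = None
    if read_counts_b is not None:
        detected = np.array([read_counts_b.get(c, 0) >= 1 for c in contigs])
    else:
        detected = b > 0
    detected_fraction = float(detected.mean()) if contigs else None
    if mean_depths_b is not None:
        depths = np.array([mean_depths_b.get(c, 0.0) for c in contigs], dtype=float)
        frac_ge_5x = float((depths >= 5.0).mean()) if contigs else None
    else:
        frac_ge_5x = None
    return AgreementResult(pearson_r2, spearman_rho, detected_fraction, frac_ge_5x, n_shared)


# ---------------------------------------------------------------------------
# per-library report


@dataclass
class LibraryBiasReport:
    """All per-library diagnostics in one record."""

    library_id: str
    dup_ratio: float | None
    dup_ratio_reads: float | None
    cv_per_contig: dict[str, float]
    ks_distance: float | None
    ks_pvalue: float | None
    cohens_d: float | None
    d_magnitude: str
    mean_insert_high: float | None
    mean_insert_low: float | None
    n_high: int
    n_low: int
    n_intermediate: int
    mode_flag: str
    n_pairs: int
    n_events: int

    @property
    def mean_cv(self) -> float | None:
        vals = list(self.cv_per_contig.values())
        return float(np.mean(vals)) if vals else None


def compile_library_report(
    refs: Mapping[str, str],
    pairs: Sequence[ReadPairAlignment],
    seq_pairs: Sequence[tuple[str, str]] | None = None,
    library_id: str = "library",
    hi_frac: float = 0.70,
    lo_frac: float = 0.30,
    window_size: int = 100,
    edge_exclusion: int = 200,
    weight_by_multiplicity: bool = False,
) -> LibraryBiasReport:
    """Run the full per-library bias analysis.

    Insert events and depth classes are computed on the contigs retained by
    the selection rule; duplication is library-wide.  By default each unique
    event contributes one insert-size observation to the KS/d comparison;
    ``weight_by_multiplicity`` repeats it by its pair count instead.
    """
    lengths = {c: len(s) for c, s in refs.items()}
    selected, mode = select_bias_contigs(lengths)

    all_events = collapse_events(pairs, refs) if pairs else []
    if seq_pairs is not None:
        dup = duplication_ratio(seq_pairs)
        dup_reads = duplication_ratio_reads(seq_pairs)
    elif pairs:
        dup = duplication_ratio_from_events(len(all_events), len(pairs))
        dup_reads = None
    else:
        dup = dup_reads = None

    if mode == MODE_NOT_ESTIMABLE or not pairs:
        return LibraryBiasReport(
            library_id, dup, dup_reads, {}, None, None, None, "not_estimable",
            None, None, 0, 0, 0, MODE_NOT_ESTIMABLE, len(pairs), len(all_events),
        )

    sel = set(selected)
    events = [ev for ev in all_events if ev.contig_id in sel]
    labels = classify_event_depth(events, hi_frac, lo_frac)
    reps = (lambda ev: ev.multiplicity) if weight_by_multiplicity else (lambda ev: 1)
    high_sizes: list[int] = []
    low_sizes: list[int] = []
    n_int = 0
    for ev, lab in zip(events, labels):
        if lab == HIGH:
            high_sizes.extend([ev.insert_len] * reps(ev))
        elif lab == LOW:
            low_sizes.extend([ev.insert_len] * reps(ev))
        else:
            n_int += reps(ev)
    bias = insert_size_bias_test(high_sizes, low_sizes)

    cv_per_contig: dict[str, float] = {}
    for cid in selected:
        prof = depth_profile_from_pairs(
            pairs, cid, lengths[cid], window_size, edge_exclusion
        )
        cv = coverage_cv(prof)
        if cv is not None:
            cv_per_contig[cid] = cv

    return LibraryBiasReport(
        library_id=library_id,
        dup_ratio=dup,
        dup_ratio_reads=dup_reads,
        cv_per_contig=cv_per_contig,
        ks_distance=bias.ks_distance,
        ks_pvalue=bias.ks_pvalue,
        cohens_d=bias.cohens_d,
        d_magnitude=bias.d_magnitude,
        mean_insert_high=bias.mean_high,
        mean_insert_low=bias.mean_low,
        n_high=bias.n_high,
        n_low=bias.n_low,
        n_intermediate=n_int,
        mode_flag=mode,
        n_pairs=len(pairs),
        n_events=len(all_events),
    )
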