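"""Assembly contiguity metrics and cross-pipeline comparison.

N50/N90 follow the "minimal contig length among contigs making up to 50%/90%
of assembly size" definition: sort lengths descending and report the length at
which the cumulative sum first reaches the target share of the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bias import cohens_d, d_magnitude


@dataclass(frozen=True)
class AssemblySummary:
    total_bp: int
    total_bp_ge_10kb: int
    n_contigs: int
    n50: int
    n90: int
    largest: int


@dataclass
class AssemblyComparison:
    fold_ratios: dict[str, float]  # finite folds only
    infinite_folds: list[str]  # library ids where A == 0 < B
    median_fold: float | None
    ks_pvalue: float | None
    cohens_d: float | None
    d_magnitude: str


@dataclass
class PartialGeneResult:
    fraction_partial: float | None
    median_ratio: float | None
    n_used: int
    n_filtered_out: int
    off_center_warning: bool  # |median ratio - 1| > 0.1


def _nx(sorted_desc: np.ndarray, total: int, frac: float) -> int:
    cum = np.cumsum(sorted_desc)
    idx = int(np.searchsorted(cum, frac * total))
    return int(sorted_desc[idx])


def assembly_summary(lengths: Sequence[int]) -> AssemblySummary:
    """Contiguity metrics of one contig set; empty input gives an all-zero
    summary."""
    lengths = [int(l) for l in lengths]
    if not lengths:
        return AssemblySummary(0, 0, 0, 0, 0, 0)
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be > 0")
    arr = np.sort(np.asarray(lengths))[::-1]
    total = int(arr.sum())
    return AssemblySummary(
        total_bp=total,
        total_bp_ge_10kb=int(arr[arr >= 10_000].sum()),
        n_contigs=len(arr),
        n50=_nx(arr, total, 0.5),
        n90=_nx(arr, total, 0.9),
        largest=int(arr[0]),
    )


def lengths_from_fasta(path: str | Path) -> dict[str, int]:
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def compare_assemblies(
    metric_a: Mapping[str, float],
    metric_b: Mapping[str, float],
    paired: bool = True,
) -> AssemblyComparison:
    """Compare one assembly metric (e.g. cumulative bp in contigs >= 10 kb)
    between two pipelines over the same libraries.

    Per-library fold = B/A; folds with A == 0 and B > 0 are reported
    separately as infinite and excluded from the median.  The two metric
    distributions are compared with a two-sample KS test and Cohen's d
    (B minus A).
    """
    if set(metric_a) != set(metric_b):
        missing = sorted(set(metric_a) ^ set(metric_b))
        raise ValueError(f"library sets differ: {missing}")
    if len(metric_a) < 3:
        raise ValueError("need at least 3 libraries to compare")
    folds: dict[str, float] = {}
    infinite: list[str] = []
    for lib in sorted(metric_a):
        a, b = metric_a[lib], metric_b[lib]
        if a == 0:
            if b > 0:
                infinite.append(lib)
            continue
        folds[lib] = b / a
    a_vals = np.array([metric_a[k] for k in sorted(metric_a)], dtype=float)
    b_vals = np.array([metric_b[k] for k in sorted(metric_b)], dtype=float)
    ks = sps.ks_2samp(b_vals, a_vals, method="asymp")
    d = cohens_d(b_vals, a_vals)
    return AssemblyComparison(
        fold_ratios=folds,
        infinite_folds=infinite,
        median_fold=float(np.median(list(folds.values()))) if folds else None,
        ks_pvalue=float(ks.pvalue),
        cohens_d=d,
        d_magnitude=d_magnitude(d),
    )


def partial_gene_fraction(
    records: pd.DataFrame,
    subsample_n: int = 20_000,
    seed: int = 0,
    evalue_cutoff: float = 1e-5,
    score_cutoff: float = 100.0,
    partial_threshold: float = 0.90,
) -> PartialGeneResult:
    """Fraction of predicted genes shorter than 90% of their best database hit.

    Records (columns gene_len, ref_len, evalue, score) are filtered to
    evalue <= 1e-5 and score >= 100, subsampled without replacement to at most
    ``subsample_n`` genes, and a gene is partial iff gene_len/ref_len < 0.90
    (a ratio of exactly 0.90 counts as complete).  The median length ratio is
    reported with a warning flag when it strays more than 0.1 from 1.
    """
    required = {"gene_len", "ref_len", "evalue", "score"}
    if not required.issubset(records.columns):
        raise ValueError(f"missing columns {sorted(required - set(records.columns))}")
    if records.empty:
        raise ValueError("no gene records given")
    keep = records[(records.evalue <= evalue_cutoff) & (records.score >= score_cutoff)]
    n_filtered_out = len(records) - len(keep)
    if keep.empty:
        return PartialGeneResult(None, None, 0, n_filtered_out, False)
    if len(keep) > subsample_n:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(keep), size=subsample_n, replace=False)
        keep = keep.iloc[np.sort(idx)]
    ratio = keep.gene_len.to_numpy(float) / keep.ref_len.to_numpy(float)
    median = float(np.median(ratio))
    return PartialGeneResult(
        fraction_partial=float((ratio < partial_threshold).mean()),
        median_ratio=median,
        n_used=len(keep),
        n_filtered_out=n_filtered_out,
        off_center_warning=abs(median - 1.0) > 0.1,
    )
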