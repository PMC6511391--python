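"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library code paths they check: naive
per-base counting for depth, sort-and-scan for N50/N90, full ECDF enumeration
for the KS distance, and O(n^2) pairwise comparison for duplication.
"""

from __future__ import annotations

import numpy as np
import pytest

from pcrbias.simulate import SimulationConfig
from pcrbias.report import bias_report_from_simulation

SWEEP_SEED = 1234
SWEEP_CYCLES = (0, 5, 10, 15, 20)


# ---------------------------------------------------------------------------
# oracles


def naive_depth(intervals, contig_len):
    """Per-base depth by direct position counting."""
    depth = np.zeros(contig_len, dtype=np.int64)
    for s, e in intervals:
        for pos in range(max(0, s), min(contig_len, e)):
            depth[pos] += 1
    return depth


def brute_force_nx(lengths, frac):
    """N50/N90 by explicit descending scan."""
    total = sum(lengths)
    cum = 0
    for l in sorted(lengths, reverse=True):
        cum += l
        if cum >= frac * total:
            return l
    raise AssertionError("unreachable for non-empty lengths")


def brute_force_ks(a, b):
    """max |ECDF_a - ECDF_b| evaluated at every sample point."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


def brute_force_duplication(seq_pairs):
    """1 - distinct/total by O(n^2) exact pairwise comparison."""
    pairs = list(seq_pairs)
    distinct = 0
    for i, p in enumerate(pairs):
        if all(pairs[j] != p for j in range(i)):
            distinct += 1
    return 1.0 - distinct / len(pairs)


# ---------------------------------------------------------------------------
# simulation harness fixtures (shared across bias/acceptance tests)


def sweep_config(cycles: int, length_bias_rate: float = 0.01, seed: int = SWEEP_SEED):
    """The parameter-recovery study conditions: 100 contigs of 2-3 kb,
    10,000 molecules, 50,000 read pairs, e0=0.9, lambda=0.01/bp."""
    return SimulationConfig(
        n_contigs=100,
        contig_len=(2000, 3000),
        n_molecules=10_000,
        n_reads=50_000,
        pcr_cycles=cycles,
        base_efficiency=0.9,
        length_bias_rate=length_bias_rate,
        seed=seed,
    )


@pytest.fixture(scope="session")
def sweep_reports():
    """LibraryBiasReport per PCR cycle count at lambda=0.01."""
    return {
        c: bias_report_from_simulation(sweep_config(c))[0] for c in SWEEP_CYCLES
    }


@pytest.fixture(scope="session")
def null_report():
    """Same harness with lambda=0 (no length bias) at 20 cycles."""
    return bias_report_from_simulation(sweep_config(20, length_bias_rate=0.0))[0]


@pytest.fixture(scope="session")
def small_library():
    """A small simulated library reused by ingest/report tests."""
    cfg = SimulationConfig(
        n_contigs=6,
        contig_len=(2500, 3500),
        n_molecules=400,
        n_reads=1200,
        pcr_cycles=12,
        seed=7,
    )
    from pcrbias.simulate import simulate_library

    return simulate_library(cfg)
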