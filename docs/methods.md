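# Methods

## The bias mechanism and its simulator

PCR amplification after adapter ligation favors short templates: shorter
inserts denature, anneal and extend more completely within a cycle, so their
effective per-cycle efficiency is higher. `pcrbias.simulate` models this with
a deterministic expected copy number per molecule,

    w(L) = (1 + e(L))^c ,   e(L) = e0 * exp(-lambda * max(0, L - L0)),

with `c` the number of PCR cycles, `e0` the plateau efficiency for inserts at
or below the pivot length `L0`, and `lambda` the per-bp decay rate. The final
library is a multinomial draw of `n_reads` pairs with probabilities
proportional to `w`; repeated draws of one molecule are the exact PCR
duplicates. This "deterministic expectation + final multinomial" design keeps
memory linear in the number of molecules while reproducing the duplicate
structure of interest; it ignores the stochasticity of early-cycle branching,
which matters only when a handful of founder molecules dominate (not the
regime simulated here).

The exponential decay is the simplest one-parameter form consistent with
preferential amplification of short inserts; no published functional form
exists for it, and nothing downstream depends on the exact shape — only on
monotonicity in L.

Pipeline and randomness: one `numpy` Generator seeded from `seed` is consumed
in the fixed order reference → inserts → sampling → errors, so identical
configs give byte-identical FASTA/FASTQ/SAM/TSV output. Reference bases are
i.i.d. with P(G)=P(C)=gc_target/2. Insert molecules pick a contig
proportionally to its length, a start uniformly over valid positions, and a
length from Normal(insert_mean, insert_sd) truncated by rejection to
[2·read_len, contig length] — the lower bound keeps mates from overlapping
past each other and avoids degenerate template-length bookkeeping. Reads are
the first/last `read_len` bases of the insert (reverse mate
reverse-complemented), with optional i.i.d. substitution errors. Truth-table
coordinates are 0-based, half-open.

Defaults (insert 350 ± 50 bp, 2×150 bp reads, e0 = 0.9, lambda = 0.01/bp,
L0 = 200 bp) are conventions for a realistic short-insert Illumina library,
not measured values; with them, one extra 100 bp of insert length costs
roughly a 1.25× amplification factor per cycle at the steep end of the decay.

What the simulator does **not** model: indels, quality-score structure,
chimeras, GC-dependent amplification (real high-depth regions show no
systematic GC shift, so GC is reported descriptively only), optical
duplicates, and multi-genome community structure. Passing recovery tests on
simulated data therefore demonstrates that the statistics detect
length-biased duplication when it is present and stay silent when it is not —
they do not certify behaviour under error profiles or community compositions
the simulator omits.

## Ingest rules

* The insert of a pair is the template span |TLEN| at the leftmost mate;
  pairs with TLEN = 0 or mates on different contigs are dropped and counted.
  Only primary, properly paired alignments are used; ambiguous-mapping
  randomization is an upstream mapper concern and is not re-done here.
* Unique insert events are distinct (contig, start, insert length) triples;
  multiplicity conservation (Σ multiplicities = usable pairs) is asserted by
  tests.
* Depth is **read** depth (aligned read bases of both mates, not the insert
  gap); an insert-span variant exists behind the `span="insert"` option for
  sensitivity analysis.
* Windowed depth uses non-overlapping 100 bp tiles, dropping tiles that
  intersect the first or last 200 bp of the contig, where depth is
  unreliable. Tiles (rather than a sliding step) keep the view deterministic
  and non-redundant; the window and edge sizes are arguments.
* Bias contigs: all contigs ≥ 10 kb if these total ≥ 50 kb, else all ≥ 2 kb,
  else "not estimable". This keeps the event sample per contig large enough
  for the depth-class comparison.

## Statistical choices

* The "read depth" of an insert in the 70%/30% rule is its event
  multiplicity, and the contig maximum is the maximum event multiplicity on
  that contig. A per-base-depth reading is possible but couples the rule to
  read length; the event-multiplicity reading is self-consistent with the
  unique-event representation. Each unique event contributes one insert-size
  observation by default (`weight_by_multiplicity=True` repeats it by its
  pair count).
* CV uses the sample (n−1) standard deviation over the full per-base depth
  vector, without edge exclusion (the edge rule is a windowed-display
  concern). Zero-mean contigs are reported as missing, not zero.
* KS distance/p-value: two-sided two-sample test, asymptotic p
  (scipy `ks_2samp(method="asymp")`); exact small-sample p-values are
  unnecessary at the event counts involved.
* Cohen's d: (high − low) / pooled sd with (n−1)-weighted pooling; sign
  convention makes short-insert enrichment negative. Bands
  0.2/0.5/0.8 → negligible/small/medium/large. Undefined (flagged) when
  either class has < 2 values.
* Duplication is keyed on the ordered (mate-1, mate-2) sequence tuple —
  exact match only, no reverse-complement canonicalization. The pair-level
  ratio is the primary number; a read-level variant is reported alongside.
  When no read sequences are available the ratio falls back to mapping
  identity (distinct events / pairs), which coincides with sequence identity
  in the absence of sequencing errors.
* Normalized coverage is mean depth per Gbp of library; the unit is
  cosmetic for the correlations it feeds.
* N50/N90 ties: when several contigs share the threshold-crossing length
  that length is reported. Cross-pipeline fold ratios with a zero baseline
  are listed separately as infinite rather than clamped, since near-zero
  baselines genuinely occur for heavily amplified libraries.
* Partial genes: filters (e-value ≤ 1e-5, score ≥ 100) are applied before
  the seeded 20,000-gene subsample; a gene with exactly 90% of its best-hit
  length counts as complete (the rule is strict "< 90%"). The median length
  ratio is reported with a warning when it strays > 0.1 from 1, since the
  fraction is only meaningful when the ratio distribution is centered at 1.

## Misassembly classification

Adjacent aligned segments of each assembled contig (sorted by query start,
segments < 65 bp ignored, query overlaps > 50 bp skipped with a warning) are
typed: different reference contig → translocation; same reference, opposite
strands → inversion; same reference and strand but the reference gap differs
from the query gap by more than `gap_threshold` (default 1,000 bp, the
conventional extensive-misassembly distance) or the reference order
contradicts the strand → relocation. The rate divides relocations +
inversions by the cumulative length of ≥ 1 kb contigs; translocations are
reported but excluded because a fragmented reference can place two correct
assemblies on overlapping contigs. Local wobble below the threshold is
deliberately not called.

## Recommendation rule

The report flags "deduplication + single-cell assembly advised" when
`dup_ratio ≥ 0.25` and `cohens_d ≤ −0.2`. This is an explicit heuristic —
the duplication threshold sits at the bottom of the range where amplified
libraries typically land, and the d threshold is the smallest conventionally
non-negligible effect with the bias's sign. Both are configurable and the raw
statistics are always printed next to the flag.

## Problem sizes in tests and the acceptance script

Parameter-recovery runs use 100 contigs of 2–3 kb, 10,000 insert molecules
and 50,000 read pairs per cycle point. The shape was chosen so that both
depth classes stay populated under the null: with a mean event multiplicity
of 5 and ~100 events per contig, the per-contig maximum multiplicity is
small enough that the ≥ 70% and ≤ 30% classes each collect thousands of
events across contigs, making the null KS distance (≈ 0.87·√(1/n_hi + 1/n_lo))
comfortably below the 0.05 bound being asserted. Deeper or sparser designs
starve one of the classes and turn the null comparison into noise. Oracle
comparisons run on hundreds of random instances small enough to brute-force
exactly.

## Known limitations

* The depth-class rule inherits the event-multiplicity interpretation;
  libraries whose duplicates are split by sequencing errors will show
  attenuated multiplicities (the sequence-based duplication ratio is also a
  lower bound in that case, matching exact-match deduplicator behaviour).
* The breakpoint classifier handles the three named categories only — no
  local misassemblies, unaligned ends, or base-level duplication ratios.
* Cross-library agreement assumes an identical contig universe; it does not
  align or reconcile assemblies.
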