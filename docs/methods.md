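# Methods

## Model

A double minute (DM) is modelled as a circular walk over a set of
amplified genomic intervals. Two observable signals define it:
amplicons (copy-number-gain calls with a mean mapping coverage) and SV
breakpoint calls whose two breakends fall near the boundaries of two
amplicons. The detection problem is cast on two graphs:

- **G**, undirected: one vertex per merged amplicon; an edge per pair of
  amplicons joined by at least one SV call (parallel evidence collapses
  onto one edge, kept as an evidence list).
- **H**, directed: same vertices; each edge of G oriented the way a
  deterministic DFS first crosses it, with weight 1.

Orienting tree edges parent→child and non-tree edges in the direction of
first traversal is a strong orientation within every bridgeless piece of
G (the classic DFS argument behind Robbins' theorem): the strongly
connected components of H are exactly the 2-edge-connected components of
G, so any circular DM whose junction evidence is complete becomes a
directed cycle of H. This equivalence is enforced by a property test
against a bridge-finding oracle on random graphs.

Cyclic detection takes, per SCC, the minimum-weight directed cycle: for
every directed edge (u, v) inside the component, 1 plus the BFS distance
from v back to u (paths confined to the component); the smallest-fewest-
amplicon cycle is kept. Choosing the *shortest* cycle is a deliberate
efficiency compromise — the longest simple path problem is NP-hard — and
means a DM threaded through more vertices than its shortest cycle is
reported in truncated form. One cycle is reported per SCC. The
coverage-uniformity filter then requires `max − min < mean` over the
candidate's member coverages: amplicons on one circle share its copy
number, and coverage is proportional to copy number. Candidates that fail
either the size threshold (`min_amplicons`, default 7) or the filter are
dropped. Weakly connected components untouched by cyclic predictions are
reported whole as acyclic candidates; no path extraction is attempted, so
their shape may be a path, tree, or star.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| insert mean / sd | 400 / 50 | bp | read-pair mapping distance of the library |
| k | 3 | – | proximity slack; L = mean + k·sd = 550 bp covers ~99.7% of insert variation |
| merge_gap | 1000 | bp | CNV calls closer than this are merged (absorbs caller fragmentation) |
| min_amplicons | 7 | – | minimum members per reported DM; chosen against circles of 10 so a DM is only called when most of its amplicons link up |
| coverage filter | on | – | applied to cyclic and acyclic candidates alike (`--no-coverage-filter-acyclic` restores cyclic-only) |

Design choices where the procedure was genuinely open, exposed as flags
where an alternative is plausible:

- A breakend matches the amplicon whose *nearer boundary* (start or
  end−1) is closest, from inside or outside the interval — boundary error
  of CNV callers is two-sided. Ties go to the smaller (genomically
  earlier) amplicon id.
- "Average mapping coverage" in the uniformity filter is the mean over
  the candidate's own amplicons; a genome-wide mean would require data
  the tool may never see.
- SVs whose two ends match the same amplicon are kept as self-junction
  annotations, not self-loop edges; single-amplicon circles are only
  reported with `min_amplicons ≤ 1` plus the `allow_singleton` flag.
- DUP calls count as edge evidence by default (`--sv-types` restricts);
  insertions never do — they do not join two loci.
- DFS root and neighbor order is ascending vertex id (= genomic order),
  making the orientation, and every downstream output, reproducible
  byte-for-byte.

## The emulator and what it does (not) show

The emulator reproduces a 20-DM benchmark at the *call* level: 20 circles
of 10 amplicons (lengths uniform in 10–200 kb) placed without overlap on
four synthetic 50-Mb chromosomes standing in for chr1/2/3/14, each circle
closed by junctions joining the end of each amplicon to the start of the
next. A minimum inter-amplicon gap of 10 kb keeps the CNV-merge step from
fusing amplicons of different DMs — real benchmark coordinates are chosen
by hand with the same effect. Emulated coverage is
`base · (ploidy + extra_copies) / ploidy` (35x diploid background, so 70x
at 2 extra copies, 122.5x at 5), with Gaussian noise floored at zero.
Caller error is modelled as Gaussian boundary jitter (default sd 200 bp),
breakend jitter (sd 50 bp), independent per-call dropout (5%), and
uniformly placed false SV calls (20). SV types are assigned by reference
geometry (CTX across chromosomes, DEL for an ordered right-end-to-left-
start join, ITX otherwise) — bookkeeping only, since detection never uses
the type for matching. Inversion orientation is not modelled.

What the emulator does **not** capture: alignment artifacts and mapping
ambiguity in repeats, correlated caller errors, coverage waviness (GC,
mappability), segmental duplications that mimic junctions, and real
breakpoint-homology effects. Passing benchmarks therefore demonstrate the
graph algorithms and the plumbing, not caller behavior on real tumors.
Read-level simulation and the callers themselves are out of scope; the
package parses or emulates their outputs.

Scoring: a predicted amplicon matches a true one at ≥ 50% reciprocal
overlap on the same chromosome; matching within a prediction is greedy by
descending overlap with ties broken by coordinate, one match per true
amplicon; a truth DM counts as detected when a *single* prediction
matches ≥ 7 of its 10 amplicons.

## Numerical and degenerate-input choices

- Coordinates are integer bp throughout; jitters are rounded Gaussians,
  positions clamped to `[0, chrom_size]` and intervals to `start < end`.
- Merged coverage is the length-weighted mean of member call coverages
  (weights = original call lengths, so overlap is not double-counted).
- Empty amplicon input yields zero predictions and exit code 0; missing
  coverage with the filter enabled is a hard validation error rather than
  a silent pass.
- BFS tie-breaks (successors in ascending id) and cycle canonicalization
  (rotate to smallest id, then lexicographic) make shortest-cycle output
  unique; output files use fixed two-decimal floats and sorted edge
  listings, so identical inputs give byte-identical files.
- Truth placement uses rejection sampling with a 1000-try bound per
  amplicon; an infeasible footprint raises a configuration error.

## Problem sizes

Benchmarks run at the study's native scale — 20 DMs × 10 amplicons, ~200
amplicon calls and ~200 SV calls per dataset — which a single core
processes in well under a second per run. Property tests fuzz random
graphs up to 50 vertices (orientation) and exhaustive cycle enumeration
up to 8 vertices (shortest-cycle oracle), sizes at which brute force is
exact yet fast. The dropout-sweep test averages 20 seeded runs per
dropout level.

## Known limitations

- One cyclic DM per SCC: nested or edge-sharing circles are not
  enumerated, and the shortest cycle may truncate a longer true circle.
- Acyclic candidates are whole components with no attempt to order their
  amplicons along the putative circle.
- DM abundance / copy-count estimation is not attempted.
- Junction orientation consistency is not checked; positions only.
- The Delly reader relies on SVTYPE/END/CHR2 and ignores confidence
  intervals (CIPOS/CIEND) and newer POS2-style mate encodings.
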