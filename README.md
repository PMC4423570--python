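# dmgraph

Graph-based detection of **double minute chromosomes** (DMs) from
next-generation-sequencing variant calls.

Double minutes are circular, acentric extrachromosomal DNA bodies found in
many tumors. They are assembled from several distinct genomic segments,
are typically highly amplified, and often carry oncogenes — which makes
locating them useful for diagnosis and for finding therapeutic targets. A
DM leaves two complementary footprints in sequencing data:

1. every segment of the circle is an **amplicon** — an interval of gained
   copy number with elevated read depth — and
2. the joins between consecutive segments look like ordinary structural
   variant (SV) breakpoints: deletions, inversions, intra- and
   inter-chromosomal translocations.

`dmgraph` integrates the outputs of any copy-number caller and any SV
caller into an **amplicon graph** *G*: vertices are merged amplicons, and
an edge joins two amplicons when an SV call has one breakend proximal to a
boundary of each — "proximal" meaning within

```
L = mean + k · stdev
```

of the insert-size distribution (defaults: mean 400 bp, stdev 50 bp, k = 3,
so L = 550 bp). A deterministic depth-first search orients each edge of
*G* the way it is first traversed, producing the unit-weight auxiliary
digraph *H* in which every undirected cycle of *G* survives as a directed
cycle. Detection then proceeds in two passes:

- **Cyclic DMs** — for each strongly connected component of *H*, the
  minimum-weight directed cycle (per-edge BFS within the component) is
  reported if it has at least `min_amplicons` members (default 7) and its
  member coverages are uniform: `max − min < mean`, computed over the
  candidate's own amplicons. Amplicons on one circle share its copy
  number, so their depths must be alike.
- **Acyclic candidates** — weakly connected components not already claimed
  by a cyclic prediction are reported whole, catching DMs whose circle the
  callers failed to close.

A caller-output **emulator** generates ground-truth DMs (by default 20
circles of 10 amplicons on four 50-Mb chromosomes) and emulates the
caller outputs over them — boundary/breakend jitter, call dropout, false
SV calls, and read depth reflecting the extra DM copies — so the whole
pipeline can be benchmarked without reads, aligners, or external callers.

## Input formats

| Kind | Dialect | Flag |
|------|---------|------|
| Amplicon calls | BED: chrom, start, end, name, coverage | `--amplicons` |
| SV calls | BreakDancer native tab format | `--sv-format breakdancer` |
| SV calls | Delly-style VCF (SVTYPE/END/CHR2) | `--sv-format delly-vcf` |
| SV calls | generic BEDPE (11th column = type) | `--sv-format bedpe` |
| Per-base depth | samtools-depth TSV (optional) | `--depth` |

Internally all coordinates are 0-based half-open; 1-based dialects are
converted at the parse boundary.

## Worked example

Simulate a dataset, detect, and score:

```
$ dmgraph simulate --seed 1 --out-dir sim
n_dms=20 n_amplicon_calls=189 n_sv_calls=211

$ dmgraph detect --amplicons sim/amplicons.bed --sv sim/sv.bedpe \
      --sv-format bedpe --out-prefix out
INFO dmgraph amplicons_read=189
INFO dmgraph svs_read=211
INFO dmgraph amplicons_merged=189
INFO dmgraph edges=168
INFO dmgraph sccs=126
INFO dmgraph predictions=17 cyclic=7

$ dmgraph evaluate --truth sim/truth.tsv --pred out.dm.tsv | tail -1
detected 17/20
```

The simulated genome carries 20 true double minutes; with the default
noise model (5% call dropout, 200 bp boundary jitter, 20 spurious SV
calls) the emulated callers report 189 of the 200 true amplicons and 211
SV calls. Detection links them into 168 graph edges; 7 circles survive
intact and are reported as cyclic DMs, 10 more surface as acyclic
components, and 17 of the 20 truth DMs are recovered with at least 7 of
their 10 amplicons each. `out.dm.tsv` lists each prediction with its
cyclic flag, ordered amplicons and junctions; `out.junctions.bedpe` holds
the supporting breakpoints and `out.dot` a GraphViz rendering, one
subgraph per DM with nodes labelled `chrom:start-end`.

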