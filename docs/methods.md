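# Methods

## Model

The assembler treats a transcriptome as a set of strings to be recovered
from unordered, error-carrying substrings (single-end short reads). Its
central assumption is that every junction inside a true transcript is
witnessed by at least one read pair whose suffix/prefix overlap is long
(a substantial fraction of the reads) and nearly exact. Assembly therefore
never decomposes reads: candidate junctions are whole-read head-tail
overlaps, and the overlap graph — node per read, arc per valid overlap — is
traversed source→sink to spell transcripts.

This trades sensitivity on low-coverage transcripts (a coverage gap breaks
the path) for a low chimera rate (a chimeric junction would need a ≥ min_len
overlap at ≤ 10% mismatches between unrelated sequences, which is
vanishingly unlikely).

## Sequence representation

Bases are recoded to 2 bits: A, C, G, T distinct; every IUPAC ambiguity code
(N, R, Y, ... and U) collapses onto the C code, keeping the alphabet at four
symbols. Heavily ambiguous reads are assumed to have been removed by
upstream quality filtering, so spurious C matches are rare. Hamming
distances are computed on packed 64-bit words: XOR, collapse each 2-bit
symbol to one indicator bit, popcount (`hamming_2bit`). The batched scorer
inside `find_overlaps` applies the same XOR-and-count metric on code
matrices grouped by overlap length; both paths return identical counts and
the tests compare them against a per-character loop.

## Overlap detection parameters

| parameter        | default | meaning |
|------------------|---------|---------|
| `anchor_len`     | 7 nt    | exact seed length; every anchor position of every read is indexed |
| `anchor_scope`   | 5       | how many anchors from each read end are looked up |
| `max_error_frac` | 0.10    | mismatch budget as a fraction of overlap length |
| `min_len_frac`   | 0.20    | minimum overlap, fraction of the *longer* read (rejects chance matches) |
| `max_len_frac`   | 0.90    | maximum overlap, fraction of the *shorter* read (rejects uninformative near-duplicates; also excludes full-length self-matches) |

An anchor hit at offset *p* of read *i* for read *j*'s anchor at offset *q*
implies exactly one overlap length k = len_i − p + q; duplicate proposals
are deduplicated before scoring. Both the head-side and tail-side anchor
windows are searched (`anchor_sides="both"`); searching a single side is a
strict subset available as a switch. When several k survive validation for
one ordered pair, the fewest-mismatch k wins, ties going to the longer
overlap (the more informative junction). Reads shorter than the anchor are
excluded with a warning, not fatal.

Boundary arithmetic uses a 1e-9 guard before ceil/floor so that exact
fractional boundaries (e.g. 20% of 100) are not perturbed by binary float
representation.

## Traversal parameters

| parameter         | default | meaning |
|-------------------|---------|---------|
| `min_length`      | 200 nt  | merged-transcript reporting floor (nucleotides, not node count; 200 nt is the conventional contig floor) |
| `sim_threshold`   | 2       | node replacements under which two same-endpoint, same-length paths are redundant |
| `white_threshold` | 1       | minimum never-output nodes a path must contain |
| `max_expansions_per_source` | 200 000 | deterministic DFS budget |

The DFS visits sources ascending and children ascending by node id, which
makes the output deterministic. The too-similar check runs every time a
node is appended: if the partial path rejoins a previously output path of
the same source at the same depth with at most `sim_threshold`
replacements, the whole subtree is discarded. Coloring (white→black on
output) persists across sources.

`sim_threshold`/`white_threshold` defaults were chosen so that the minimal
redundant case — a diamond of two equal-length paths sharing endpoints —
collapses to one transcript while disjoint paths survive; both are exposed
in the configuration and worth revisiting per dataset.

Two safeguards bound the search on dense graphs (at 20× coverage a single
transcript's component has astronomically many simple paths):

* **white-reachability pruning** — descent stops when the current path holds
  fewer than `white_threshold` white nodes and no white node is reachable
  ahead. Since nodes only ever turn black, no path that could still be
  output is lost; the prune is exact, not heuristic.
* **expansion budget** — a per-source cap on DFS edge expansions (default
  200 000). On every dataset exercised by the test suite the white prune
  terminates the search well below the budget; the cap exists so that
  adversarial repeat structures cannot stall the assembler. Hitting it is
  logged.

Cycles (possible through repeats) are handled by keeping paths simple;
strongly connected regions with no external source are never entered and
their node count is logged. Merging resolves junction disagreements in
favour of the earlier read; output length is exactly Σ read lengths − Σ
overlap lengths, which the tests assert on every path.

## Post-processing

Clustering is greedy centroid: sequences longest-first, each joining the
first representative it matches at ≥ `identity_threshold` (default 0.95)
identity over its own length, in either orientation; otherwise it founds a
new cluster. Identity comes from an edlib semi-global alignment (free end
gaps on the longer sequence), banded at the threshold. Containment counts
as redundancy by default (`containment_counts`) — a fragment wholly inside
a longer transcript carries no extra information. The 0.95 default is meant
to collapse strand duplicates and path variants while keeping distinct
transcripts separate; it is configurable.

Weighting assigns each raw read to at most one transcript: candidate
placements are seeded by the read's terminal anchors against an index of
transcript anchor positions, scored as ungapped end-to-end Hamming
distance, fewest mismatches winning (ties → lowest transcript index).
Weights are a support signal, not an abundance estimate — no
multi-mapping redistribution, no EM. Reads with no seeded placement are
counted as unmapped; Σ weights + unmapped = read count always.

## Block-iterative mode

`block_size` (default 50 000 reads, chosen so one block's anchor index stays
around a gigabyte at 150 nt) controls the grid-friendly mode: seeded random
permutation, split into ⌈n/k⌉ blocks, independent per-block assembly,
merged outputs clustered and fed forward. `min_length` is not applied to
intermediate outputs (a short contig may still extend) — only to the final
single-block pass. Iteration stops when the dataset fits one block, when two
consecutive iterations produce the identical sequence set (logged notice;
shrinkage is otherwise assumed), or at `max_iterations` (default 20).
Blocks are independent and may be processed concurrently; merging in block
order keeps results identical either way. Identical configuration and seed
give byte-identical FASTA output.

## Synthetic data and benchmark

`make_transcriptome` generates a random genome with `n_genes` genes; each
gene is a chain of exons (lengths and counts drawn from the given ranges,
introns 60–200 nt, intergenic spacers 100–300 nt). Isoform 1 always uses
the full exon chain; further isoforms drop random internal exons, so all
isoforms of a gene share their first and last exon and skipped-exon false
positives are constructible. A per-gene expressed subset
(`expressed_fraction`) defines what is actually transcribed. With
`isoforms_per_gene=1` (the bacterial case) no FPA can exist by
construction.

`simulate_reads` draws ⌈coverage × length / read_length⌉ reads per
expressed transcript at uniform random starts with i.i.d. substitutions
(default rate 0.001). It emulates uniform-coverage 150 bp single-end
sequencing at 20×; it does **not** model position-dependent quality decay,
indels (the overlap model is ungapped), coverage bias, or adapter/quality
artefacts, and it draws reads from the sense strand only — the assembler
has no reverse-complement pairing, so strand-mixing would only split each
transcript into two independently assembled strands. Passing tests
therefore demonstrate the machinery on idealised reads, not performance on
real libraries.

Classification replaces the external aligners a real benchmark would use
with edlib semi-global alignments against the simulator's own truth, which
is legitimate because truth is known. The operational statistic is the
*matched fraction* of a query: the fraction of the reconstruction's length
accounted for by its best single semi-global placement (both orientations;
when the query is longer than the target, unmatched flanks count against
it). A reconstruction is **TP** when its matched fraction against some
expressed reference is ≥ 0.85; a false positive is **FPA** when its matched
fraction against a non-expressed annotated isoform, or any enumerable
first-to-last exon chain of one gene, is ≥ 0.81 (= 0.90 coverage × 0.90
identity folded into one floor); otherwise **FPB**. Per-reference
sensitivity uses the same statistic normalised by reference length:
full-length at ≥ 0.90, recovered at ≥ 0.70. S100, S70 and FPR are the
corresponding percentages (0/0 defined as 0); raw values are kept in
reports and rounding for display is half-up.

Exon-chain enumeration is capped at 4096 chains per gene; beyond that only
annotated isoforms are used (logged).

## Problem sizes

The test suite runs the full pipeline at desk scale: 20 single-isoform
transcripts of 500–2000 nt at 20× / 150 bp (≈ 3 400 reads) for the
benchmark tests, 30–50 reads for the brute-force overlap oracles, and a
1 kb transcript tiled at 25 nt stagger for the exact-recovery check. These
sizes keep the whole suite under a minute while exercising every stage.

## Known limitations

* Paired-end information is ignored (reads are treated as single-end) and
  reverse-complement overlaps are not detected; each transcript can appear
  once per strand upstream of clustering.
* Gapped overlaps are not modelled; indel-rich data will fragment.
* Weights are raw best-hit read counts, not abundance estimates.
* The simulator's idealisations listed above; FPA detection requires a
  known annotation and is only meaningful on synthetic data.
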