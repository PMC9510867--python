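# Methods

## Scope and data model

The package handles insertions (INS) and deletions (DEL) of at least 50 bp.
Internally all coordinates are 0-based half-open; a deletion spans
`[start, start + svlen)` and an insertion is anchored at its breakpoint
(`end == start`, footprint `[start, start+1)` for interval tests). VCF POS
is converted at the I/O boundary, both padded and unpadded allele dialects
are accepted, and deletion SVLEN may arrive with either sign. Symbolic
alleles (`<DEL>`, `<INS>`) are kept with empty sequences, in which case
sequence-based matching degrades to length-based matching. Inversions,
duplications, translocations and breakend algebra are out of scope.

## Pairwise matching and clustering

`MatchParams` bundles the five thresholds: breakpoint (start) distance cap,
size-ratio floor, reciprocal-overlap floor (deletions), allele-divergence
cap (insertions), and a same-type requirement. All enabled criteria combine
by AND — the strictest reading where the combination is not otherwise
specified. "Within 1 kb" is applied to the start breakpoints; deletion end
agreement is constrained by the reciprocal-overlap criterion instead.
Insertions have no genomic span, so insertion pairs use distance + size
ratio, plus sequence divergence (edit distance over the longer allele,
computed by edlib) when both alleles carry sequence. Deletion pairs use
distance + size ratio + reciprocal overlap; no divergence term is applied
to deletions, since the size-ratio criterion already bounds length
disagreement and deleted-allele sequences are frequently absent.

Two named presets exist: `svmerge-default` (1000 bp / 0.5 / 0.5 / 0.2), the
multi-platform integration criteria, and `truvari-default`
(500 bp / 0.7 / none / 0.3), mirroring the documented defaults of the
standard SV evaluation tool.

Clustering is a greedy seeded sweep in (chrom, start) order: each record
joins the first existing cluster (creation order) whose *current*
representative it matches, else seeds a new cluster. The representative is
the highest-priority member (platform priority CCS > CLR > ONT > ASM > BN;
ties broken by smallest start, then longest svlen), updated as members
join. This avoids the unbounded transitive chaining a 1 kb criterion would
otherwise permit and is fully deterministic. The sweep retires clusters
whose representative lies more than `max_dist` behind the scan position;
retirement is sound because a retired cluster's representative can no
longer change. Tests verify the windowed sweep against an all-pairs replay
of the same rule. The merged representative carries the union of member
support sets; genotypes are resolved by majority vote over members (ties →
unknown), since the upstream genotyping method is not part of this
pipeline's contract.

## High-confidence integration

After merging, records intersecting the exclusion regions are removed — a
deletion by span overlap, an insertion by breakpoint containment. Exclusion
regions are a user-supplied BED (no annotation engine is bundled). The two
retention tiers then apply: (anchor platform CCS present AND at least one
of {CLR, ONT} present) OR (svlen strictly greater than 1.5 kb AND both
{ASM, BN} present), tiers combined as an inclusive OR. "Longer than
1.5 kb" is read strictly (> 1500 bp). Retention is monotone in support by
construction. The manual image-review step of the original procedure is
replaced by a machine-readable per-stage audit table (input/kept/removed
counts per stage); no automated surrogate judgement is applied, because
manual curation is not an algorithm.

## Trio-binning

Parent-unique k-mer sets are built directly from the parental sequences
(either haplotype FASTA or reads): canonical (strand-collapsed) k-mers of
one parent minus the other's, at k = 21, 41, 51, 61, 81. No abundance
filtering is applied by default; genome-derived k-mer sets have no
sequencing-error k-mers to suppress.

Because k reaches 81 (beyond 2-bit packing into 64-bit words), k-mers are
represented by 64-bit polynomial rolling hashes of the canonical
orientation, computed vectorised over whole sequences (prefix sums in
wrap-around uint64 arithmetic with an odd, hence invertible, base). Set
membership runs through a 2^23-entry prefix-occupancy filter before exact
binary search. With ~10^7 distinct k-mers per index, the probability of any
hash collision is below 10^-5; a collision at worst perturbs one marker
count by one. Small-k indexes are verified against exact string enumeration
in the tests.

Per k, a read's verdict is the simple majority of its paternal vs maternal
marker counts (ties, including 0–0, are undecided); the per-k decision rule
is not further specified upstream, and count majority is the natural
choice. Across k, a parent wins iff (1) at least `min_agreeing = 2` k
values voted for it and (2) it holds a strict majority of the *decided*
votes. The majority denominator is configurable (`decided_ks` | `all_ks`);
decided-votes is the default because an all-five denominator would make
criterion (1) vacuous — any strict majority of five already implies at
least three agreeing votes. Reads failing both criteria are unassigned and
are intended to feed both downstream haplotype assemblies. Swapping the
parental inputs swaps the output bins exactly.

## CHCRs and the benchmark

High-confidence SVs are annotated with haplotype support by matching them
against the paternal and maternal assembly callsets (`match_pair`, merge
preset). Candidate regions are the union (optionally intersection) of the
two haplotype coverage tracks. How region boundaries are drawn is a design
choice here: every high-confidence SV *without* haplotype support excises a
window of ± `flank` (default 1000 bp) around its span, splitting the
candidate region; surviving fragments shorter than `min_region` (default
10 kb) are dropped. Benchmark SVs are the supported SVs wholly contained in
a surviving region; supported SVs inside an excised window are dropped with
it. Each CHCR records which coverage tracks overlap it. The benchmark is
distributed as a truth VCF (with a HAP INFO tag) plus a regions BED4, and
both round-trip back into the in-memory benchmark.

## Evaluation

Test calls outside every CHCR are ignored. Candidate (benchmark, test)
pairs under the match parameters are assigned greedily by increasing
breakpoint distance (ties: longer test call, then lexicographic ids), each
side used at most once — one-to-one matching prevents a single test call
from absorbing several truth SVs. TP/FN partition the benchmark; FP are
unmatched in-region test calls; precision, recall and F1 follow, with
zero-denominator cases defined as 0. Depth curves evaluate pre-called
per-depth callsets; synthetic depth titration uses a saturating detection
model s(d) = 1 − exp(−d/d₀) with d₀ = 4× by default.

Replicate consensus (for short-read callsets) clusters calls across
replicates within 1 kb of the same type and keeps clusters present in at
least `min_support = 2` replicates with representative length ≥ 30 bp —
the "1000 2 1 1 0 30" parameter convention; the strand flag is parsed but
inert, as strand carries no meaning for symmetric DEL/INS.

Benchmark comparison intersects the two CHCR sets, counts one-to-one
matched SV pairs overall and within the intersection (side-symmetric
tie-breaking), and reports each side's shared fraction with its own
denominator, shared/(shared + unique_side).

## Sanger concordance

The module consumes a pre-extracted observation table (chromatogram
processing and BLAST alignment of Sanger reads are instrument-bound and out
of scope): per targeted SV, whether PCR amplified, whether sequencing
succeeded, and the observed type/length/breakpoint. Concordance is scored
per dimension with a ± 10 bp tolerance on length and breakpoint (start
coordinate; either-endpoint acceptance for deletions is available behind a
flag, default off). A dimension is uncertain when unobserved; insertions
longer than a single Sanger reaction can resolve (500 bp) are uncertain in
all dimensions; heterozygous double-allele traces should be marked
uncertain upstream. Aggregation reports amplification rate (overall and by
genic/intergenic class), sequencing rate among amplified, and per-dimension
concordance as matches/(matches + mismatches) with uncertain excluded —
counts always accompany rates.

## Synthetic data

All generators are deterministic under their seed.

* **Reference**: random sequence at GC 0.41 with planted element copies
  (Poisson, default 50/Mb; 80 % Alu-like 300 bp, 20 % LINE-like 6 kb,
  ~2 % mutated per copy) from small per-run consensus libraries.
* **SV sizes**: a mixture of a uniform 50–1000 bp background (weight 0.45)
  and normal components at 300 ± 30 bp (0.35) and 6000 ± 400 bp (0.20),
  floored at 50 bp — reproducing the mobile-element peaks that dominate
  real insertion/deletion spectra. Peak-size deletions snap onto planted
  element copies when available; peak-size insertions insert element-library
  sequence.
* **Trio**: four parental haplotypes receive per-haplotype SNVs at 10^-3
  (plentiful parent-unique k-mers at every k on Mb-scale fixtures) and the
  planted SVs; the child inherits one haplotype from each parent. Each SV
  is carried heterozygously by the child, homozygously (p = 0.15), or only
  by untransmitted haplotypes (p = 0.25, absent from the child). The first
  10 % of the genome is variant-free — a homozygous-identical region whose
  reads must stay unassigned in trio-binning. Applying the recorded
  variants to the reference reproduces each haplotype exactly, and tests
  verify this with an independent reconstruction.
* **Platform callsets**: each child truth SV is detected per platform with
  a size- and type-dependent sensitivity, then breakpoint-jittered and
  length-perturbed (normal, per-platform sd); spurious calls are added at a
  per-Mb rate. The default profiles encode the qualitative platform
  contrasts — CCS/CLR sensitivity collapses for ≥ 5 kb insertions, ONT
  detects deletions better than insertions, optical mapping is blind below
  1 kb, coarse at breakpoints (jitter sd 500 bp) and emits no allele
  sequence. These numbers are free configuration values, not claims about
  any instrument. Detection uniforms are drawn before the corruption draws,
  so lowering a sensitivity under a fixed seed can only shrink the detected
  set.
* **Reads**: uniform sampling, normal lengths (default 10 ± 1.5 kb),
  substitution-only errors (default 1 %) — k-mer membership is the consumer,
  and substitutions are the error channel that matters for it. Each read
  carries its haplotype of origin for accuracy scoring.

What the generator does **not** emulate: long-read homopolymer/indel error
profiles, optical-map raw signal, coverage biases, reference mosaicism, and
repeat-driven mis-mapping. Passing tests therefore demonstrate the
correctness of the construction and evaluation logic under controlled
corruption, not calling performance on real instruments.

## Standard problem sizes

The test suite and the acceptance script run the full pipeline on a 2 Mb
trio with 300 planted SVs (platform sensitivities 0.9/0.8/0.7 across
CCS/CLR/ONT) and bin 60× child reads at all five k values — large enough
for stable rate estimates (≈ 200 benchmark SVs, ≈ 12 000 reads) while a
complete run stays within a few minutes on one CPU. Unit tests use a
300 kb / 50-SV fixture.

## Numerical and degenerate-input choices

Zero-length intervals have reciprocal overlap 0; divergence of two empty
strings is 0 and of one empty string 1. Precision/recall/F1 are 0 when
their denominators vanish. Interval sets are half-open and merged
adjacency-inclusive; region subtraction and intersection are sweep-based
and oracle-tested against per-base boolean arrays. Records on unplaced
contigs survive I/O but fall outside any coverage track, so they never
enter CHCRs. All randomness flows through `numpy.random.default_rng`
seeded from explicit arguments.

## Known limitations

Genotype handling is carry-through with majority vote; no read-backed
genotyping or genotype-aware evaluation. Breakpoints are never refined or
realigned. The CHCR boundary rule (flank excision) is one defensible
mechanization of "regions supported by both evidence sets"; alternative
rules would shift region totals without changing the evaluation semantics.
Hash-based k-mer sets cannot enumerate their members as strings; exactness
is only verified through membership queries.
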