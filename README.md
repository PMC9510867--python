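# svbench

Construction and evaluation of haplotype-resolved structural-variant (SV)
benchmarks, as a reusable, tested pipeline.

## The problem

Structural variants — insertions and deletions of at least 50 bp here — are
called very differently by different sequencing platforms and callers, and no
single technology detects them all. A *benchmark* resolves this by combining
evidence: multi-platform callsets are merged and filtered into a
high-confidence callset, the child's long reads are partitioned by
parent-unique k-mers (trio-binning) so each haplotype can be assembled
independently, and only high-confidence SVs corroborated by at least one
haplotype assembly, inside *continuous high-confidence regions* (CHCRs),
enter the final benchmark. Inside a CHCR the benchmark claims completeness,
so any test callset can be scored there as TP/FP/FN.

`svbench` implements every stage of that construction plus the evaluation
machinery, exercised end to end on deterministic synthetic trio data:

| stage | module |
| --- | --- |
| SV data model, VCF/BED/TSV I/O | `svbench.model`, `svbench.io` |
| match predicates and cross-platform clustering | `svbench.matching` |
| exclusion filtering + retention tiers | `svbench.integration` |
| trio-binning by parent-unique k-mers | `svbench.triobin` |
| CHCRs and the benchmark set | `svbench.chcr` |
| P/R/F1 evaluation, depth curves, replicate consensus, benchmark comparison | `svbench.evaluation` |
| Sanger concordance scoring | `svbench.sanger` |
| seeded synthetic trio generators | `svbench.simulate` |

## The rules at the core

Two calls describe the same SV when they are of the same type, their start
breakpoints lie within `d = 1000` bp, their sizes satisfy
`min(l1,l2)/max(l1,l2) >= 0.5`, deletions reciprocally overlap by `r >= 0.5`,
and insertion alleles (when present) differ by less than 20 %
(edit distance / longer length). A merged call is *high-confidence* when

* it is detected by CCS **and** supported by CLR or ONT, **or**
* it is longer than 1.5 kb **and** supported by both the assembly-based
  callset and optical mapping,

and it lies outside the user-supplied exclusion regions (centromeres,
telomeres, segmental duplications, short tandem repeats).

A child read is binned as paternal/maternal from per-k marker-count votes at
k = 21, 41, 51, 61, 81 under two criteria: at least two k values must agree,
and the winning parent must hold a strict majority of the decided votes.

Evaluation is Truvari-style: calls outside every CHCR are ignored; inside,
each benchmark SV is matched to at most one test call (nearest breakpoint
first), giving precision = TP/(TP+FP), recall = TP/(TP+FN) and their
harmonic mean F1.

## Worked example

```python
from svbench.pipeline import run_trio_pipeline, corrupted_test_callset
from svbench.evaluation import evaluate

run = run_trio_pipeline(seed=7, length=500_000, sv_count=80)
recall, precision = run.recovery()
test, planted_r, planted_p = corrupted_test_callset(run.benchmark, 0.9, 0.05, seed=8)
res = evaluate(test, run.benchmark)
```

prints (via the accompanying formatting):

```
child truth SVs:        58
high-confidence SVs:    48
planted-truth recovery: recall 1.000, precision 1.000
CHCRs:                  1 spanning 500,000 bp
benchmark SVs:          48
test callset:           planted recall 0.917, planted precision 0.957
measured:               P=0.957 R=0.917 F1=0.936
```

The generator plants 80 SVs on a 500 kb trio genome; 58 land on transmitted
haplotypes (the child's truth). Five corrupted platform callsets are merged
and filtered: all 48 SVs whose planted detection pattern satisfies the
retention tiers are recovered, with nothing spurious (recovery 1.000/1.000).
Every high-confidence SV is confirmed by a haplotype assembly, so one CHCR
covers the genome and all 48 become benchmark SVs. A test callset with 90 %
sensitivity and 5 % spurious in-CHCR calls then scores exactly its planted
rates — the evaluator reads back what was planted.

The same pipeline is available from the shell:

```bash
svbench simulate --length 300000 --sv-count 40 --seed 3 -o fix/
svbench merge fix/CCS.vcf fix/CLR.vcf fix/ONT.vcf fix/ASM.vcf fix/BN.vcf -o merged.vcf
svbench integrate merged.vcf -o hc.vcf --audit audit.tsv
svbench chcr --highconf hc.vcf --pat-calls pat_asm.vcf --mat-calls mat_asm.vcf \
             --pat-cov fix/pat_cov.bed --mat-cov fix/mat_cov.bed -o bench.vcf -b bench.bed
svbench bench --test test.vcf --truth bench.vcf --regions bench.bed -o eval.tsv
svbench triobin --pat father.fa --mat mother.fa --child fix/child_reads.fasta -o bins/
```

## Documentation

`docs/methods.md` describes the model and procedure in full: parameter
defaults and their units, what the synthetic generator does and does not
emulate, numerical choices, and known limitations.
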