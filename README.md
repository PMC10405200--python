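# leukotype

**WGS-based genomic subtype classification for B-other acute lymphoblastic
leukemia.**

At diagnosis, B-cell precursor ALL is classified by cytogenetics, FISH and
RT-PCR. Cases lacking any established lesion after that work-up — roughly a
third of adult ALL — are labelled *B-other* and managed without a molecular
subtype. Whole-genome sequencing can resolve most of them: ploidy classes
hidden by low tumor purity, cytogenetically cryptic fusions, immunoglobulin
enhancer hijacks without fusion transcripts, and subtype-defining point
mutations. `leukotype` re-implements that analysis layer as a tested,
reusable Python library for methodologists working on ALL genomics and
WGS-based diagnostics: the inputs are variant-level calls (SV breakends,
allele-specific copy number, small variants with VAF, RNA classifier labels),
not reads.

Because no sequencing data accompany the study design this package follows,
it ships a first-class **synthetic cohort generator** whose `paper-roster`
preset encodes a 57-case cohort with the published lesion tally, so every
cohort-level result is reproducible end to end on a desk-scale synthetic
reference (1.5 Mb chromosome surrogates plus a D4Z4-like repeat contig).

## What it computes

- **Breakend graph + enhancer-proximity walks** (`leukotype.graph`).
  Chromosomes are split into oriented segments at every breakpoint; each SV
  junction contributes a variant edge and its orientation mirror. A candidate
  enhancer hijack for gene *g* is a minimum-cost orientation-consistent path
  from the Eμ *IGH* (or *IGK*) anchor to the body of *g*, with cost = reference
  bases traversed outside anchor and gene plus inserted sequence, emitted iff
  cost < 100 kb. Direct and chained (≤2 junctions) fusion calling and a
  chromothripsis flag (≥8 two-state CN switches on ≥2 chromosomes) share the
  same graph machinery.
- **DUX4 rearrangement detection** (`leukotype.dux4`). *DUX4* lives in the
  D4Z4 macrosatellite, so its rearrangements are often anchored at only one
  placeable locus. Single breakends in a partner window (IGH, ERG) are called
  when their attached sequence maps to the repeat contig by exact k-mer
  seeding (k = 15, ≥5 distinct seed hits, ≥25% hit fraction); opposite-
  orientation repeat- and telomere-bearing breakends yield the
  inverted-insertion configuration that RNA fusion calling cannot see.
- **Subtype precedence ladder** (`leukotype.subtypes`). A deterministic rung
  order — WHO ploidy classes → WHO fusions → DUX4-r → MEF2D-r → ZNF384-r →
  UBTF::ATXN7L3 → Ph-like JAK-STAT → ZEB2/CEBP → PAX5 P80R (biallelic
  required) → PAX5alt → IDH1/2 → other IG hijacks → reportable-but-
  unclassifiable → no-driver — with biallelic *PAX5* mechanics (two mutations,
  mutation+deletion, mutation+LOH, fusion+LOH) and RNA-consensus
  reconciliation that reports, but never overwrites, discordance.
- **Signatures, clock, RAG** (`leukotype.signatures`). 96-context SBS
  catalogs; exposures `argmin_{e≥0} ‖c − S·e‖₂` by NNLS against a packaged
  7-signature reference; hypermutator flagging; SNV burden vs age by Huber
  robust regression (c = 1.345) with asymptotic 95% CIs; RSS-heptamer
  (CACAGTG, ≤1 mismatch, ±25 bp) annotation of deletion breakpoints.
- **MLPA concordance** (`leukotype.mlpa`). Probe dosage
  `r = (p·ccf·cn + (1 − p·ccf)·2)/2`, deletion call at ≥2 consecutive probes
  with r < 0.75, and categorization of WGS-only deletions as probe placement,
  subclonal (ccf < 0.6), or purity/ploidy.

## Worked example

```python
from leukotype import generate_cohort, paper_roster_config, run

cohort = generate_cohort(paper_roster_config(seed=1))
report = run(cohort)
print(report.summary)
```

Running `python examples/01_roster_cohort_classification.py` prints:

```
cases sequenced           : 57
excluded (<100 SNVs)      : 5
WHO 2016 reclassifications: 5
classified / analyzable   : 46/52 (88%)
named among true B-other  : 41/47
subtype counts:
  DUX4-r             8
  PAX5alt            7
  ZNF384-r           5
  ...
```

Five low-burden samples fail the QC gate (<100 somatic SNVs), five of the 52
analyzable cases turn out to carry a missed WHO 2016 subtype (two
hypodiploid-lineage cases, a near haploid, a high hyperdiploid and a
*TCF3::PBX1*), and 46/52 (88%) of a cohort that standard-of-care called
"B-other" ends up in an established genetic subtype. The other examples walk
through each capability: `02` the enhancer-proximity walk, `03` single-
breakend DUX4 calling, `04` signatures/clock/RAG (the MSH6-loss hypermutator
fits the thio-MMR shape at cosine 0.994 vs 0.825 for the CpG clock
signature; the cohort clock recovers ≈16 mutations/year), and `05` the MLPA
comparison (82/82 deletions concordant; 21 WGS-only events split 14
purity/ploidy, 5 subclonal, 2 probe placement).

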