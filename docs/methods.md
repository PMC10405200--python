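# Methods

This note documents the models, rules and numerical choices behind
`leukotype`, and what the synthetic cohort does and does not emulate.

## Coordinate and breakend conventions

All internal coordinates are 1-based inclusive (VCF-shaped inputs); BED
export is the single place a 0-based half-open conversion happens. Breakend
orientation uses a two-word vocabulary fixed at parse time: `tail` means the
left (reference-5') side of the breakpoint is retained in the derivative
chromosome, `head` the right side. VCF bracket ALTs map onto it as
`t[p[`/`t]p]` → local `tail`, `]p]t`/`[p[t` → local `head`, with the bracket
direction giving the mate's orientation. For intra-chromosomal junctions the
orientation pair implies the SV class (tail→head = deletion, head→tail =
duplication, same-orientation = inversion).

## The mini reference build

A genome build is abstracted behind `MiniGenome`: 23 placed contigs named
like GRCh37 chromosomes, 1.5 Mb each, generated deterministically from a
fixed build seed, plus an 8 kb unplaced contig of tandem 3.3 kb D4Z4-like
units modelling chrUn_gl000228. Gene bodies, the Eμ-IGH and IGK enhancer
anchors, DUX4 partner windows and the 8-gene MLPA panel sit at fixed scaled
coordinates. Real GRCh37 coordinates do not fit the 1.5 Mb contigs, so
printed genomic intervals are planted at scaled positions with their true
lengths preserved (the 102,163 bp intragenic *ERG* deletion keeps its length;
its source interval is recorded in the ground-truth table). Sequence is
i.i.d. uniform ACGT: realistic for k-mer collision and motif-occurrence
statistics, but it contains no repeat families, GC structure or mutational
hotspots, so tests passing here say nothing about alignment-level artefacts
in real genomes — variant calls are this package's inputs by design.

## Proximity walks

The breakend graph holds both orientations of every reference segment;
traversal cost accrues when leaving a segment, so a walk's length is the
reference DNA strictly between the anchor and the target gene (anchor and
target-gene interiors are free), plus any inserted junction sequence. Search
is Dijkstra over (segment-orientation, junctions-used) states with at most 4
variant edges; a candidate needs ≥1 variant edge and cost strictly below
100,000 bp. Reference traversal before the first junction is capped at 50 kb
— "proximity" should not mean walking half a chromosome before the first
rearrangement. The exhaustive simple-path oracle in the tests shows the state
search is exact on small graphs; cost non-negativity makes cycle removal
never worse, so simple paths suffice. Fusion calling reuses the graph:
direct calls require the two junction ends to retain the 5' portion of one
gene and the 3' portion of the other; chained calls (≤2 junctions, <1 Mb
intergenic) require leaving the 5' gene and entering the 3' gene in their
transcriptional directions. Chromothripsis is operationalized as ≥8
consecutive switches between one pair of copy-number states on each of ≥2
chromosomes; the source material describes the oscillation only
qualitatively, so these counts are package conventions.

## DUX4 detection

BLAT-style mapping is replaced by exact k-mer seeding against the packaged
repeat contig (k = 15, match iff ≥5 distinct seed hits and ≥25% of the
read's k-mers hit; strand = majority strand). On random 60–100 nt sequences
the expected number of chance 15-mer hits against an 8 kb contig is ~10⁻³,
so the thresholds sit far from the noise floor; the brute-force intersection
oracle in the tests pins the hit arithmetic. A partner-window single
breakend with repeat-mapping attached sequence suffices for a call; a second
opposite-orientation breakend carrying ≥3 tandem telomeric repeats
(TTAGGG/CCCTAA) upgrades the configuration to an inverted insertion of the
DUX4 locus plus proximal telomere — the configuration that defeats RNA
fusion callers because no chimeric transcript junction exists.

## Ploidy, purity and the subtype ladder

Modal chromosome count is the sum over contigs of the length-weighted modal
total copy number; bands follow B-ALL convention (24–30 near haploid, 31–39
low hypodiploid, 51–65 high hyperdiploid), and a 60–78 count with
genome-wide LOH fraction > 0.5 is read as the chromosome-doubled ("masked")
form of low hypodiploidy and labelled near triploid. The band edges and the
0.5 LOH rule are conventions, chosen once; the doubling test is the only
place the LOH fraction is decisive. Purity is estimated as
2 × median VAF of ≥20 SNVs on total=2/minor=1 segments, clipped to 1 — a
deliberately simple estimator sufficient for QC and MLPA dosage logic, and
testable by recovery (the generator writes VAFs at purity·ccf/2 with σ=0.02
noise; recovery is within ±0.05).

The ladder's rung order encodes lesion mutual exclusivity and resolves the
two known overlaps deliberately: a ZEB2 H1038R co-occurring with a DUX4
rearrangement resolves to DUX4-r (the rearrangement outranks the mutation,
and the co-occurrence is recorded as evidence), and IGH::CEBPB sits inside
ZEB2/CEBP while a standalone IGH::CEBPA is its own single-case subtype —
matching how those overlaps partition in the cohort the roster encodes.
PAX5 P80R requires biallelic targeting; PAX5alt accepts a PAX5 fusion,
intragenic amplification (a sub-gene segment ≥ baseline+2 flanked by
baseline), or non-P80R biallelic targeting. Biallelic mechanisms are
evaluated in fixed order (two_mutations → mutation_plus_deletion →
mutation_plus_LOH → fusion_plus_LOH → monoallelic → none) so each case maps
to exactly one mechanism. RNA consensus needs agreement of ≥2 of 3
expression classifiers, falling back to the reference-clustering label;
contamination or low-purity flags void the RNA arm. Reconciliation never
overwrites the WGS label.

## Signatures, clock and RAG

The packaged 96×7 signature matrix is synthetic but shape-faithful (SBS1 as
CpG C>T; a broad C>T clock-like blood signature; flat SBS5-like; T>G/T>C
SBS9; C>A SBS18; two MMR-deficiency shapes, one thiopurine-flavored
overlapping SBS1's CpG peaks). Absolute exposures are therefore not
comparable to any published catalog; all signature results in this package
are recovery and ordering properties (mixture fractions within ±0.03 at
n=20,000; the hypermutator catalog scoring higher against the thio-MMR shape
than against SBS1), which is also exactly what the acceptance surface
checks. Refitting is scipy NNLS on the column-normalized matrix; the
residual is bounded by random non-negative candidates in the tests. The
clock is `statsmodels` RLM with Huber's M-estimator (c = 1.345) — the Python
equivalent of the `MASS::rlm` default — with normal-approximation 95% CIs;
hypermutators (burden > max(10 × cohort median, 10,000)) are excluded before
fitting. RAG attribution replaces de-novo motif discovery with a fixed scan:
a deletion is RAG-attributed iff the RSS heptamer CACAGTG (either strand,
≤1 mismatch) occurs within ±25 bp of either breakpoint; window and mismatch
are documented configuration, not biological constants.

## MLPA model

Probe dosage is modelled as r = (p·ccf·cn + (1 − p·ccf)·2)/2 against a
diploid normal, with a gene called deleted at ≥2 consecutive probes below
0.75 — an operationalization of P335-kit dosage analysis; the acceptance
surface is the discrepancy categories, not the ratios. WGS calls a gene
deleted when any segment below the chromosome's modal copy number overlaps
the gene at ccf > 0.1 (per-chromosome baselines keep aneuploid genomes from
flooding the panel with pseudo-deletions). WGS-only events are categorized
in precedence order probe_placement → subclonal (ccf < 0.6) → purity_ploidy,
chosen so each planted fixture maps to exactly one category.

## The synthetic cohort and the roster preset

The generator plants lesions through a per-case builder: chromosome-level CN
states plus non-overlapping focal events materialize into a full-cover
segment profile; junction orientations for fusions are derived from gene
strands; SNV contexts are drawn from signature mixtures and placed on two
designated diploid chromosomes so reference bases, VAFs and purity recovery
stay consistent; RAG deletions are planted at genomic heptamer occurrences
(non-RAG plantings are rejection-sampled to be motif-free within the
annotation window) on three chromosomes away from anchors and panel genes.
Clock-like burden is round(16 × age) plus a 50–300 SNV non-clock remainder;
ages are uniform on 25–65 (an adult trial population); default purity is
0.85–0.97 with the low-purity cases set explicitly (0.28–0.50). The
`paper-roster` preset pins the full 57-case lesion roster — subtype counts,
the 82 MLPA-detectable deletions across 32 cases (counts 1–4, median 3), the
14/5/2 discrepancy plantings in 15 cases, the 10/11 biallelic PAX5
configurations, the 49/69 RAG outlier, and a 15,000-SNV hypermutator (the
published case's 77k burden scaled to desk size; every shape property is
scale-free). Tallies are seed-invariant because the roster, not the sampler,
fixes every count; seeds move breakpoints and noise only. Generation takes a
few seconds; the full pipeline a few hundred milliseconds.

What passing on this cohort shows: the detection rules, ladder and
comparators implement the intended decision surfaces exactly. What it does
not show: performance on real WGS calls, where caller noise, impure
segmentations and reference artefacts precede this layer.

## Known limitations

No read-level evidence (BAM/CRAM) anywhere; no junction-balanced CN fitting
or full karyotype reconstruction; no de-novo signature extraction and no
indel/doublet signatures; telomere length and expression-based classifier
internals are out of scope (RNA enters as labels); iAMP21 is noted only as a
chr21 gain; the walk search truncates at 4 junctions.
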