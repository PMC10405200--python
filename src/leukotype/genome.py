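"""Synthetic mini reference build.

A desk-scale genome with contigs named like GRCh37 chromosomes (chr1-chr22,
chrX at 1.5 Mb each) plus one unplaced macrosatellite repeat contig modelled on
chrUn_gl000228 (the hg19 contig of D4Z4 repeats containing DUX4). Sequence is
generated deterministically from a fixed build seed, so every run of the
package sees the same reference without shipping megabytes of FASTA. Gene
bodies, immunoglobulin enhancer anchors and partner windows are placed at fixed
coordinates scaled to the mini build; a real GRCh37 can be substituted through
the same interface.
"""
from __future__ import annotations

import functools
import re
from importlib import resources

import numpy as np

from .model import GenomicInterval
from .sequtils import codes_to_str, revcomp, str_to_codes

BUILD_SEED = 20230304  # fixed: the reference is an artifact, not a simulation knob
CHROM_LENGTH = 1_500_000
PLACED_CONTIGS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)
REPEAT_CONTIG = "chrUn_repeat228"

#: chromosomes on which simulated SNVs are placed (kept diploid-heterozygous in
#: most templates so VAFs are purity-informative)
MUTATION_CHROMS = ("chr2", "chr3")
#: chromosomes used for planting RAG / non-RAG deletions, chosen away from the
#: immunoglobulin anchors and the MLPA panel genes
RAG_CHROMS = ("chr10", "chr15", "chr16")

# name: (chrom, start, end, strand)
_GENES: dict[str, tuple[str, int, int, str]] = {
    # IG enhancer-hijack partner genes
    "DUX4": ("chr4", 1_430_000, 1_440_000, "+"),
    "EPOR": ("chr19", 500_000, 530_000, "-"),
    "CEBPA": ("chr19", 900_000, 905_000, "-"),
    "CEBPB": ("chr20", 700_000, 705_000, "+"),
    "MIR125B1": ("chr11", 1_100_000, 1_101_000, "-"),
    "ID4": ("chr6", 200_000, 205_000, "+"),
    "BCL2": ("chr18", 600_000, 800_000, "-"),
    # fusion genes
    "ZNF384": ("chr12", 100_000, 130_000, "-"),
    "EP300": ("chr22", 400_000, 490_000, "+"),
    "AKAP8": ("chr19", 200_000, 230_000, "-"),
    "TCF3": ("chr19", 300_000, 330_000, "-"),
    "PBX1": ("chr1", 500_000, 790_000, "+"),
    "MEF2D": ("chr1", 1_000_000, 1_040_000, "-"),
    "BCL9": ("chr1", 900_000, 985_000, "+"),
    "HNRNPUL1": ("chr19", 1_100_000, 1_140_000, "+"),
    "ATXN7L3": ("chr17", 780_000, 790_000, "-"),
    "UBTF": ("chr17", 810_000, 825_000, "-"),
    "CDX2": ("chr13", 250_000, 260_000, "-"),
    "PAN3": ("chr13", 300_000, 340_000, "+"),
    "P2RY8": ("chrX", 50_000, 55_000, "+"),
    "CRLF2": ("chrX", 100_000, 110_000, "+"),
    "MYO18A": ("chr17", 200_000, 300_000, "-"),
    "FGFR1": ("chr8", 300_000, 360_000, "-"),
    "KDM6A": ("chrX", 500_000, 740_000, "+"),
    "ERG": ("chr21", 780_000, 920_000, "-"),
    # MLPA panel tumor suppressors
    "EBF1": ("chr5", 800_000, 1_190_000, "-"),
    "IKZF1": ("chr7", 200_000, 300_000, "+"),
    "CDKN2A": ("chr9", 400_000, 430_000, "-"),
    "CDKN2B": ("chr9", 440_000, 450_000, "-"),
    "PAX5": ("chr9", 700_000, 900_000, "-"),
    "ETV6": ("chr12", 500_000, 750_000, "+"),
    "BTG1": ("chr12", 1_100_000, 1_110_000, "-"),
    "RB1": ("chr13", 800_000, 980_000, "+"),
    # recurrently mutated genes
    "ZEB2": ("chr2", 1_000_000, 1_060_000, "-"),
    "IDH1": ("chr2", 1_200_000, 1_215_000, "-"),
    "IDH2": ("chr15", 600_000, 620_000, "-"),
    "TP53": ("chr17", 100_000, 120_000, "-"),
    "PTPN2": ("chr18", 200_000, 210_000, "-"),
    "WT1": ("chr11", 300_000, 350_000, "-"),
    "ASXL1": ("chr20", 400_000, 410_000, "+"),
    "MSH6": ("chr2", 700_000, 724_000, "+"),
    "FOXP1": ("chr3", 600_000, 900_000, "-"),
    "NRAS": ("chr1", 100_000, 110_000, "-"),
    "KRAS": ("chr12", 300_000, 330_000, "-"),
}

# immunoglobulin loci and enhancer anchors (mini-build surrogates of
# 14q32.33 IGH / 2p11.2 IGK)
IGH_LOCUS = GenomicInterval("chr14", 1_150_000, 1_400_000)
IGH_EMU_ANCHOR = GenomicInterval("chr14", 1_300_000, 1_301_500)
IGK_LOCUS = GenomicInterval("chr2", 300_000, 400_000)
IGK_ANCHOR = GenomicInterval("chr2", 350_000, 351_000)

#: window around the D4Z4/DUX4 macrosatellite on the 4q surrogate subtelomere
DUX4_LOCUS_WINDOW = GenomicInterval("chr4", 1_400_000, 1_490_000)
#: partner windows for DUX4 rearrangement calling
DUX4_PARTNER_WINDOWS: dict[str, GenomicInterval] = {
    "IGH": IGH_LOCUS,
    "ERG": GenomicInterval("chr21", 730_000, 970_000),
}

RSS_HEPTAMER = "CACAGTG"


def gene_models() -> dict[str, GenomicInterval]:
    return {
        name: GenomicInterval(c, s, e, strand)
        for name, (c, s, e, strand) in _GENES.items()
    }


class MiniGenome:
    """Deterministic synthetic reference with lazy per-contig sequence."""

    def __init__(self, build_seed: int = BUILD_SEED, chrom_length: int = CHROM_LENGTH):
        self.build_seed = build_seed
        self.contig_lengths: dict[str, int] = {c: chrom_length for c in PLACED_CONTIGS}
        self.genes = gene_models()
        self._seqs: dict[str, str] = {}

    # -- sequence access -------------------------------------------------
    def seq(self, chrom: str) -> str:
        if chrom == REPEAT_CONTIG:
            return repeat_contig_seq()
        if chrom not in self.contig_lengths:
            raise KeyError(f"unknown contig {chrom!r}")
        if chrom not in self._seqs:
            idx = PLACED_CONTIGS.index(chrom)
            rng = np.random.default_rng(np.random.SeedSequence([self.build_seed, idx]))
            codes = rng.integers(0, 4, size=self.contig_lengths[chrom], dtype=np.uint8)
            self._seqs[chrom] = codes_to_str(codes)
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice."""
        if start < 1 or end > len(self.seq(chrom)):
            raise ValueError(f"{chrom}:{start}-{end} outside contig")
        return self.seq(chrom)[start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    # -- derived indexes -------------------------------------------------
    @functools.lru_cache(maxsize=None)
    def trinuc_positions(self, chrom: str) -> dict[str, np.ndarray]:
        """1-based center positions keyed by pyrimidine-folded trinucleotide."""
        codes = str_to_codes(self.seq(chrom)).astype(np.int32)
        raw = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
        lut = np.empty(64, dtype=np.int8)
        folded_names: list[str] = []
        fold_of: dict[str, int] = {}
        for code in range(64):
            tri = "ACGT"[code // 16] + "ACGT"[(code // 4) % 4] + "ACGT"[code % 4]
            f = tri if tri[1] in "CT" else revcomp(tri)
            if f not in fold_of:
                fold_of[f] = len(folded_names)
                folded_names.append(f)
            lut[code] = fold_of[f]
        folded = lut[raw]
        out: dict[str, np.ndarray] = {}
        for name, idx in fold_of.items():
            out[name] = np.flatnonzero(folded == idx).astype(np.int64) + 2  # 1-based center
        return out

    @functools.lru_cache(maxsize=None)
    def heptamer_sites(self, chrom: str) -> np.ndarray:
        """1-based start positions of exact RSS heptamer matches (either strand)."""
        seq = self.seq(chrom)
        pat = re.compile(f"(?=({RSS_HEPTAMER}|{revcomp(RSS_HEPTAMER)}))")
        return np.array(sorted(m.start() + 1 for m in pat.finditer(seq)), dtype=np.int64)


@functools.lru_cache(maxsize=1)
def repeat_contig_seq() -> str:
    """Sequence of the packaged D4Z4-like repeat contig."""
    text = resources.files("leukotype.data").joinpath("repeat_contig.fa").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


@functools.lru_cache(maxsize=1)
def default_genome() -> MiniGenome:
    return MiniGenome()
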