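"""Seeded synthetic cohort generator.

Produces B-other ALL cohorts with the statistical and lesion structure the
downstream analysis assumes: subtype-defining SVs and point mutations planted
inside the mini reference build, copy-number profiles with ploidy classes,
signature-mixture SNV burdens tied to age by a clock-like component, RAG-motif
deletions, MLPA-visible and MLPA-invisible focal deletions, and RNA classifier
labels with configurable quality flags. Every planted lesion is recorded in a
ground-truth table so recovery is testable.

The ``paper-roster`` preset hard-codes a 57-case roster (52 analyzable plus 5
low-burden) whose per-subtype lesion tally mirrors the published cohort this
pipeline re-implements, making cohort-level tallies reproducible end to end.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import genome as gn
from .genome import MiniGenome, default_genome
from .model import (
    HEAD,
    TAIL,
    BreakendEnd,
    BreakendPair,
    Case,
    Cohort,
    CopyNumberSegment,
    GenomicInterval,
    RnaEvidence,
    SingleBreakend,
    SmallVariant,
)
from .sequtils import revcomp
from .signatures import CONTEXT_LABELS, load_reference, rss_at_breakpoint

CLOCK_SLOPE = 16.0  # clock-like SNVs per year of life
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    seed: int
    preset: Optional[str] = None  # "paper-roster" or None
    per_subtype_counts: dict[str, int] = field(default_factory=dict)
    low_burden_count: int = 0
    clock_slope: float = CLOCK_SLOPE
    default_purity: tuple[float, float] = (0.85, 0.97)

    @property
    def case_count(self) -> int:
        return sum(self.per_subtype_counts.values()) + self.low_burden_count


def paper_roster_config(seed: int) -> CohortConfig:
    return CohortConfig(seed=seed, preset="paper-roster")


# ---------------------------------------------------------------------------
# mutation simulation
# ---------------------------------------------------------------------------

def _mixture_probs(weights: dict[str, float]) -> np.ndarray:
    ref = load_reference()
    p = np.zeros(96)
    for name, w in weights.items():
        if w < 0:
            raise ValueError("mixture weights must be non-negative")
        p += w * ref[name].to_numpy()
    return p / p.sum()


def simulate_mutations(
    mixture_weights: dict[str, float],
    n: int,
    rng: np.random.Generator,
    reference: Optional[MiniGenome] = None,
    purity: float = 0.9,
    ccf: float = 1.0,
) -> list[SmallVariant]:
    """Draw ``n`` SNVs whose trinucleotide contexts follow a signature mixture.

    Positions are sampled (without replacement per context) from the
    designated mutation chromosomes of the mini build, so reference bases
    always agree with the planted ref alleles. VAFs model clonal heterozygous
    events on diploid background at the given purity.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    reference = reference or default_genome()
    probs = _mixture_probs(mixture_weights)
    counts = rng.multinomial(n, probs)
    pools: dict[str, list[tuple[str, np.ndarray]]] = {}
    out: list[SmallVariant] = []
    for b, c in enumerate(counts):
        if c == 0:
            continue
        lab = CONTEXT_LABELS[b]  # e.g. A[C>T]G
        tri = lab[0] + lab[2] + lab[6]
        alt_pyr = lab[4]
        if tri not in pools:
            pools[tri] = [
                (chrom, reference.trinuc_positions(chrom)[tri]) for chrom in gn.MUTATION_CHROMS
            ]
        sizes = np.array([len(p) for _, p in pools[tri]])
        idx = rng.choice(int(sizes.sum()), size=int(c), replace=False)
        for i in np.sort(idx):
            j = 0
            while i >= sizes[j]:
                i -= sizes[j]
                j += 1
            chrom, positions = pools[tri][j]
            pos = int(positions[i])
            ref_base = reference.base(chrom, pos)
            alt = alt_pyr if ref_base in "CT" else _COMP[alt_pyr]
            vaf = float(np.clip(rng.normal(purity * ccf / 2, 0.02), 0.01, 1.0))
            out.append(SmallVariant((chrom, pos), ref_base, alt, vaf, classification="SNV"))
    return out


def plant_rag_deletions(
    case: Case,
    k: int,
    rng: np.random.Generator,
    reference: Optional[MiniGenome] = None,
    k_non_rag: int = 0,
    window: int = 25,
) -> list[dict]:
    """Add ``k`` deletions carrying an RSS heptamer at a breakpoint (plus
    optional motif-free deletions); returns ground-truth rows."""
    if k < 0 or k_non_rag < 0:
        raise ValueError("counts must be >= 0")
    reference = reference or default_genome()
    rows = []
    lo, hi = 100_000, 1_390_000
    chroms = gn.RAG_CHROMS

    def bad_zone(chrom: str, pos: int) -> bool:
        return chrom == "chr15" and 550_000 <= pos <= 670_000

    n_existing = len(case.svs)
    for i in range(k):
        while True:
            chrom = chroms[rng.integers(len(chroms))]
            sites = reference.heptamer_sites(chrom)
            sites = sites[(sites > lo) & (sites < hi - 110_000)]
            h = int(sites[rng.integers(len(sites))])
            p = h + int(rng.integers(-10, 11))
            size = int(rng.integers(1_000, 100_000))
            q = p + size
            if not (bad_zone(chrom, p) or bad_zone(chrom, q)) and lo < p < q < hi:
                break
        sv_id = f"{case.case_id}_rag{n_existing + i}"
        case.svs.append(BreakendPair(sv_id, BreakendEnd(chrom, p, TAIL), BreakendEnd(chrom, q, HEAD)))
        rows.append({"case_id": case.case_id, "category": "rag_deletion", "name": sv_id,
                     "chrom": chrom, "start": p, "end": q})
    for i in range(k_non_rag):
        while True:
            chrom = chroms[rng.integers(len(chroms))]
            p = int(rng.integers(lo, hi - 110_000))
            size = int(rng.integers(1_000, 100_000))
            q = p + size
            if bad_zone(chrom, p) or bad_zone(chrom, q):
                continue
            if rss_at_breakpoint(reference, chrom, p, window) or rss_at_breakpoint(reference, chrom, q, window):
                continue  # keep non-RAG plantings clean of the motif
            break
        sv_id = f"{case.case_id}_del{n_existing + k + i}"
        case.svs.append(BreakendPair(sv_id, BreakendEnd(chrom, p, TAIL), BreakendEnd(chrom, q, HEAD)))
        rows.append({"case_id": case.case_id, "category": "nonrag_deletion", "name": sv_id,
                     "chrom": chrom, "start": p, "end": q})
    return rows


# ---------------------------------------------------------------------------
# case builder
# ---------------------------------------------------------------------------

class CaseBuilder:
    """Accumulates planted lesions for one case, then materializes a Case."""

    def __init__(self, case_id: str, rng: np.random.Generator, reference: MiniGenome,
                 age: float, sex: str, purity: float, karyotype: str = "nonspecific-abnormal"):
        self.case = Case(case_id, age=age, sex=sex, karyotype_class=karyotype, purity=purity)
        self.rng = rng
        self.ref = reference
        self.chrom_states: dict[str, tuple[int, int]] = {}  # chrom -> (total, minor)
        self.focal: list[tuple[str, int, int, int, int, float]] = []
        self.truth: list[dict] = []
        self._sv_n = 0

    # -- low-level helpers ------------------------------------------------
    def _sv_id(self) -> str:
        self._sv_n += 1
        return f"{self.case.case_id}_sv{self._sv_n}"

    def note(self, category: str, name: str, **extra) -> None:
        self.truth.append({"case_id": self.case.case_id, "category": category, "name": name, **extra})

    def set_chrom_state(self, chroms, total: int, minor: int) -> None:
        for c in chroms:
            self.chrom_states[c] = (total, minor)

    def add_focal_cn(self, chrom: str, start: int, end: int, total: int, minor: int, ccf: float = 1.0) -> None:
        for (c, s, e, *_rest) in self.focal:
            if c == chrom and s <= end and start <= e:
                raise ValueError(f"{self.case.case_id}: overlapping focal CN plantings on {chrom}")
        self.focal.append((chrom, start, end, total, minor, ccf))

    def add_gene_deletion(self, gene: str, cn: int = 1, ccf: float = 1.0, category: str = "deletion_detected") -> None:
        iv = self.ref.genes[gene]
        self.add_focal_cn(iv.chrom, iv.start - 1_000, iv.end + 1_000, cn, 0, ccf)
        self.note(category, gene, chrom=iv.chrom, start=iv.start - 1_000, end=iv.end + 1_000, ccf=ccf)

    def add_micro_deletion(self, gene: str, start: int, end: int, category: str = "deletion_missed_placement") -> None:
        iv = self.ref.genes[gene]
        self.add_focal_cn(iv.chrom, start, end, 1, 0, 1.0)
        self.note(category, gene, chrom=iv.chrom, start=start, end=end)

    def add_driver_variant(self, gene: str, protein_change: str, vaf: Optional[float] = None,
                           kind: str = "SNV") -> None:
        iv = self.ref.genes[gene]
        pos = int(self.rng.integers(iv.start + 100, iv.end - 100))
        ref_base = self.ref.base(iv.chrom, pos)
        if vaf is None:
            vaf = float(np.clip(self.rng.normal(self.case.purity / 2, 0.02), 0.02, 1.0))
        if kind == "SNV":
            alt = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        elif kind == "insertion":
            alt = ref_base + "A"
        else:  # small deletion: ref covers 2 bases
            ref_base = self.ref.fetch(iv.chrom, pos, pos + 1)
            alt = ref_base[0]
        self.case.small_variants.append(
            SmallVariant((iv.chrom, pos), ref_base, alt, vaf, gene, protein_change)
        )
        self.note("driver_variant", f"{gene} {protein_change}", chrom=iv.chrom, start=pos, end=pos, vaf=round(vaf, 3))

    def add_fusion(self, gene5: str, gene3: str) -> BreakendPair:
        iv5, iv3 = self.ref.genes[gene5], self.ref.genes[gene3]
        p = int(self.rng.integers(iv5.start + len(iv5) // 4, iv5.end - len(iv5) // 4))
        q = int(self.rng.integers(iv3.start + len(iv3) // 4, iv3.end - len(iv3) // 4))
        o5 = TAIL if iv5.strand == "+" else HEAD  # retain the 5' portion
        o3 = HEAD if iv3.strand == "+" else TAIL  # retain the 3' portion
        sv = BreakendPair(self._sv_id(), BreakendEnd(iv5.chrom, p, o5), BreakendEnd(iv3.chrom, q, o3))
        self.case.svs.append(sv)
        self.note("fusion", f"{gene5}::{gene3}", chrom=iv5.chrom, start=p, end=q)
        return sv

    def add_ig_hijack(self, anchor: GenomicInterval, gene: str, anchor_name: str = "IGH") -> BreakendPair:
        iv = self.ref.genes[gene]
        d1 = int(self.rng.integers(4_000, 35_000))
        d2 = int(self.rng.integers(4_000, 28_000))
        a_end = BreakendEnd(anchor.chrom, anchor.end + d1, TAIL)
        if iv.strand == "+":
            g_end = BreakendEnd(iv.chrom, iv.start - d2, HEAD)
        else:
            g_end = BreakendEnd(iv.chrom, iv.end + d2, TAIL)
        sv = BreakendPair(self._sv_id(), a_end, g_end)
        self.case.svs.append(sv)
        self.note("ig_hijack", f"{anchor_name}::{gene}", chrom=iv.chrom, start=a_end.pos, end=g_end.pos,
                  detail=f"walk={d1 + d2}bp")
        return sv

    def add_single_breakend(self, chrom: str, pos: int, orientation: str, unplaced: str, label: str) -> None:
        base = self.ref.base(chrom, pos)
        seq = base + unplaced if orientation == TAIL else unplaced + base
        sb = SingleBreakend(self._sv_id(), BreakendEnd(chrom, pos, orientation), seq)
        self.case.single_breakends.append(sb)
        self.note("single_breakend", label, chrom=chrom, start=pos, end=pos)

    def repeat_fragment(self, length: int = 80, rc: bool = False) -> str:
        contig = gn.repeat_contig_seq()
        off = int(self.rng.integers(0, len(contig) - length))
        frag = contig[off : off + length]
        return revcomp(frag) if rc else frag

    def add_oscillation(self, chrom: str, start: int, n_segments: int = 12, seg_len: int = 20_000) -> None:
        for i in range(n_segments):
            cn = 2 if i % 2 == 0 else 1
            s = start + i * seg_len
            self.add_focal_cn(chrom, s, s + seg_len - 1, cn, 1 if cn == 2 else 0, 1.0)
        self.note("oscillation", chrom, chrom=chrom, start=start, end=start + n_segments * seg_len - 1)

    def add_background_snvs(self, n: int, mixture: dict[str, float]) -> None:
        self.case.small_variants.extend(
            simulate_mutations(mixture, n, self.rng, self.ref, purity=self.case.purity)
        )

    def set_rna(self, label: str, fusions=(), flags=(), cluster: Optional[str] = None,
                split: Optional[tuple[str, str, str]] = None) -> None:
        labels = split if split else (label, label, "B-other")
        self.case.rna = RnaEvidence(
            classifier_labels={"classifier1": labels[0], "classifier2": labels[1], "classifier3": labels[2]},
            cluster_label=cluster if cluster is not None else label,
            fusions=[tuple(f) for f in fusions],
            quality_flags=set(flags),
        )

    # -- materialization ---------------------------------------------------
    def build(self) -> Case:
        segments: list[CopyNumberSegment] = []
        for chrom, length in self.ref.contig_lengths.items():
            total, minor = self.chrom_states.get(chrom, (2, 1))
            events = sorted((f for f in self.focal if f[0] == chrom), key=lambda f: f[1])
            cursor = 1
            for (_c, s, e, t, m, ccf) in events:
                if s > cursor:
                    segments.append(CopyNumberSegment(GenomicInterval(chrom, cursor, s - 1), total, minor))
                segments.append(CopyNumberSegment(GenomicInterval(chrom, s, e), t, m, ccf))
                cursor = e + 1
            if cursor <= length:
                segments.append(CopyNumberSegment(GenomicInterval(chrom, cursor, length), total, minor))
        self.case.segments = segments
        return self.case


# ---------------------------------------------------------------------------
# subtype templates (generic mode + self-consistency testing)
# ---------------------------------------------------------------------------

@dataclass
class SubtypeTemplate:
    label: str
    plant: Callable[[CaseBuilder], None]
    rna_label: str = ""
    unclassifiable: bool = False


def _t_dux4(b: CaseBuilder) -> None:
    anchor = gn.IGH_EMU_ANCHOR
    pos = int(b.rng.integers(gn.IGH_LOCUS.start + 20_000, anchor.start - 20_000))
    b.add_single_breakend(anchor.chrom, pos, TAIL, b.repeat_fragment(), "IGH::DUX4 single breakend")


def _t_pax5alt(b: CaseBuilder) -> None:
    b.add_driver_variant("PAX5", "R38H")
    b.add_driver_variant("PAX5", "R140L")


def _t_p80r(b: CaseBuilder) -> None:
    b.add_driver_variant("PAX5", "P80R")
    b.add_focal_cn("chr9", 1, 950_000, 2, 0, 1.0)  # arm-level copy-neutral LOH


def _t_znf384(b: CaseBuilder) -> None:
    b.add_fusion("EP300", "ZNF384")


def _t_zeb2(b: CaseBuilder) -> None:
    b.add_driver_variant("ZEB2", "H1038R")


def _t_mef2d(b: CaseBuilder) -> None:
    b.add_fusion("MEF2D", "BCL9")


def _t_ubtf(b: CaseBuilder) -> None:
    b.add_fusion("UBTF", "ATXN7L3")
    b.add_focal_cn("chr13", 262_000, 298_000, 1, 0, 1.0)  # 13q12.2-like deletion


def _t_jakstat(b: CaseBuilder) -> None:
    b.add_fusion("P2RY8", "CRLF2")


def _t_idh(b: CaseBuilder) -> None:
    b.add_driver_variant("IDH2", "R140Q")


def _t_low_hypodiploid(b: CaseBuilder) -> None:
    lost = ["chr1", "chr4", "chr6", "chr8", "chr10", "chr11", "chr14", "chr15",
            "chr16", "chr17", "chr18", "chr20", "chr21"]
    b.set_chrom_state(lost, 1, 0)
    b.add_driver_variant("TP53", "R248Q")


def _t_near_haploid(b: CaseBuilder) -> None:
    kept = {"chr2", "chr3", "chr21"}
    b.set_chrom_state([c for c in gn.PLACED_CONTIGS if c not in kept], 1, 0)


def _t_high_hyperdiploid(b: CaseBuilder) -> None:
    b.set_chrom_state(["chr4", "chr6", "chr8", "chr10", "chr14", "chr17", "chr18", "chr21", "chrX"], 3, 1)


def _t_near_triploid(b: CaseBuilder) -> None:
    loh = ["chr1", "chr2", "chr3", "chr4", "chr5", "chr7", "chr9", "chr12",
           "chr13", "chr17", "chr19", "chr22", "chrX"]
    b.set_chrom_state(loh, 2, 0)
    b.set_chrom_state([c for c in gn.PLACED_CONTIGS if c not in loh], 4, 2)
    b.add_driver_variant("TP53", "N239D", vaf=0.87)


def _t_tcf3pbx1(b: CaseBuilder) -> None:
    b.add_fusion("TCF3", "PBX1")


def _t_igk_bcl2(b: CaseBuilder) -> None:
    b.add_ig_hijack(gn.IGK_ANCHOR, "BCL2", "IGK")


def _t_unclassifiable(b: CaseBuilder) -> None:
    b.add_driver_variant("ASXL1", "R417*")


def _t_no_driver(b: CaseBuilder) -> None:
    pass


TEMPLATES: dict[str, SubtypeTemplate] = {
    t.label: t
    for t in [
        SubtypeTemplate("DUX4-r", _t_dux4, "DUX4-r"),
        SubtypeTemplate("PAX5alt", _t_pax5alt, "PAX5alt"),
        SubtypeTemplate("PAX5 P80R", _t_p80r, "PAX5 P80R"),
        SubtypeTemplate("ZNF384-r", _t_znf384, "ZNF384-r"),
        SubtypeTemplate("ZEB2/CEBP", _t_zeb2, "ZEB2/CEBP"),
        SubtypeTemplate("MEF2D-r", _t_mef2d, "MEF2D-r"),
        SubtypeTemplate("UBTF::ATXN7L3", _t_ubtf, "UBTF::ATXN7L3"),
        SubtypeTemplate("Ph-like JAK-STAT", _t_jakstat, "Ph-like JAK-STAT"),
        SubtypeTemplate("IDH1/2", _t_idh, "PAX5alt"),
        SubtypeTemplate("low-hypodiploid", _t_low_hypodiploid),
        SubtypeTemplate("near-haploid", _t_near_haploid),
        SubtypeTemplate("high-hyperdiploid", _t_high_hyperdiploid),
        SubtypeTemplate("near-triploid", _t_near_triploid),
        SubtypeTemplate("TCF3::PBX1", _t_tcf3pbx1),
        SubtypeTemplate("IGK::BCL2", _t_igk_bcl2),
        SubtypeTemplate("unclassifiable", _t_unclassifiable, unclassifiable=True),
        SubtypeTemplate("no-driver", _t_no_driver, unclassifiable=True),
    ]
}

DEFAULT_MIXTURE = {"SBSblood": 0.72, "SBS5like": 0.16, "SBS1": 0.06, "SBS18": 0.06}
SBS9_MIXTURE = {"SBSblood": 0.45, "SBS9": 0.40, "SBS5like": 0.15}
HYPERMUTATOR_MIXTURE = {"thioMMR": 0.85, "SBS1": 0.10, "SBSblood": 0.05}


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, reference: Optional[MiniGenome] = None) -> Cohort:
    """Deterministic cohort generation; same seed, byte-identical output."""
    reference = reference or default_genome()
    if config.preset == "paper-roster":
        return _build_paper_roster(config, reference)
    for label in config.per_subtype_counts:
        if label not in TEMPLATES:
            raise ValueError(f"no template for subtype {label!r}")
    cases: list[Case] = []
    truth: list[dict] = []
    idx = 0
    for label, count in config.per_subtype_counts.items():
        for _ in range(count):
            idx += 1
            rng = np.random.default_rng([config.seed, idx])
            age = float(np.round(rng.uniform(25, 65), 1))
            purity = float(np.round(rng.uniform(*config.default_purity), 2))
            b = CaseBuilder(f"G{idx:03d}", rng, reference, age, "MF"[int(rng.integers(2))], purity)
            TEMPLATES[label].plant(b)
            n = round(config.clock_slope * age) + int(rng.integers(50, 300))
            b.add_background_snvs(n, DEFAULT_MIXTURE)
            b.note("subtype_truth", label)
            if TEMPLATES[label].rna_label:
                b.set_rna(TEMPLATES[label].rna_label)
            cases.append(b.build())
            truth.extend(b.truth)
    for _ in range(config.low_burden_count):
        idx += 1
        rng = np.random.default_rng([config.seed, idx])
        b = CaseBuilder(f"G{idx:03d}", rng, reference, float(np.round(rng.uniform(25, 65), 1)),
                        "MF"[int(rng.integers(2))], round(float(rng.uniform(0.1, 0.25)), 2),
                        karyotype="normal")
        b.add_background_snvs(int(rng.integers(40, 90)), DEFAULT_MIXTURE)
        b.note("subtype_truth", "excluded_low_burden")
        cases.append(b.build())
        truth.extend(b.truth)
    gt = pd.DataFrame(truth)
    return Cohort(cases, ground_truth=gt, config={"seed": config.seed, "preset": config.preset,
                                                  "n_cases": len(cases)})


# -- the printed-roster preset ----------------------------------------------

# WGS-detected focal deletions per hosting case (the 82 MLPA-concordant events)
_DETECTED_DELS: dict[str, list[str]] = {
    "B006": ["CDKN2A", "CDKN2B", "IKZF1", "BTG1"],
    "B010": ["CDKN2A", "CDKN2B", "ETV6", "RB1"],
    "B014": ["PAX5", "CDKN2B", "IKZF1", "EBF1"],
    "B025": ["CDKN2A", "CDKN2B", "ETV6", "BTG1"],
    "B039": ["CDKN2A", "CDKN2B", "IKZF1", "RB1"],
    "B007": ["CDKN2A", "CDKN2B", "EBF1"],
    "B011": ["CDKN2A", "IKZF1", "PAX5"],
    "B012": ["CDKN2A", "CDKN2B", "BTG1"],
    "B015": ["PAX5", "ETV6", "RB1"],
    "B020": ["PAX5", "CDKN2A", "CDKN2B"],
    "B026": ["CDKN2A", "IKZF1", "ETV6"],
    "B030": ["CDKN2A", "CDKN2B", "PAX5"],
    "B031": ["CDKN2A", "IKZF1", "RB1"],
    "B036": ["CDKN2A", "CDKN2B", "EBF1"],
    "B040": ["CDKN2A", "PAX5", "BTG1"],
    "B043": ["CDKN2A", "CDKN2B", "RB1"],
    "B046": ["CDKN2A", "IKZF1", "EBF1"],
    "B008": ["CDKN2A", "CDKN2B"],
    "B013": ["IKZF1", "PAX5"],
    "B022": ["EBF1", "ETV6"],
    "B027": ["CDKN2A", "BTG1"],
    "B032": ["CDKN2A", "CDKN2B"],
    "B033": ["IKZF1", "ETV6"],
    "B034": ["CDKN2A", "CDKN2B"],
    "B035": ["CDKN2A", "IKZF1"],
    "B037": ["CDKN2A", "CDKN2B"],
    "B041": ["CDKN2A", "IKZF1"],
    "B044": ["CDKN2A", "RB1"],
    "B016": ["CDKN2A"],
    "B018": ["CDKN2B"],
    "B023": ["ETV6"],
    "B045": ["CDKN2A"],
}
#: heterozygous deletions planted in low-purity cases (missed by MLPA dosage)
_PURITY_MISSED: dict[str, list[str]] = {
    "B001": ["CDKN2A", "ETV6"],
    "B002": ["PAX5", "RB1"],
    "B004": ["IKZF1", "CDKN2B"],
    "B009": ["EBF1", "BTG1"],
    "B048": ["CDKN2A"],
    "B049": ["IKZF1"],
    "B050": ["CDKN2A", "RB1"],
    "B052": ["CDKN2A", "PAX5"],
}
#: low-cell-fraction deletions (missed by MLPA, ccf < 0.6)
_SUBCLONAL: dict[str, str] = {
    "B014": "CDKN2A", "B025": "IKZF1", "B030": "BTG1", "B041": "ETV6", "B045": "CDKN2B",
}
_HOM_DEL_CASES = {"B006", "B008"}  # homozygous CDKN2A deletions
_NO_MLPA = {"B005", "B017", "B028", "B047"}  # cases without usable MLPA data
_COMPLEX = ["B006", "B007", "B030", "B034", "B035", "B037", "B043", "B045"]
_FAILED = ["B005", "B036"]
_NORMAL = ["B001", "B002", "B003", "B004", "B008", "B010", "B011", "B013", "B016",
           "B018", "B021", "B023", "B026", "B029", "B032", "B039", "B041", "B048", "B051"]
_FEMALE_DUX4 = {"B006", "B007", "B008", "B010", "B011", "B012"}  # 6 of 8
_RAG_HIGH = {"B006", "B007", "B008", "B009", "B010", "B011", "B012", "B013",
             "B025", "B026", "B027", "B028", "B029"}  # DUX4-r and ZNF384-r
_RAG_LOW = {"B034", "B035", "B036"}  # MEF2D-r


def _build_paper_roster(config: CohortConfig, reference: MiniGenome) -> Cohort:
    cases: list[Case] = []
    truth: list[dict] = []

    def new_builder(i: int, purity: float, karyo_default="nonspecific-abnormal",
                    age: Optional[float] = None) -> CaseBuilder:
        cid = f"B{i:03d}"
        rng = np.random.default_rng([config.seed, i])
        if age is None:
            age = float(np.round(rng.uniform(25, 65), 1))
        karyo = ("complex" if cid in _COMPLEX else
                 "failed" if cid in _FAILED else
                 "normal" if cid in _NORMAL else karyo_default)
        if cid in _FEMALE_DUX4:
            sex = "F"
        else:
            sex = "MF"[int(rng.integers(2))]
        return CaseBuilder(cid, rng, reference, age, sex, purity, karyo)

    def finish(b: CaseBuilder, subtype: str, mixture=None, n_snvs: Optional[int] = None) -> None:
        cid = b.case.case_id
        mixture = mixture or DEFAULT_MIXTURE
        if n_snvs is None:
            n_snvs = round(config.clock_slope * b.case.age) + int(b.rng.integers(50, 300))
        b.add_background_snvs(n_snvs, mixture)
        # focal-deletion plan
        for gene in _DETECTED_DELS.get(cid, []):
            cn = 0 if (gene == "CDKN2A" and cid in _HOM_DEL_CASES) else 1
            b.add_gene_deletion(gene, cn=cn)
        for gene in _PURITY_MISSED.get(cid, []):
            b.add_gene_deletion(gene, cn=1, category="deletion_missed_purity")
        if cid in _SUBCLONAL:
            b.add_gene_deletion(_SUBCLONAL[cid], cn=1, ccf=0.3, category="deletion_missed_subclonal")
        if cid == "B034":  # micro-deletion falling between two consecutive PAX5 probes
            b.add_micro_deletion("PAX5", 745_000, 775_000)
        if cid == "B035":  # micro-deletion between ETV6 probes
            b.add_micro_deletion("ETV6", 570_000, 610_000)
        # RAG-motif deletion load
        if cid == "B046":
            rag, nonrag = 49, 20  # the outlier immunoglobulin-hijack case
        elif cid in _RAG_HIGH:
            rag, nonrag = int(b.rng.integers(9, 15)), int(b.rng.integers(2, 7))
        elif cid in _RAG_LOW:
            rag, nonrag = int(b.rng.integers(1, 3)), int(b.rng.integers(2, 6))
        else:
            rag, nonrag = int(b.rng.integers(4, 10)), int(b.rng.integers(2, 8))
        case = b.build()
        truth_rows = plant_rag_deletions(case, rag, b.rng, reference, k_non_rag=nonrag)
        b.note("subtype_truth", subtype)
        truth.extend(b.truth + truth_rows)
        cases.append(case)
        if case.case_id not in _NO_MLPA:
            from .mlpa import ProbePanel, simulate_mlpa
            case.mlpa = simulate_mlpa(case, ProbePanel.packaged())

    anchor = gn.IGH_EMU_ANCHOR

    # ---- 5 cases with a missed WHO 2016 subtype (low purity) ----
    b = new_builder(1, 0.40)
    _t_low_hypodiploid(b)
    finish(b, "low-hypodiploid", mixture=SBS9_MIXTURE)

    b = new_builder(2, 0.33)
    _t_near_triploid(b)
    finish(b, "near-triploid", mixture=SBS9_MIXTURE)

    b = new_builder(3, 0.46)
    _t_near_haploid(b)
    finish(b, "near-haploid")

    b = new_builder(4, 0.48)
    _t_high_hyperdiploid(b)
    finish(b, "high-hyperdiploid")

    b = new_builder(5, 0.96)
    _t_tcf3pbx1(b)
    finish(b, "TCF3::PBX1")

    # ---- DUX4-r (8): 7 IGH (2 mated pairs, 3 direct single breakends,
    # 2 inverted insertions) + 1 ERG ----
    for i, purity in ((6, 0.90), (7, 0.92)):
        b = new_builder(i, purity)
        b.add_ig_hijack(anchor, "DUX4", "IGH")
        b.add_focal_cn("chr17", 1, 700_000, 1, 0, 1.0)  # 17p loss
        b.add_driver_variant("TP53", "R273H")
        if i == 6:
            # concurrent intragenic ERG deletion (102,163 bp, scaled placement)
            b.case.svs.append(BreakendPair(b._sv_id(), BreakendEnd("chr21", 790_000, TAIL),
                                           BreakendEnd("chr21", 892_163, HEAD)))
            b.add_focal_cn("chr21", 790_000, 892_163, 1, 0, 1.0)
            b.note("sv", "ERG intragenic deletion", chrom="chr21", start=790_000, end=892_163,
                   detail="GRCh37 source interval 21:39773785-39875948")
            b.add_driver_variant("ZEB2", "H1038R", vaf=0.20)  # resolves to DUX4-r
        b.set_rna("DUX4-r", fusions=[("IGH", "DUX4")])
        finish(b, "DUX4-r")

    b = new_builder(8, 0.91)  # hypermutator: homozygous MSH6 loss
    _t_dux4(b)
    b.add_focal_cn("chr2", 699_000, 725_000, 0, 0, 1.0)
    b.note("hypermutator", "MSH6 homozygous loss")
    b.set_rna("DUX4-r", fusions=[("IGH", "DUX4")])
    finish(b, "DUX4-r", mixture=HYPERMUTATOR_MIXTURE, n_snvs=15_000)

    b = new_builder(9, 0.45)  # low purity, RNA quality impaired
    _t_dux4(b)
    b.set_rna("DUX4-r", fusions=[("IGH", "DUX4")], flags=["low_purity"])
    finish(b, "DUX4-r")

    b = new_builder(10, 0.93)
    _t_dux4(b)
    finish(b, "DUX4-r")

    for i in (11, 12):  # inverted insertion of DUX4 locus + proximal telomere
        b = new_builder(i, 0.90)
        pos = int(b.rng.integers(gn.IGH_LOCUS.start + 20_000, anchor.start - 30_000))
        b.add_single_breakend(anchor.chrom, pos, TAIL, b.repeat_fragment(rc=True),
                              "IGH::DUX4 inverted (repeat side)")
        b.add_single_breakend(anchor.chrom, pos + int(b.rng.integers(2_000, 8_000)), HEAD,
                              "TTAGGG" * 15, "IGH::DUX4 inverted (telomere side)")
        b.set_rna("DUX4-r", fusions=[])  # fusion calling misses this configuration
        finish(b, "DUX4-r")

    b = new_builder(13, 0.89)  # ERG::DUX4
    b.case.svs.append(BreakendPair(b._sv_id(), BreakendEnd("chr21", 850_000, TAIL),
                                   BreakendEnd("chr4", 1_452_000, HEAD)))
    b.note("sv", "ERG::DUX4", chrom="chr21", start=850_000, end=1_452_000)
    b.set_rna("DUX4-r", fusions=[("ERG", "DUX4")])
    finish(b, "DUX4-r")

    # ---- PAX5alt (7) ----
    b = new_builder(14, 0.90)
    b.add_fusion("ETV6", "PAX5")
    b.set_rna("PAX5alt", fusions=[("ETV6", "PAX5")])
    finish(b, "PAX5alt")  # PAX5 deletion (fusion + LOH) from the deletion plan

    b = new_builder(15, 0.88)
    b.add_fusion("FOXP1", "PAX5")
    finish(b, "PAX5alt")

    for i in (16, 17, 18):  # R38 + R140 biallelic mutations
        b = new_builder(i, 0.91)
        _t_pax5alt(b)
        if i == 16:
            b.set_rna("PAX5alt", fusions=[("KMT2A", "AFF1")], flags=["contamination"])
        finish(b, "PAX5alt")

    b = new_builder(19, 0.92)  # intragenic PAX5 amplification (the 11th, monoallelic)
    b.add_focal_cn("chr9", 760_000, 820_000, 5, 1, 1.0)
    b.note("amplification", "PAX5 intragenic", chrom="chr9", start=760_000, end=820_000)
    b.set_rna("PAX5alt")
    finish(b, "PAX5alt")

    b = new_builder(20, 0.90)  # deletion + truncating mutation
    b.add_driver_variant("PAX5", "M335fs*68", kind="insertion")
    b.set_rna("PAX5alt")
    finish(b, "PAX5alt")  # PAX5 deletion from the plan -> mutation_plus_deletion

    # ---- PAX5 P80R (4) ----
    for i in (21, 22, 23):
        b = new_builder(i, 0.93)
        _t_p80r(b)
        if i != 22:
            b.set_rna("PAX5 P80R")
        finish(b, "PAX5 P80R")
    b = new_builder(24, 0.91)
    b.add_driver_variant("PAX5", "P80R")
    b.add_driver_variant("PAX5", "R38H")
    finish(b, "PAX5 P80R")

    # ---- ZNF384-r (5) ----
    for i, age in ((25, 28.0), (26, 33.5), (27, 26.0), (28, 38.0)):
        b = new_builder(i, 0.92, age=age)
        b.add_fusion("EP300", "ZNF384")
        if i in (25, 26):
            b.set_rna("ZNF384-r", fusions=[("EP300", "ZNF384")],
                      flags=["contamination"] if i == 26 else [])
        finish(b, "ZNF384-r")
    b = new_builder(29, 0.90)
    b.add_fusion("AKAP8", "ZNF384")
    finish(b, "ZNF384-r")

    # ---- ZEB2/CEBP (4): 2 with IGH::CEBPB, 2 with H1038R alone ----
    for i in (30, 31):
        b = new_builder(i, 0.90)
        b.add_driver_variant("ZEB2", "H1038R")
        b.add_ig_hijack(anchor, "CEBPB", "IGH")
        b.set_rna("ZEB2/CEBP")
        finish(b, "ZEB2/CEBP", mixture=SBS9_MIXTURE if i == 30 else None)
    for i in (32, 33):
        b = new_builder(i, 0.94)
        b.add_driver_variant("ZEB2", "H1038R")
        b.set_rna("ZEB2/CEBP")
        finish(b, "ZEB2/CEBP")

    # ---- MEF2D-r (3) ----
    b = new_builder(34, 0.88)  # chromothripsis chr1/4/9/11 + direct MEF2D::BCL9
    b.add_fusion("MEF2D", "BCL9")
    for chrom in ("chr1", "chr4", "chr9", "chr11"):
        b.add_oscillation(chrom, 100_000)
    b.set_rna("MEF2D-r", fusions=[("MEF2D", "BCL9")])
    finish(b, "MEF2D-r", mixture={"SBSblood": 0.6, "SBS18": 0.3, "SBS5like": 0.1})

    b = new_builder(35, 0.90)  # chromothripsis chr6/9/13 + MEF2D::HNRNPUL1
    b.add_fusion("MEF2D", "HNRNPUL1")
    b.add_oscillation("chr6", 300_000)
    b.add_oscillation("chr9", 100_000)
    b.add_oscillation("chr13", 400_000)
    finish(b, "MEF2D-r", mixture={"SBSblood": 0.6, "SBS18": 0.3, "SBS5like": 0.1})

    b = new_builder(36, 0.92)  # quiet genome; chained inversion+deletion fusion
    p1 = int(b.rng.integers(1_010_000, 1_030_000))
    q = int(b.rng.integers(940_000, 975_000))
    b.case.svs.append(BreakendPair(f"{b.case.case_id}_chain1", BreakendEnd("chr1", p1, HEAD),
                                   BreakendEnd("chr1", 860_500, HEAD)))
    b.case.svs.append(BreakendPair(f"{b.case.case_id}_chain2", BreakendEnd("chr1", 868_000, TAIL),
                                   BreakendEnd("chr1", q, HEAD)))
    b.note("sv", "MEF2D::BCL9 chained (inversion + interstitial jump + deletion)",
           chrom="chr1", start=860_500, end=p1)
    b.set_rna("MEF2D-r", fusions=[("MEF2D", "BCL9")])
    finish(b, "MEF2D-r", mixture={"SBSblood": 0.6, "SBS18": 0.3, "SBS5like": 0.1})

    # ---- UBTF::ATXN7L3 (2) ----
    for i in (37, 38):
        b = new_builder(i, 0.91)
        _t_ubtf(b)
        if i == 37:
            b.set_rna("UBTF::ATXN7L3", fusions=[("UBTF", "ATXN7L3")])
        finish(b, "UBTF::ATXN7L3")

    # ---- IDH1/2 (2): RNA phenocopies PAX5alt ----
    for i in (39, 40):
        b = new_builder(i, 0.93)
        b.add_driver_variant("IDH2", "R140Q")
        b.set_rna("PAX5alt")
        finish(b, "IDH1/2", mixture={"SBSblood": 0.55, "SBS18": 0.30, "SBS5like": 0.15})

    # ---- Ph-like JAK-STAT (2) ----
    b = new_builder(41, 0.92)
    b.add_ig_hijack(anchor, "EPOR", "IGH")
    b.set_rna("Ph-like JAK-STAT")
    finish(b, "Ph-like JAK-STAT")

    b = new_builder(42, 0.90)
    b.add_fusion("P2RY8", "CRLF2")
    b.set_chrom_state(["chr21"], 3, 1)  # single chr21 gain seen on karyotype
    b.set_rna("Ph-like JAK-STAT", fusions=[("P2RY8", "CRLF2")],
              split=("Ph-like JAK-STAT", "Ph-like JAK-STAT", "iAMP21"))
    finish(b, "Ph-like JAK-STAT")

    # ---- single-case IG enhancer hijacks (4) ----
    b = new_builder(43, 0.89)  # IGK::BCL2, high SBS9 burden
    b.add_ig_hijack(gn.IGK_ANCHOR, "BCL2", "IGK")
    b.add_focal_cn("chr17", 1, 700_000, 1, 0, 1.0)
    b.add_driver_variant("TP53", "R175H")
    b.set_rna("IGK::BCL2")
    finish(b, "IGK::BCL2", mixture={"SBSblood": 0.40, "SBS9": 0.42, "SBS5like": 0.18},
           n_snvs=round(CLOCK_SLOPE * 60) + 900)

    b = new_builder(44, 0.90)
    b.add_ig_hijack(anchor, "CEBPA", "IGH")
    b.set_rna("IGH::CEBPA", flags=["contamination"])
    finish(b, "IGH::CEBPA")

    b = new_builder(45, 0.92)  # unbalanced translocation with 14q32 loss
    b.add_ig_hijack(anchor, "ID4", "IGH")
    b.add_focal_cn("chr14", 1_310_000, 1_400_000, 1, 0, 1.0)
    b.set_rna("IGH::ID4")
    finish(b, "IGH::ID4")

    b = new_builder(46, 0.91)  # highest RAG burden (49 of 69 deletions)
    b.add_ig_hijack(anchor, "MIR125B1", "IGH")
    finish(b, "IGH::MIR125B1")

    # ---- named but unclassifiable (5) + no putative driver (1) ----
    b = new_builder(47, 0.90)
    b.add_fusion("MYO18A", "FGFR1")
    finish(b, "unclassifiable")

    b = new_builder(48, 0.47)
    b.add_driver_variant("PTPN2", "A108fs*5", kind="insertion")
    finish(b, "unclassifiable")

    b = new_builder(49, 0.48)
    b.add_driver_variant("WT1", "V371fs*14", kind="insertion")
    b.set_rna("PAX5alt")  # phenocopy call on the RNA side
    finish(b, "unclassifiable")

    b = new_builder(50, 0.45)  # ETV6 R399C + complex intragenic KDM6A SV
    b.add_driver_variant("ETV6", "R399C")
    b.case.svs.append(BreakendPair(f"{b.case.case_id}_kdm6a", BreakendEnd("chrX", 600_000, TAIL),
                                   BreakendEnd("chrX", 650_000, TAIL)))
    b.note("sv", "KDM6A intragenic inversion", chrom="chrX", start=600_000, end=650_000)
    b.set_rna("B-other", flags=["low_purity"], split=("B-other", "Ph-like JAK-STAT", "PAX5alt"))
    finish(b, "unclassifiable")

    b = new_builder(51, 0.90)
    b.add_driver_variant("ASXL1", "R417*")
    finish(b, "unclassifiable")

    b = new_builder(52, 0.28)  # no putative driver at low purity
    finish(b, "no-driver")

    # ---- 5 low-burden excluded cases (cytogenetically "normal") ----
    for i in range(53, 58):
        rng = np.random.default_rng([config.seed, i])
        purity = round(float(rng.uniform(0.12, 0.25)), 2)
        b = CaseBuilder(f"B{i:03d}", rng, reference, float(np.round(rng.uniform(25, 65), 1)),
                        "MF"[int(rng.integers(2))], purity, karyotype="normal")
        if i == 53:  # the low-purity IGH::CEBPA detectable by the walk workflow
            b.add_ig_hijack(anchor, "CEBPA", "IGH")
        b.add_background_snvs(int(b.rng.integers(40, 90)), DEFAULT_MIXTURE)
        b.note("subtype_truth", "excluded_low_burden")
        cases.append(b.build())
        truth.extend(b.truth)

    gt = pd.DataFrame(truth)
    return Cohort(cases, ground_truth=gt,
                  config={"seed": config.seed, "preset": "paper-roster", "n_cases": len(cases)})
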