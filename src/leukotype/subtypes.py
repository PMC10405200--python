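"""Rule-based genomic subtype assignment for B-other ALL.

Each QC-passing case is pushed through a deterministic precedence ladder that
integrates ploidy class, WHO-defining fusions, DUX4 rearrangement calls,
enhancer-hijack walk candidates, defining point mutations and biallelic PAX5
logic. The top matching rung wins, the evidence chain is recorded, and the RNA
arm (expression-classifier consensus plus fusion calls) is reconciled against
the WGS label without ever overwriting it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .dux4 import Dux4Call
from .graph import WalkCandidate
from .model import Case, CopyNumberSegment, GenomicInterval, RnaEvidence

QC_MIN_SNVS = 100

WHO_PLOIDY_LABELS = ("near-haploid", "low-hypodiploid", "high-hyperdiploid", "near-triploid")
WHO_FUSIONS = {
    ("TCF3", "PBX1"): "TCF3::PBX1",
    ("BCR", "ABL1"): "BCR::ABL1",
    ("ETV6", "RUNX1"): "ETV6::RUNX1",
}
IG_HIJACK_PARTNERS = ("BCL2", "ID4", "MIR125B1", "CEBPA")
#: reportable-but-unclassifiable lesion watchlist
WATCHLIST_FUSIONS = {("MYO18A", "FGFR1")}
WATCHLIST_GENES = ("PTPN2", "WT1", "ETV6", "ASXL1", "KDM6A")

NON_SUBTYPE_LABELS = ("unclassifiable", "no-driver")


def qc_gate(case: Case, min_snvs: int = QC_MIN_SNVS) -> str:
    """Exclude cases whose somatic SNV burden suggests low tumor content."""
    return "included" if len(case.snvs) >= min_snvs else "excluded_low_burden"


# ---------------------------------------------------------------------------
# ploidy
# ---------------------------------------------------------------------------

@dataclass
class PloidyClass:
    label: str
    modal_chromosomes: int
    loh_fraction: float


def classify_ploidy(
    segments: list[CopyNumberSegment], chrom_lengths: dict[str, int]
) -> PloidyClass:
    """Ploidy class from the genome-wide copy-number profile.

    The modal chromosome count sums, over contigs, each contig's
    length-weighted modal total copy number. Class boundaries follow the
    conventional B-ALL bands: 24-30 near haploid, 31-39 low hypodiploid,
    51-65 high hyperdiploid; a 60-78 count with genome-wide LOH above one half
    is called near triploid (the chromosome-doubled "masked" form of low
    hypodiploidy); everything else is diploid-range.
    """
    by_chrom: dict[str, dict[int, int]] = {c: {} for c in chrom_lengths}
    covered: dict[str, int] = {c: 0 for c in chrom_lengths}
    loh_bases = 0
    total_bases = sum(chrom_lengths.values())
    for s in segments:
        c = s.interval.chrom
        if c not in by_chrom:
            raise ValueError(f"segment on unknown contig {c}")
        by_chrom[c][s.total_cn] = by_chrom[c].get(s.total_cn, 0) + len(s.interval)
        covered[c] += len(s.interval)
        if s.minor_cn == 0:
            loh_bases += len(s.interval)
    for c, length in chrom_lengths.items():
        if covered[c] < length:
            raise ValueError(f"incomplete copy-number cover on {c}: {covered[c]}/{length} bp")
    modal = sum(max(w, key=lambda cn: (w[cn], -cn)) for w in by_chrom.values())
    loh_fraction = loh_bases / total_bases
    if 60 <= modal <= 78 and loh_fraction > 0.5:
        label = "near-triploid"
    elif 24 <= modal <= 30:
        label = "near-haploid"
    elif 31 <= modal <= 39:
        label = "low-hypodiploid"
    elif 51 <= modal <= 65:
        label = "high-hyperdiploid"
    else:
        label = "diploid-range"
    return PloidyClass(label, modal, loh_fraction)


# ---------------------------------------------------------------------------
# biallelic logic
# ---------------------------------------------------------------------------

@dataclass
class BiallelicStatus:
    gene: str
    mechanism: str  # two_mutations / mutation_plus_deletion / mutation_plus_LOH /
    #                 fusion_plus_LOH / monoallelic / none

    @property
    def biallelic(self) -> bool:
        return self.mechanism in (
            "two_mutations",
            "mutation_plus_deletion",
            "mutation_plus_LOH",
            "fusion_plus_LOH",
        )


def assess_biallelic(
    gene: str,
    case: Case,
    gene_body: GenomicInterval,
    fusions: list[tuple] = (),
    has_amplification: bool = False,
) -> BiallelicStatus:
    """Biallelic-targeting mechanism for one gene, evaluated in fixed order."""
    muts = [v for v in case.small_variants if v.gene == gene]
    from .mlpa import _modal_cn_by_chrom  # shared modal-CN helper

    baseline = _modal_cn_by_chrom(case.segments)
    over_gene = [s for s in case.segments if s.interval.overlaps(gene_body)]
    has_deletion = any(
        s.total_cn < baseline.get(s.interval.chrom, 2) and s.ccf > 0.1 for s in over_gene
    )
    has_loh = any(s.minor_cn == 0 and s.total_cn >= 1 for s in over_gene)
    has_fusion = any(gene in f[:2] for f in fusions)
    if len({(v.pos, v.protein_change) for v in muts}) >= 2:
        return BiallelicStatus(gene, "two_mutations")
    if muts and has_deletion:
        return BiallelicStatus(gene, "mutation_plus_deletion")
    if muts and has_loh:
        return BiallelicStatus(gene, "mutation_plus_LOH")
    if has_fusion and has_loh:
        return BiallelicStatus(gene, "fusion_plus_LOH")
    if muts or has_deletion or has_fusion or has_amplification:
        return BiallelicStatus(gene, "monoallelic")
    return BiallelicStatus(gene, "none")


def detect_intragenic_amplification(
    case: Case, gene_body: GenomicInterval, min_gain: int = 2
) -> bool:
    """Focal amplification: a sub-gene segment >= baseline+``min_gain`` copies
    with the gene otherwise at baseline."""
    from .mlpa import _modal_cn_by_chrom

    baseline = _modal_cn_by_chrom(case.segments).get(gene_body.chrom, 2)
    inside_high = any(
        s.interval.chrom == gene_body.chrom
        and s.interval.start >= gene_body.start
        and s.interval.end <= gene_body.end
        and s.total_cn >= baseline + min_gain
        for s in case.segments
    )
    flank_normal = any(
        s.interval.overlaps(gene_body) and s.total_cn == baseline for s in case.segments
    )
    return inside_high and flank_normal


# ---------------------------------------------------------------------------
# the precedence ladder
# ---------------------------------------------------------------------------

@dataclass
class Detections:
    """Per-case detection bundle fed to the ladder."""

    ploidy: Optional[PloidyClass] = None
    dux4: Optional[Dux4Call] = None
    walks: list[WalkCandidate] = field(default_factory=list)
    fusions: list[tuple] = field(default_factory=list)  # (gene5, gene3, sv_ids)
    chromothripsis: bool = False


@dataclass
class SubtypeCall:
    case_id: str
    label: str
    evidence: list[str]
    precedence_rank: int
    qc_status: str = "included"
    rna_agreement: str = "na"


def _walk_partners(detections: Detections, anchor_prefix: str = "IGH") -> dict[str, WalkCandidate]:
    return {
        w.gene: w
        for w in detections.walks
        if w.anchor.startswith(anchor_prefix)
    }


def assign_subtype(case: Case, detections: Detections, gene_models: dict[str, GenomicInterval]) -> SubtypeCall:
    """First matching rung of the precedence ladder wins.

    Ladder (top to bottom): WHO ploidy classes -> WHO fusions -> DUX4-r ->
    MEF2D-r -> ZNF384-r -> UBTF::ATXN7L3 -> Ph-like JAK-STAT -> ZEB2/CEBP ->
    PAX5 P80R (requires biallelic) -> PAX5alt -> IDH1/2 -> other IG-hijack
    partners -> named-but-unclassifiable lesions -> no-driver. The ordering
    encodes the mutual exclusivity of the subtype-defining lesions and
    resolves the known overlaps (a ZEB2 H1038R inside a DUX4-r case resolves
    to DUX4-r; IGH::CEBPB sits inside ZEB2/CEBP while standalone IGH::CEBPA
    is its own IG-hijack subtype).
    """
    cid = case.case_id
    fus = detections.fusions
    igh = _walk_partners(detections, "IGH")
    igk = _walk_partners(detections, "IGK")

    # 1. WHO ploidy classes
    if detections.ploidy and detections.ploidy.label in WHO_PLOIDY_LABELS:
        p = detections.ploidy
        return SubtypeCall(cid, p.label, [f"ploidy:modal={p.modal_chromosomes},loh={p.loh_fraction:.2f}"], 1)
    # 2. WHO fusions
    for g5, g3, *_ in fus:
        if (g5, g3) in WHO_FUSIONS:
            return SubtypeCall(cid, WHO_FUSIONS[(g5, g3)], [f"fusion:{g5}::{g3}"], 2)
    # 3. DUX4-r
    if detections.dux4 is not None:
        d = detections.dux4
        ev = [f"dux4:{d.partner}:{d.configuration}:{d.evidence}"]
        if "DUX4" in igh:
            ev.append(f"walk:IGH::DUX4:{igh['DUX4'].walk_length_bp}bp")
        for v in case.small_variants:
            if v.gene == "ZEB2" and "H1038R" in v.protein_change:
                ev.append(f"co-occurring variant:ZEB2 {v.protein_change} (resolved to DUX4-r)")
        return SubtypeCall(cid, "DUX4-r", ev, 3)
    if "DUX4" in igh:
        return SubtypeCall(cid, "DUX4-r", [f"walk:IGH::DUX4:{igh['DUX4'].walk_length_bp}bp"], 3)
    # 4. MEF2D-r
    for g5, g3, *_ in fus:
        if "MEF2D" in (g5, g3):
            return SubtypeCall(cid, "MEF2D-r", [f"fusion:{g5}::{g3}"], 4)
    # 5. ZNF384-r
    for g5, g3, *_ in fus:
        if "ZNF384" in (g5, g3):
            return SubtypeCall(cid, "ZNF384-r", [f"fusion:{g5}::{g3}"], 5)
    # 6. UBTF::ATXN7L3
    for g5, g3, *_ in fus:
        if (g5, g3) == ("UBTF", "ATXN7L3") or (g5, g3) == ("ATXN7L3", "UBTF"):
            return SubtypeCall(cid, "UBTF::ATXN7L3", [f"fusion:{g5}::{g3}"], 6)
    # 7. Ph-like JAK-STAT
    if "EPOR" in igh:
        return SubtypeCall(cid, "Ph-like JAK-STAT", [f"walk:IGH::EPOR:{igh['EPOR'].walk_length_bp}bp"], 7)
    for g5, g3, *_ in fus:
        if "CRLF2" in (g5, g3):
            return SubtypeCall(cid, "Ph-like JAK-STAT", [f"fusion:{g5}::{g3}"], 7)
    # 8. ZEB2/CEBP
    zeb2 = [v for v in case.small_variants if v.gene == "ZEB2" and "H1038R" in v.protein_change]
    if zeb2 or "CEBPB" in igh:
        ev = [f"variant:ZEB2 {v.protein_change} vaf={v.vaf:.2f}" for v in zeb2]
        if "CEBPB" in igh:
            ev.append(f"walk:IGH::CEBPB:{igh['CEBPB'].walk_length_bp}bp")
        return SubtypeCall(cid, "ZEB2/CEBP", ev, 8)
    # 9/10. PAX5 rungs
    pax5_body = gene_models["PAX5"]
    pax5_amp = detect_intragenic_amplification(case, pax5_body)
    bi = assess_biallelic("PAX5", case, pax5_body, fusions=fus, has_amplification=pax5_amp)
    p80r = [v for v in case.small_variants if v.gene == "PAX5" and "P80R" in v.protein_change]
    if p80r and bi.biallelic:
        return SubtypeCall(cid, "PAX5 P80R", [f"variant:PAX5 P80R, mechanism={bi.mechanism}"], 9)
    pax5_fusion = [f for f in fus if "PAX5" in f[:2]]
    if pax5_fusion or pax5_amp or (bi.biallelic and not p80r):
        ev = [f"fusion:{f[0]}::{f[1]}" for f in pax5_fusion]
        if pax5_amp:
            ev.append("amplification:PAX5 intragenic")
        if bi.biallelic:
            ev.append(f"biallelic:PAX5 mechanism={bi.mechanism}")
        return SubtypeCall(cid, "PAX5alt", ev, 10)
    # 11. IDH1/2
    idh = [v for v in case.small_variants if v.gene in ("IDH1", "IDH2") and v.classification == "SNV"]
    if idh:
        v = idh[0]
        return SubtypeCall(cid, "IDH1/2", [f"variant:{v.gene} {v.protein_change} vaf={v.vaf:.2f}"], 11)
    # 12. other IG enhancer hijacks
    for partner in IG_HIJACK_PARTNERS:
        if partner in igh:
            return SubtypeCall(cid, f"IGH::{partner}", [f"walk:IGH::{partner}:{igh[partner].walk_length_bp}bp"], 12)
        if partner in igk:
            return SubtypeCall(cid, f"IGK::{partner}", [f"walk:IGK::{partner}:{igk[partner].walk_length_bp}bp"], 12)
    # 13. named but unclassifiable findings
    findings = [f"fusion:{g5}::{g3}" for g5, g3, *_ in fus if (g5, g3) in WATCHLIST_FUSIONS]
    findings += [
        f"variant:{v.gene} {v.protein_change}"
        for v in case.small_variants
        if v.gene in WATCHLIST_GENES and v.protein_change
    ]
    findings += [f"sv:{g5}::{g3}" for g5, g3, *_ in fus if "KDM6A" in (g5, g3)]
    if findings:
        return SubtypeCall(cid, "unclassifiable", findings, 13)
    # 14. nothing
    return SubtypeCall(cid, "no-driver", [], 14)


# ---------------------------------------------------------------------------
# RNA consensus and reconciliation
# ---------------------------------------------------------------------------

def rna_consensus(rna: RnaEvidence) -> Optional[str]:
    """Label agreed by >=2 of 3 expression classifiers, else the reference
    clustering label; ``None`` when quality flags void the RNA arm."""
    if rna.quality_flags & {"contamination", "low_purity"}:
        return None
    labels = [l for l in rna.classifier_labels.values() if l]
    for lab in labels:
        if labels.count(lab) >= 2:
            return lab
    return rna.cluster_label or None


def reconcile(
    wgs_call: SubtypeCall,
    rna: Optional[RnaEvidence],
) -> SubtypeCall:
    """Attach RNA agreement to the WGS call; discordances are reported, never
    overwritten."""
    if rna is None:
        wgs_call.rna_agreement = "na"
        return wgs_call
    label = rna_consensus(rna)
    fusion_names = {f"{a}::{b}" for a, b in rna.fusions}
    evidence_blob = " ".join(wgs_call.evidence) + " " + wgs_call.label
    fusion_match = any(name in evidence_blob for name in fusion_names)
    if label is None:
        wgs_call.rna_agreement = "wgs_only" if fusion_match is False else "concordant"
    elif wgs_call.label in NON_SUBTYPE_LABELS:
        wgs_call.rna_agreement = "rna_only"
    elif label == wgs_call.label or fusion_match:
        wgs_call.rna_agreement = "concordant"
    else:
        wgs_call.rna_agreement = "discordant"
    return wgs_call
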