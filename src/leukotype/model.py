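"""Shared domain types for the B-ALL WGS classification pipeline.

Coordinates are 1-based inclusive throughout (VCF convention). BED export is
the only place a conversion happens (start minus one, half-open).

Breakend orientation vocabulary: ``tail`` means the *left* (5' on the
reference) side of the breakpoint is retained in the derivative chromosome —
the junction hangs off the right end of the retained piece (VCF ``t[p[`` /
``t]p]`` records). ``head`` means the right side is retained (``]p]t`` /
``[p[t``). All downstream logic uses this vocabulary; VCF brackets are decoded
once at parse time.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional

TAIL = "tail"  # left/5' side of the breakpoint retained
HEAD = "head"  # right/3' side retained

SV_CLASSES = ("deletion", "duplication", "inversion", "translocation")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end < start on {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def to_bed(self) -> tuple[str, int, int]:
        """0-based half-open triple for BED export."""
        return (self.chrom, self.start - 1, self.end)


@dataclass(frozen=True)
class BreakendEnd:
    chrom: str
    pos: int
    orientation: str  # TAIL or HEAD

    def __post_init__(self) -> None:
        if self.orientation not in (TAIL, HEAD):
            raise ValueError(f"orientation must be head/tail, got {self.orientation!r}")


def classify_junction(end1: BreakendEnd, end2: BreakendEnd) -> str:
    """SV class implied by an orientation pair (intra-chromosomal) or translocation."""
    if end1.chrom != end2.chrom:
        return "translocation"
    lo, hi = sorted((end1, end2), key=lambda e: e.pos)
    if lo.orientation == TAIL and hi.orientation == HEAD:
        return "deletion"
    if lo.orientation == HEAD and hi.orientation == TAIL:
        return "duplication"
    return "inversion"


@dataclass(frozen=True)
class BreakendPair:
    """A mated breakend junction (one SV call)."""

    id: str
    end1: BreakendEnd
    end2: BreakendEnd
    svclass: str = ""
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        svclass = self.svclass or classify_junction(self.end1, self.end2)
        object.__setattr__(self, "svclass", svclass)
        if svclass not in SV_CLASSES:
            raise ValueError(f"bad svclass {svclass!r}")
        if svclass == "deletion" and not (
            self.end1.chrom == self.end2.chrom
            and min(self.end1.pos, self.end2.pos) < max(self.end1.pos, self.end2.pos)
        ):
            raise ValueError(f"deletion {self.id} must have two ordered ends on one chromosome")

    def reversed(self) -> "BreakendPair":
        return BreakendPair(self.id, self.end2, self.end1, self.svclass, self.inserted_seq)

    @property
    def span(self) -> int:
        """Breakpoint distance for intra-chromosomal events (0 for translocations)."""
        if self.end1.chrom != self.end2.chrom:
            return 0
        return abs(self.end2.pos - self.end1.pos)


@dataclass(frozen=True)
class SingleBreakend:
    """An SV anchored at only one locus, with unplaced partner sequence attached."""

    id: str
    locus: BreakendEnd
    attached_seq: str

    def __post_init__(self) -> None:
        if not self.attached_seq:
            raise ValueError(f"single breakend {self.id} has empty attached sequence")


@dataclass(frozen=True)
class CopyNumberSegment:
    interval: GenomicInterval
    total_cn: int
    minor_cn: int
    ccf: float = 1.0  # cancer-cell fraction of the aberration

    def __post_init__(self) -> None:
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} > total_cn {self.total_cn} "
                f"at {self.interval.chrom}:{self.interval.start}"
            )
        if not 0.0 <= self.ccf <= 1.0:
            raise ValueError(f"ccf must be in [0,1], got {self.ccf}")

    @property
    def is_loh(self) -> bool:
        return self.minor_cn == 0 and self.total_cn >= 1


@dataclass(frozen=True)
class SmallVariant:
    locus: BreakendEnd | GenomicInterval | tuple
    ref: str
    alt: str
    vaf: float
    gene: str = ""
    protein_change: str = ""
    classification: str = ""  # SNV / insertion / deletion-small

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0,1], got {self.vaf}")
        cls = self.classification
        if not cls:
            if len(self.ref) == 1 and len(self.alt) == 1:
                cls = "SNV"
            elif len(self.alt) > len(self.ref):
                cls = "insertion"
            else:
                cls = "deletion-small"
            object.__setattr__(self, "classification", cls)
        if (cls == "SNV") != (len(self.ref) == 1 and len(self.alt) == 1):
            raise ValueError("SNV classification requires single-base ref and alt")

    @property
    def chrom(self) -> str:
        return self.locus[0] if isinstance(self.locus, tuple) else self.locus.chrom

    @property
    def pos(self) -> int:
        return self.locus[1] if isinstance(self.locus, tuple) else getattr(self.locus, "pos", self.locus.start)


@dataclass
class RnaEvidence:
    """RNA-side evidence, consumed as labels (expression classifiers are upstream)."""

    classifier_labels: dict[str, str] = field(default_factory=dict)
    cluster_label: str = ""
    fusions: list[tuple[str, str]] = field(default_factory=list)
    quality_flags: set[str] = field(default_factory=set)


KARYOTYPE_CLASSES = ("normal", "nonspecific-abnormal", "complex", "failed")


@dataclass
class Case:
    """One patient's variant-level evidence bundle."""

    case_id: str
    age: float
    sex: str = "F"
    karyotype_class: str = "normal"
    purity: Optional[float] = None
    svs: list[BreakendPair] = field(default_factory=list)
    single_breakends: list[SingleBreakend] = field(default_factory=list)
    segments: list[CopyNumberSegment] = field(default_factory=list)
    small_variants: list[SmallVariant] = field(default_factory=list)
    rna: Optional[RnaEvidence] = None
    mlpa: Optional[dict[str, str]] = None  # gene -> {deleted, normal}

    @property
    def snvs(self) -> list[SmallVariant]:
        return [v for v in self.small_variants if v.classification == "SNV"]


@dataclass
class Cohort:
    cases: list[Case]
    ground_truth: "object" = None  # pandas DataFrame of planted lesions
    config: Optional[dict] = None

    def __iter__(self):
        return iter(self.cases)

    def __len__(self) -> int:
        return len(self.cases)

    def case(self, case_id: str) -> Case:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)


def estimate_purity(case: Case, min_snvs: int = 20) -> Optional[float]:
    """Estimate tumor purity as 2 x median VAF of SNVs on diploid-heterozygous segments.

    On a total_cn=2 / minor_cn=1 segment a clonal heterozygous somatic SNV has
    expected VAF = purity/2, so twice the median VAF (clipped to 1) recovers the
    admixture fraction. Returns ``None`` (purity unknown) when fewer than
    ``min_snvs`` informative SNVs exist.
    """
    diploid_het = [
        s for s in case.segments if s.total_cn == 2 and s.minor_cn == 1
    ]
    if not diploid_het:
        return None
    vafs = [
        v.vaf
        for v in case.snvs
        if any(s.interval.contains(v.chrom, v.pos) for s in diploid_het)
    ]
    if len(vafs) < min_snvs:
        return None
    return min(1.0, 2.0 * statistics.median(vafs))
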