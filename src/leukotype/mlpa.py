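"""MLPA probe-dosage simulation and WGS-vs-MLPA deletion concordance.

MLPA reports a per-probe dosage ratio against a diploid normal. With tumor
purity p and aberration cell fraction ccf, a probe sitting on tumor copy
number ``cn`` has expected ratio

    r = (p * ccf * cn + (1 - p * ccf) * 2) / 2

and a gene is called deleted when at least two consecutive probes drop below a
ratio threshold (default 0.75). The WGS arm calls a gene deleted when any
tumor segment below the chromosome's modal copy number overlaps the gene body
at an appreciable cell fraction. Discrepancies (WGS-only events) are
categorized in precedence order: probe placement (the deletion touches fewer
than two consecutive probes), subclonal (ccf < 0.6), then purity/ploidy.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .model import Case, CopyNumberSegment

MLPA_THRESHOLD = 0.75
SUBCLONAL_CCF = 0.6
MIN_WGS_CCF = 0.1

PANEL_GENES = ("EBF1", "IKZF1", "CDKN2A", "CDKN2B", "PAX5", "ETV6", "BTG1", "RB1")


@dataclass(frozen=True)
class ProbePanel:
    """Probe coordinates for the 8-gene focal-deletion panel (3-8 probes/gene)."""

    probes: dict[str, tuple[tuple[str, int], ...]]  # gene -> ((chrom, pos), ...)

    def __post_init__(self) -> None:
        for gene, pp in self.probes.items():
            if len(pp) < 3:
                raise ValueError(f"{gene}: panel needs >=3 probes")

    @classmethod
    def packaged(cls) -> "ProbePanel":
        with resources.files("leukotype.data").joinpath("mlpa_panel.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
        probes = {
            gene: tuple((r.chrom, int(r.pos)) for r in sub.sort_values("probe").itertuples())
            for gene, sub in df.groupby("gene", sort=True)
        }
        return cls(probes)


def _segment_at(segments: list[CopyNumberSegment], chrom: str, pos: int) -> CopyNumberSegment | None:
    for s in segments:
        if s.interval.contains(chrom, pos):
            return s
    return None


def _modal_cn_by_chrom(segments: list[CopyNumberSegment]) -> dict[str, int]:
    weights: dict[str, dict[int, int]] = {}
    for s in segments:
        weights.setdefault(s.interval.chrom, {})
        weights[s.interval.chrom][s.total_cn] = (
            weights[s.interval.chrom].get(s.total_cn, 0) + len(s.interval)
        )
    return {c: max(w, key=lambda cn: (w[cn], -cn)) for c, w in weights.items()}


def simulate_mlpa(
    case: Case,
    panel: ProbePanel,
    threshold: float = MLPA_THRESHOLD,
) -> dict[str, str]:
    """Per-gene MLPA calls ('deleted' / 'normal') from copy-number truth."""
    if case.purity is None:
        raise ValueError(f"{case.case_id}: purity unknown, cannot simulate MLPA")
    p = case.purity
    calls: dict[str, str] = {}
    for gene, probes in panel.probes.items():
        ratios = []
        for chrom, pos in probes:
            seg = _segment_at(case.segments, chrom, pos)
            cn, ccf = (seg.total_cn, seg.ccf) if seg is not None else (2, 1.0)
            ratios.append((p * ccf * cn + (1 - p * ccf) * 2) / 2)
        low = [r < threshold for r in ratios]
        consecutive = any(a and b for a, b in zip(low, low[1:]))
        calls[gene] = "deleted" if consecutive else "normal"
    return calls


def wgs_deletion_calls(
    case: Case,
    panel_genes: dict[str, "object"],
    min_ccf: float = MIN_WGS_CCF,
) -> dict[str, str]:
    """Per-gene WGS deletion calls: any sub-modal segment overlapping the gene."""
    baseline = _modal_cn_by_chrom(case.segments)
    calls: dict[str, str] = {}
    for gene, body in panel_genes.items():
        hit = any(
            s.interval.overlaps(body)
            and s.total_cn < baseline.get(s.interval.chrom, 2)
            and s.ccf > min_ccf
            for s in case.segments
        )
        calls[gene] = "deleted" if hit else "normal"
    return calls


@dataclass
class ConcordanceRecord:
    case_id: str
    gene: str
    mlpa_call: str
    wgs_call: str
    discrepancy_category: str  # none / purity_ploidy / subclonal / probe_placement


def compare(
    mlpa_calls: dict[str, str],
    wgs_calls: dict[str, str],
    case: Case,
    panel: ProbePanel,
    panel_genes: dict[str, "object"],
) -> list[ConcordanceRecord]:
    """Gene-level concordance records with WGS-only events categorized."""
    records = []
    baseline = _modal_cn_by_chrom(case.segments)
    for gene in panel.probes:
        m, w = mlpa_calls.get(gene, "normal"), wgs_calls.get(gene, "normal")
        category = "none"
        if m != w and w == "deleted":
            category = _categorize(case, gene, panel, panel_genes, baseline)
        elif m != w:
            category = "purity_ploidy"  # MLPA-only event: dosage artefact
        records.append(ConcordanceRecord(case.case_id, gene, m, w, category))
    return records


def _categorize(case, gene, panel, panel_genes, baseline) -> str:
    body = panel_genes[gene]
    del_segs = [
        s
        for s in case.segments
        if s.interval.overlaps(body)
        and s.total_cn < baseline.get(s.interval.chrom, 2)
        and s.ccf > MIN_WGS_CCF
    ]
    probes = panel.probes[gene]
    # probe placement: the deletion never covers two consecutive probes
    covered = [any(s.interval.contains(c, pos) for s in del_segs) for c, pos in probes]
    if not any(a and b for a, b in zip(covered, covered[1:])):
        return "probe_placement"
    if max(s.ccf for s in del_segs) < SUBCLONAL_CCF:
        return "subclonal"
    return "purity_ploidy"


def cohort_concordance(
    cases: list[Case],
    panel: ProbePanel,
    panel_genes: dict[str, "object"],
) -> pd.DataFrame:
    """Tidy concordance table over every case with MLPA data."""
    rows = []
    for case in cases:
        if case.mlpa is None:
            continue
        wgs = wgs_deletion_calls(case, panel_genes)
        for rec in compare(case.mlpa, wgs, case, panel, panel_genes):
            rows.append(vars(rec))
    return pd.DataFrame(
        rows,
        columns=["case_id", "gene", "mlpa_call", "wgs_call", "discrepancy_category"],
    )
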